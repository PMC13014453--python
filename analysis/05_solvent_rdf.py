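"""Water-accessibility diagnostic: RDF around a shielded vs exposed bond.

Builds synthetic solvent frames around an interaction site with and without
a glue-like excluded region, computes g(r) on the standard 0–10 Å grid with
0.1 Å bins, and integrates the difference over the first-shell window.  A
positive shielding delta means the ternary site is drier — the hydrophobic
shielding signature that accompanies strengthened interface H-bonds.
"""

import argparse
from pathlib import Path

import numpy as np

from hbpmf import PointFrameSet, radial_distribution, shielding_delta


def frames_with_exclusion(rng, box, n_points, n_frames, excluded_radius):
    center = np.array([[box / 2, box / 2, box / 2]])
    frames = []
    for _ in range(n_frames):
        pts = rng.uniform(0, box, size=(n_points, 3))
        if excluded_radius > 0:
            d = np.linalg.norm(pts - center, axis=1)
            # soft exclusion: solvent within the shielded shell is mostly gone
            keep = (d > excluded_radius) | (rng.random(len(pts)) < 0.15)
            pts = pts[keep]
        frames.append((pts, center))
    return PointFrameSet(frames=tuple(frames), box=(box,) * 3)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20260101)
    ap.add_argument("--out", type=Path, default=Path("results/rdf"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    box, n_points, n_frames = 24.0, 8000, 12
    binary = frames_with_exclusion(rng, box, n_points, n_frames, 0.0)
    ternary = frames_with_exclusion(rng, box, n_points, n_frames, 4.5)

    r, g_binary = radial_distribution(binary)
    _, g_ternary = radial_distribution(ternary)
    with open(args.out / "rdf.tsv", "w", encoding="utf-8") as fh:
        fh.write("r_A\tg_binary\tg_ternary\n")
        for ri, gb, gt in zip(r, g_binary, g_ternary):
            fh.write(f"{ri:.2f}\t{gb:.5f}\t{gt:.5f}\n")

    delta = shielding_delta(r, g_binary, g_ternary, (2.0, 4.5))
    print(f"first-shell g(r) binary  ~ {g_binary[(r > 2.5) & (r < 4.0)].mean():.2f}")
    print(f"first-shell g(r) ternary ~ {g_ternary[(r > 2.5) & (r < 4.0)].mean():.2f}")
    print(f"shielding delta over [2.0, 4.5] Å: {delta:.2f} (positive = drier "
          "ternary interface)")
    print(f"profiles written to {args.out / 'rdf.tsv'}")


if __name__ == "__main__":
    main()
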