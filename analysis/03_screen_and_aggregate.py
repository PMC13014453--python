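"""Screen simulated interactions and aggregate them into a summary table.

Runs the full pipeline on a three-bond demo system: two independent bonds
plus one whose rupture is strongly correlated with the first (shared-noise
fraction 0.95).  The Mann–Whitney screen keeps bonds whose binary and
ternary work distributions differ; the Pearson screen then drops the
correlated duplicate so its contribution is not double-counted.  The
resulting ΣPMF table shows the glue-induced stabilisation ΔΣPMF.
"""

import argparse
from pathlib import Path

from hbpmf import RunConfig, render_table, run_pipeline
from hbpmf.config import InteractionSpec


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20260101)
    ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()

    config = RunConfig(
        system="toy-glue-demo",
        interactions=(
            InteractionSpec("bond_1"),
            InteractionSpec("bond_2",
                            potential_overrides={"well_depth": 4.5}),
            InteractionSpec("bond_1_twin", correlated_with="bond_1",
                            rho=0.95),
        ),
        base_seed=args.seed)
    table = run_pipeline(config, args.out)
    print(render_table(table, "markdown"))

    d, sd = table.delta_sigma("ternary")
    excluded = [r.interaction_id for r in table.rows if not r.included]
    print(f"ΔΣPMF_HB_break = {d:.2f} ± {sd:.2f} kcal/mol over "
          f"{len(table.included_rows())} retained interactions; "
          f"excluded: {excluded or 'none'}")
    print(f"artifacts in {args.out}")


if __name__ == "__main__":
    main()
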