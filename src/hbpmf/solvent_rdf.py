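"""Radial distribution function of solvent around interaction sites.

g(r) is the ratio of the local solvent number density at distance r from a
set of reference centres to the bulk density, averaged over frames and over
the pooled centres.  A depressed first/second shell around an interface
hydrogen bond relative to its binary counterpart is the signature of
hydrophobic shielding by a bound molecular glue; ``shielding_delta``
quantifies it as the integrated difference over a distance window.

Defaults follow common trajectory-analysis practice: 0–10 Å range with
0.1 Å bins.  Shell volumes are exact spherical shells, (4π/3)(r_o³ − r_i³);
distances use the minimum-image convention when a periodic box is given and
open boundaries otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PointFrameSet", "radial_distribution", "shielding_delta"]


@dataclass(frozen=True)
class PointFrameSet:
    """Solvent and centre coordinates per frame, with an optional periodic box.

    ``frames`` is a sequence of ``(solvent, centers)`` pairs of (N, 3) and
    (M, 3) arrays in Å; ``box`` is the orthorhombic box edge lengths in Å,
    or ``None`` for open boundaries.
    """

    frames: tuple
    box: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("at least one frame required")
        frames = []
        for solvent, centers in self.frames:
            s = np.atleast_2d(np.asarray(solvent, dtype=float))
            c = np.atleast_2d(np.asarray(centers, dtype=float))
            if s.size and (s.shape[1] != 3 or not np.all(np.isfinite(s))):
                raise ValueError("solvent coordinates must be finite (N, 3)")
            if c.shape[1] != 3 or not np.all(np.isfinite(c)):
                raise ValueError("center coordinates must be finite (M, 3)")
            frames.append((s, c))
        object.__setattr__(self, "frames", tuple(frames))
        if self.box is not None:
            b = tuple(float(x) for x in self.box)
            if len(b) != 3 or any(x <= 0 for x in b):
                raise ValueError("box must be three positive edge lengths")
            object.__setattr__(self, "box", b)


def _pair_distances(centers: np.ndarray, solvent: np.ndarray,
                    box: tuple | None) -> np.ndarray:
    diff = solvent[None, :, :] - centers[:, None, :]
    if box is not None:
        b = np.asarray(box)
        diff -= b * np.round(diff / b)
    return np.sqrt((diff ** 2).sum(axis=2)).ravel()


def radial_distribution(
    frames: PointFrameSet,
    r_max: float = 10.0,
    bin_width: float = 0.1,
    bulk_density: float | str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """g(r) of solvent points around pooled centres.

    Returns ``(r, g)`` where ``r`` holds bin midpoints.  With
    ``bulk_density="auto"`` the bulk is the mean solvent count divided by
    the box volume (requires a periodic box); otherwise pass an explicit
    number density in 1/Å³.
    """
    if not (r_max > bin_width > 0):
        raise ValueError("require r_max > bin_width > 0")
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    n_bins = len(edges) - 1
    counts = np.zeros(n_bins)
    n_center_frames = 0
    total_solvent = 0
    for solvent, centers in frames.frames:
        total_solvent += len(solvent)
        n_center_frames += len(centers)
        if len(solvent) == 0:
            continue
        d = _pair_distances(centers, solvent, frames.box)
        hist, _ = np.histogram(d, bins=edges)
        counts += hist
    if total_solvent == 0:
        warnings.warn("no solvent points; g(r) is identically zero")
        return 0.5 * (edges[:-1] + edges[1:]), np.zeros(n_bins)

    if bulk_density == "auto":
        if frames.box is None:
            raise ValueError("auto bulk density requires a periodic box")
        volume = float(np.prod(frames.box))
        bulk = (total_solvent / len(frames.frames)) / volume
    else:
        bulk = float(bulk_density)
        if bulk <= 0:
            raise ValueError("bulk_density must be positive")

    shell_volumes = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / n_center_frames / (shell_volumes * bulk)
    r = 0.5 * (edges[:-1] + edges[1:])
    return r, g


def shielding_delta(
    r: np.ndarray,
    g_binary: np.ndarray,
    g_ternary: np.ndarray,
    window: tuple[float, float],
) -> float:
    """Integrated solvent-depletion difference over a distance window.

    Trapezoid integral of (g_binary − g_ternary) over ``window``; positive
    values mean the ternary complex is drier (shielded) around the bond.
    Grids must be aligned.
    """
    r = np.asarray(r, dtype=float)
    gb = np.asarray(g_binary, dtype=float)
    gt = np.asarray(g_ternary, dtype=float)
    if not (r.shape == gb.shape == gt.shape):
        raise ValueError("misaligned grids")
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must satisfy r_hi > r_lo")
    if lo < r[0] or hi > r[-1]:
        raise ValueError("window extends beyond the g(r) grid")
    diff = gb - gt
    inner = r[(r > lo) & (r < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    return float(np.trapezoid(np.interp(grid, r, diff), grid))
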