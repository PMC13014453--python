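"""Reaction coordinates used to steer and measure hydrogen-bond interactions.

Three kinds of coordinate cover the interactions measured in molecular-glue
interfaces:

* a plain donor–acceptor distance,
* a distance to the centre of mass of a symmetric group (carboxylates and
  similar rotatable groups, where pulling a single atom would not strain the
  interaction), and
* a smooth "number of bonds" coordination count over several atom pairs,
  needed for the higher symmetry of a fully deprotonated phosphate,

      CV = sum_p (1 - (r_p/r0)^6) / (1 - (r_p/r0)^12).

The rational 6-12 switching term has a removable singularity at r = r0; it is
algebraically identical to 1/(1 + (r/r0)^6) for all r >= 0, which is the form
evaluated here.  At r = r0 the value is exactly 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CollectiveVariable",
    "eval_distance",
    "eval_com_distance",
    "eval_number_of_bonds",
    "switching_term",
]

#: Outward shift (in Å) applied to pulling thresholds when the steered
#: coordinate is a centre-of-mass distance rather than an atom–atom distance.
COM_THRESHOLD_ADJUSTMENT = 0.5


@dataclass(frozen=True)
class CollectiveVariable:
    """Definition of a steered/measured reaction coordinate.

    Parameters
    ----------
    kind :
        One of ``"distance"``, ``"com_distance"``, ``"number_of_bonds"``.
    atom_pairs :
        Point-pair selectors (opaque labels or index pairs); at least one
        pair is required for ``number_of_bonds``.
    r0 :
        Switching radius in Å (``number_of_bonds`` only; must be > 0).  No
        universally agreed value exists for phosphate coordination counts, so
        it is always explicit, never defaulted.
    threshold_adjustment :
        Å added outward to the pulling window: 0 for a plain distance,
        0.5 for a centre-of-mass distance.
    """

    kind: str
    atom_pairs: Sequence = field(default_factory=tuple)
    r0: float | None = None
    threshold_adjustment: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"distance", "com_distance", "number_of_bonds"}:
            raise ValueError(f"unknown collective-variable kind {self.kind!r}")
        if self.kind == "number_of_bonds":
            if self.r0 is None or self.r0 <= 0:
                raise ValueError("number_of_bonds requires r0 > 0")
            if len(self.atom_pairs) < 1:
                raise ValueError("number_of_bonds requires at least one atom pair")
        if self.kind == "com_distance" and self.threshold_adjustment == 0.0:
            object.__setattr__(
                self, "threshold_adjustment", COM_THRESHOLD_ADJUSTMENT
            )

    def adjusted_window(self, pull_start: float, pull_end: float) -> tuple[float, float]:
        """Pulling window shifted outward by ``threshold_adjustment``.

        The shift is applied outward (start unchanged downward is not needed
        because the coordinate starts deeper in the well; the end is extended)
        so that the full rupture event is still spanned when the coordinate is
        a centre-of-mass distance.
        """
        return pull_start, pull_end + self.threshold_adjustment


def eval_distance(p, q) -> float:
    """Euclidean distance in Å between two 3-vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def eval_com_distance(point, group: Sequence[tuple]) -> float:
    """Distance from ``point`` to the mass-weighted centroid of ``group``.

    ``group`` is a sequence of ``(3-vector, mass)`` pairs with positive masses.
    """
    if len(group) == 0:
        raise ValueError("group must be nonempty")
    coords = np.asarray([g[0] for g in group], dtype=float)
    masses = np.asarray([g[1] for g in group], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    total = masses.sum()
    if total == 0:
        raise ValueError("zero total mass")
    com = (coords * masses[:, None]).sum(axis=0) / total
    return eval_distance(point, com)


def switching_term(r, r0: float):
    """Single-pair rational 6-12 switching term, evaluated stably.

    Uses the closed form 1/(1 + (r/r0)^6), identical to
    (1 - (r/r0)^6)/(1 - (r/r0)^12) everywhere the latter is defined and equal
    to its continuous limit 1/2 at r = r0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    return 1.0 / (1.0 + (r / r0) ** 6)


def eval_number_of_bonds(cv: CollectiveVariable, distances: Sequence[float]) -> float:
    """Smooth coordination count over the pairs of ``cv`` at the given distances.

    Each term lies in (0, 1]; the total lies in (0, n_pairs].  The count is
    strictly decreasing in every distance.
    """
    if cv.kind != "number_of_bonds":
        raise ValueError("eval_number_of_bonds requires a number_of_bonds CV")
    r = np.asarray(distances, dtype=float)
    return float(np.sum(switching_term(r, cv.r0)))
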