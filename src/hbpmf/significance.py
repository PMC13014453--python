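"""Significance screening, independence screening, and summary tables.

A per-bond rupture free energy only counts toward a complex's total if

* the binary and ternary work distributions differ significantly
  (two-sided Mann–Whitney U test, α = 0.05), and
* its rupture is not strongly correlated with another retained bond's
  rupture (Pearson correlation of rupture distances > 0.5), which would
  double-count a single mechanical event.

The retained rows sum to ΣPMF_HB_break per condition, with uncertainties
combined in quadrature; ΔΣPMF_HB_break is the ternary-minus-binary footer
difference.  Rendering rounds half-away-from-zero to one decimal; full
precision is kept internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .pmf_estimation import PMFEstimate
from .work_model import RuptureRecord

__all__ = [
    "InteractionComparison",
    "ExclusionReport",
    "SummaryRow",
    "SummaryTable",
    "mann_whitney_screen",
    "correlation_screen",
    "aggregate",
    "summary_from_estimates",
    "render_table",
    "round_half_away",
]

DEFAULT_ALPHA = 0.05
DEFAULT_CORRELATION_THRESHOLD = 0.5


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (2.45 -> 2.5, -2.45 -> -2.5)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def mann_whitney_screen(
    works_a: Sequence[float],
    works_b: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, float, bool]:
    """Two-sided Mann–Whitney U test on two work distributions.

    Returns ``(U, p, significant)`` where U is the statistic of the first
    sample (number of (a, b) pairs with a > b, plus half the ties) and
    ``significant`` means p ≤ alpha.  The null distribution is exact for
    samples of at most 8 per side without ties, and the tie-corrected normal
    approximation otherwise.  If every value is tied across both samples the
    test is degenerate: p = 1, not significant.
    """
    a = np.asarray(works_a, dtype=float)
    b = np.asarray(works_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return float(a.size * b.size / 2.0), 1.0, False
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), p, p <= alpha


@dataclass(frozen=True)
class InteractionComparison:
    """Binary-vs-ternary screening result for one interaction."""

    interaction_id: str
    pmf_binary: PMFEstimate
    pmf_ternary: PMFEstimate
    mwu_u: float
    mwu_p: float
    alpha: float = DEFAULT_ALPHA

    @property
    def delta(self) -> float:
        return self.pmf_ternary.value - self.pmf_binary.value

    @property
    def delta_sd(self) -> float:
        return math.hypot(self.pmf_binary.bootstrap_sd,
                          self.pmf_ternary.bootstrap_sd)

    @property
    def significant(self) -> bool:
        return self.mwu_p <= self.alpha

    def to_dict(self) -> dict:
        return {
            "interaction_id": self.interaction_id,
            "pmf_binary": self.pmf_binary.to_dict(),
            "pmf_ternary": self.pmf_ternary.to_dict(),
            "delta": self.delta,
            "delta_sd": self.delta_sd,
            "mwu_u": self.mwu_u,
            "mwu_p": self.mwu_p,
            "alpha": self.alpha,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of the rupture-distance correlation screen.

    ``pairs`` lists every computed (id_a, id_b, pearson_r); ``excluded_ids``
    are interactions dropped because they shared a correlated rupture with a
    retained interaction of larger |ΔPMF|.
    """

    pairs: tuple
    excluded_ids: tuple
    threshold: float = DEFAULT_CORRELATION_THRESHOLD

    def __post_init__(self) -> None:
        flagged = {i for a, b, r in self.pairs if abs(r) > self.threshold
                   for i in (a, b)}
        for ex in self.excluded_ids:
            if ex not in flagged:
                raise ValueError(
                    f"excluded id {ex!r} not in any pair above threshold")


def _rupture_distances(records: Sequence) -> np.ndarray:
    vals = [r.rupture_distance if isinstance(r, RuptureRecord) else float(r)
            for r in records]
    return np.asarray(vals, dtype=float)


def correlation_screen(
    records: Mapping[str, Sequence],
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
    deltas: Mapping[str, float] | None = None,
) -> ExclusionReport:
    """Pairwise Pearson screen of rupture distances across interactions.

    ``records`` maps interaction id to its per-replicate rupture records (or
    raw rupture distances), matched on replicate index across interactions.
    For every retained pair with |r| above ``threshold`` exactly one member
    is excluded: the one with the smaller |ΔPMF| (as given by ``deltas``;
    ties drop the lexicographically later id).  Exclusions cascade until no
    retained pair exceeds the threshold.  Zero-variance vectors make r
    undefined; those pairs are skipped with a warning.
    """
    ids = sorted(records.keys())
    vecs = {i: _rupture_distances(records[i]) for i in ids}
    lengths = {len(v) for v in vecs.values()}
    if len(lengths) > 1:
        raise ValueError("interactions must be measured on matched replicates")
    deltas = dict(deltas or {})
    pairs = []
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1:]:
            va, vb = vecs[id_a], vecs[id_b]
            if np.std(va) == 0 or np.std(vb) == 0:
                warnings.warn(
                    f"zero-variance rupture distances for pair "
                    f"({id_a}, {id_b}); correlation undefined, pair skipped")
                continue
            r = float(stats.pearsonr(va, vb).statistic)
            pairs.append((id_a, id_b, r))

    retained = set(ids)
    excluded: list[str] = []
    while True:
        live = [(a, b, r) for a, b, r in pairs
                if a in retained and b in retained and abs(r) > threshold]
        if not live:
            break
        a, b, r = max(live, key=lambda t: abs(t[2]))
        da, db = abs(deltas.get(a, 0.0)), abs(deltas.get(b, 0.0))
        if da < db:
            drop = a
        elif db < da:
            drop = b
        else:
            drop = max(a, b)  # tie: lexicographically later id
        retained.discard(drop)
        excluded.append(drop)
    return ExclusionReport(pairs=tuple(pairs), excluded_ids=tuple(excluded),
                           threshold=threshold)


@dataclass(frozen=True)
class SummaryRow:
    """One interaction's values across conditions.

    ``values`` maps condition label to ``(value, sd)``; the reference
    (binary) condition is included.  Excluded or non-significant rows carry
    ``included=False`` and a short reason, and do not enter the footer.
    """

    interaction_id: str
    values: Mapping[str, tuple]
    included: bool = True
    reason: str = ""

    def delta(self, condition: str, reference: str) -> tuple[float, float]:
        v, s = self.values[condition]
        v0, s0 = self.values[reference]
        return v - v0, math.hypot(s, s0)


@dataclass(frozen=True)
class SummaryTable:
    """ΣPMF summary for one system: rows per interaction, footer per condition.

    ``reference`` is the binary condition; ``conditions`` the ternary
    condition labels (one per glue variant).  Footer sums run over included
    rows only, with quadrature uncertainties.
    """

    system: str
    reference: str
    conditions: tuple
    rows: tuple

    def included_rows(self) -> tuple:
        return tuple(r for r in self.rows if r.included)

    def sigma(self, condition: str) -> tuple[float, float]:
        rows = self.included_rows()
        total = sum(r.values[condition][0] for r in rows)
        sd = math.sqrt(sum(r.values[condition][1] ** 2 for r in rows))
        return total, sd

    def delta_sigma(self, condition: str) -> tuple[float, float]:
        t, ts = self.sigma(condition)
        b, bs = self.sigma(self.reference)
        return t - b, math.hypot(ts, bs)

    def to_dict(self) -> dict:
        out = {"system": self.system, "reference": self.reference,
               "conditions": list(self.conditions), "rows": [], "footer": {}}
        for r in self.rows:
            out["rows"].append({
                "interaction_id": r.interaction_id,
                "values": {c: list(v) for c, v in r.values.items()},
                "included": r.included,
                "reason": r.reason,
            })
        if self.included_rows():
            for c in (self.reference, *self.conditions):
                out["footer"][c] = list(self.sigma(c))
            for c in self.conditions:
                out["footer"][f"delta[{c}]"] = list(self.delta_sigma(c))
        return out


def summary_from_estimates(
    system: str,
    reference: str,
    conditions: Sequence[str],
    estimates: Mapping[tuple, tuple],
    excluded: Mapping[str, str] | None = None,
) -> SummaryTable:
    """Build a SummaryTable from ``(interaction_id, condition) -> (value, sd)``.

    ``excluded`` maps interaction id to a reason string for rows kept in the
    table but left out of the footer sums.
    """
    excluded = dict(excluded or {})
    ids = []
    for (iid, _c) in estimates:
        if iid not in ids:
            ids.append(iid)
    rows = []
    for iid in ids:
        values = {}
        for c in (reference, *conditions):
            if (iid, c) not in estimates:
                raise ValueError(f"missing estimate for ({iid!r}, {c!r})")
            values[c] = tuple(estimates[(iid, c)])
        rows.append(SummaryRow(
            interaction_id=iid, values=values,
            included=iid not in excluded, reason=excluded.get(iid, "")))
    return SummaryTable(system=system, reference=reference,
                        conditions=tuple(conditions), rows=tuple(rows))


def aggregate(
    comparisons: Sequence[InteractionComparison],
    exclusions: ExclusionReport | None = None,
    system: str = "",
) -> SummaryTable:
    """Aggregate screened comparisons into a single-condition summary table.

    Rows failing the significance screen or named by the exclusion report
    remain visible in the table but are dropped from the footer sums.  With
    zero included rows the table renders with an explicit empty-footer
    notice rather than a zero total.
    """
    if not comparisons:
        raise ValueError("comparisons must be nonempty")
    reference = comparisons[0].pmf_binary.condition
    condition = comparisons[0].pmf_ternary.condition
    excluded_ids = set(exclusions.excluded_ids) if exclusions else set()
    rows = []
    for cmp_ in comparisons:
        reason = ""
        if not cmp_.significant:
            reason = f"not significant (p={cmp_.mwu_p:.3g})"
        elif cmp_.interaction_id in excluded_ids:
            reason = "correlated rupture (|r| > threshold)"
        rows.append(SummaryRow(
            interaction_id=cmp_.interaction_id,
            values={
                reference: (cmp_.pmf_binary.value, cmp_.pmf_binary.bootstrap_sd),
                condition: (cmp_.pmf_ternary.value, cmp_.pmf_ternary.bootstrap_sd),
            },
            included=not reason,
            reason=reason,
        ))
    return SummaryTable(system=system, reference=reference,
                        conditions=(condition,), rows=tuple(rows))


def _fmt(value: float, sd: float) -> str:
    return f"{round_half_away(value):.1f} ± {round_half_away(sd):.1f}"


def _fmt_delta(delta: float, sd: float) -> str:
    return f"({'+' if delta >= 0 else '−'}{abs(round_half_away(delta)):.1f} ± {round_half_away(sd):.1f})"


def render_table(table: SummaryTable, fmt: str = "markdown") -> str:
    """Deterministic text rendering, mirroring the published table layout.

    Interactions are rows; the reference condition and each ternary
    condition are columns, with the ternary-minus-reference delta in
    parentheses; the footer row carries ΣPMF_HB_break and its deltas.
    Values are rounded half-away-from-zero to one decimal at this layer
    only.
    """
    if fmt not in {"markdown", "tsv"}:
        raise ValueError(f"unknown format {fmt!r}")
    header = ["interaction", table.reference, *table.conditions]
    body: list[list[str]] = []
    for row in table.rows:
        cells = [row.interaction_id, _fmt(*row.values[table.reference])]
        for c in table.conditions:
            cell = _fmt(*row.values[c]) + " " + _fmt_delta(*row.delta(c, table.reference))
            if not row.included:
                cell += " [excluded: " + row.reason + "]"
            cells.append(cell)
        body.append(cells)
    if table.included_rows():
        footer = ["∑PMF_HB_break", _fmt(*table.sigma(table.reference))]
        for c in table.conditions:
            footer.append(_fmt(*table.sigma(c)) + " "
                          + _fmt_delta(*table.delta_sigma(c)))
    else:
        footer = ["∑PMF_HB_break", "(no interactions retained)"]
        footer += ["" for _ in table.conditions]
    body.append(footer)

    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in body]
        return "\n".join(lines) + "\n"
    widths = [max(len(h), *(len(r[i]) for r in body))
              for i, h in enumerate(header)]
    def mdrow(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    lines = [mdrow(header),
             "|" + "|".join("-" * (w + 2) for w in widths) + "|"]
    lines += [mdrow(r) for r in body]
    title = f"**{table.system}**\n\n" if table.system else ""
    return title + "\n".join(lines) + "\n"
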