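"""Shipped reference tables of published per-interaction rupture free energies.

Three molecular-glue systems are included:

* ``crbn_sall4`` — CRBN–SALL4(ZF2) with the IMiDs pomalidomide,
  lenalidomide and thalidomide;
* ``cbd_sensor`` — the CA14–DB21 dual-nanobody cannabidiol biosensor;
* ``ssbp4_14_3_3`` — 14-3-3σ–SSBP4 with Fusicoccin A.

Each table carries the per-interaction PMF_HB_break values (kcal/mol) with
bootstrap uncertainties for the glue-free and glue-bound conditions, exactly
as published for the interactions retained by the significance and
correlation screens.  Rebuilding the footers from these rows exercises the
aggregation layer end to end: the sums, quadrature uncertainties and
ΔΣPMF_HB_break values must reproduce the published footers after one-decimal
rounding.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .significance import SummaryTable, summary_from_estimates

__all__ = ["REFERENCE_SYSTEMS", "load_reference_values", "load_reference_table"]

REFERENCE_SYSTEMS = ("crbn_sall4", "cbd_sensor", "ssbp4_14_3_3")


def _data_path(name: str):
    if name not in REFERENCE_SYSTEMS:
        raise KeyError(f"unknown reference system {name!r}; "
                       f"expected one of {REFERENCE_SYSTEMS}")
    return resources.files("hbpmf").joinpath("data", "reference_tables",
                                             f"{name}.tsv")


def load_reference_values(name: str) -> tuple[str, pd.DataFrame]:
    """Return ``(reference_condition, frame)`` for a shipped table.

    The frame has columns ``interaction_id, condition, value, sd`` with one
    row per interaction and condition.
    """
    path = _data_path(name)
    reference = None
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# reference_condition:"):
                reference = line.split(":", 1)[1].strip()
    if reference is None:
        raise ValueError(f"{path} lacks a reference_condition header")
    frame = pd.read_csv(path, sep="\t", comment="#")
    return reference, frame


def load_reference_table(name: str) -> SummaryTable:
    """Build the SummaryTable for a shipped system from its per-row values."""
    reference, frame = load_reference_values(name)
    conditions = [c for c in frame["condition"].unique() if c != reference]
    estimates = {
        (row.interaction_id, row.condition): (float(row.value), float(row.sd))
        for row in frame.itertuples()
    }
    return summary_from_estimates(
        system=name, reference=reference, conditions=conditions,
        estimates=estimates)
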