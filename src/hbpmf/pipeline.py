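"""End-to-end pipeline: simulate → estimate → screen → aggregate → render.

Each stage is a thin composition of the library modules; every artifact is
written with the base seed and a hash of the configuration, and a rerun with
the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np

from .config import RunConfig
from .pmf_estimation import estimate_pmf
from .significance import (
    InteractionComparison,
    SummaryTable,
    aggregate,
    correlation_screen,
    mann_whitney_screen,
    render_table,
)
from .synthetic_smd import CorrelationSpec, simulate_correlated_pair, simulate_set
from .work_model import ReplicateSet, write_work_traces

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("hbpmf.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _interaction_seed(base_seed: int, idx: int, condition_idx: int) -> int:
    state = np.random.SeedSequence([base_seed, idx, condition_idx])
    return int(state.generate_state(1)[0] % (2 ** 31))


def _simulate_all(config: RunConfig) -> dict:
    """Simulate every (interaction, condition) replicate set."""
    sets: dict[tuple, ReplicateSet] = {}
    done: set[str] = set()
    specs = {s.id: (i, s) for i, s in enumerate(config.interactions)}
    for cond_idx, condition in enumerate(("binary", "ternary")):
        base_pot = config.potentials[condition]
        for spec_idx, spec in enumerate(config.interactions):
            if (spec.id, condition) in sets:
                continue
            pot = replace(base_pot, **spec.potential_overrides) \
                if spec.potential_overrides else base_pot
            seed = _interaction_seed(config.base_seed, spec_idx, cond_idx)
            if spec.correlated_with is not None:
                partner_idx, partner = specs[spec.correlated_with]
                partner_pot = replace(base_pot, **partner.potential_overrides) \
                    if partner.potential_overrides else base_pot
                set_self, set_partner = simulate_correlated_pair(
                    pot, partner_pot, config.protocol,
                    CorrelationSpec(rho=spec.rho), config.n_replicates,
                    seed, interaction_ids=(spec.id, partner.id),
                    condition=condition)
                sets[(spec.id, condition)] = set_self
                sets[(partner.id, condition)] = set_partner
            else:
                sets[(spec.id, condition)] = simulate_set(
                    pot, config.protocol, config.n_replicates, seed,
                    interaction_id=spec.id, condition=condition)
    return sets


def run_pipeline(config: RunConfig, output_dir,
                 write_traces: bool = False) -> SummaryTable:
    """Run the full analysis for one system configuration.

    Writes, under ``output_dir``: per-interaction PMF estimates and rupture
    records (JSON), the screening comparisons and exclusion report (JSON),
    and the rendered summary table (markdown and TSV).  Returns the
    SummaryTable.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"base_seed": config.base_seed, "config_hash": config.config_hash()}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sets = _simulate_all(config)
        log.info("simulate: %d replicate sets in %.1fs",
                 len(sets), time.perf_counter() - t0)

        stage = "estimate"
        t0 = time.perf_counter()
        estimates, records = {}, {}
        for key, rset in sets.items():
            boot_seed = _interaction_seed(
                config.base_seed,
                zlib.crc32(key[0].encode()) % 100000,
                zlib.crc32(key[1].encode()) % 100000)
            est, recs = estimate_pmf(
                rset, temperature=config.protocol.temperature,
                n_bootstrap=config.n_bootstrap, seed=boot_seed)
            estimates[key] = est
            records[key] = recs
        log.info("estimate: %d PMF estimates in %.1fs",
                 len(estimates), time.perf_counter() - t0)

        stage = "screen"
        comparisons = []
        for spec in config.interactions:
            works_b = [r.rupture_work for r in records[(spec.id, "binary")]]
            works_t = [r.rupture_work for r in records[(spec.id, "ternary")]]
            u, p, _sig = mann_whitney_screen(works_b, works_t, config.alpha)
            comparisons.append(InteractionComparison(
                interaction_id=spec.id,
                pmf_binary=estimates[(spec.id, "binary")],
                pmf_ternary=estimates[(spec.id, "ternary")],
                mwu_u=u, mwu_p=p, alpha=config.alpha))
        exclusions = correlation_screen(
            {spec.id: records[(spec.id, "ternary")]
             for spec in config.interactions},
            threshold=config.correlation_threshold,
            deltas={c.interaction_id: c.delta for c in comparisons})

        stage = "aggregate"
        table = aggregate(comparisons, exclusions, system=config.system)

        stage = "write"
        (out / "estimates.json").write_text(json.dumps(
            {**meta, "estimates": [e.to_dict() for e in estimates.values()]},
            indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        (out / "comparisons.json").write_text(json.dumps(
            {**meta,
             "comparisons": [c.to_dict() for c in comparisons],
             "exclusions": {
                 "pairs": [list(p) for p in exclusions.pairs],
                 "excluded_ids": list(exclusions.excluded_ids),
                 "threshold": exclusions.threshold,
             }},
            indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        (out / "summary.json").write_text(json.dumps(
            {**meta, "table": table.to_dict()}, indent=2, ensure_ascii=False)
            + "\n", encoding="utf-8")
        (out / "summary.md").write_text(
            render_table(table, "markdown"), encoding="utf-8")
        (out / "summary.tsv").write_text(
            render_table(table, "tsv"), encoding="utf-8")
        if write_traces:
            traces_dir = out / "work_traces"
            traces_dir.mkdir(exist_ok=True)
            for (iid, cond), rset in sets.items():
                write_work_traces(rset, traces_dir / f"{iid}.{cond}.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return table
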