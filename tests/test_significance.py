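"""Mann–Whitney screening, correlation exclusion, and table aggregation."""

import itertools

import numpy as np
import pytest

from hbpmf import (
    PMFEstimate,
    aggregate,
    correlation_screen,
    load_reference_table,
    load_reference_values,
    mann_whitney_screen,
    render_table,
    summary_from_estimates,
)
from hbpmf.significance import (
    ExclusionReport,
    InteractionComparison,
    round_half_away,
)


def est(value, sd, interaction="x", condition="binary"):
    return PMFEstimate(interaction_id=interaction, condition=condition,
                       value=value, bootstrap_sd=sd, n_replicates=25,
                       n_bootstrap=50, temperature=298.0)


def comparison(interaction, vb, sb, vt, st_, p):
    return InteractionComparison(
        interaction_id=interaction,
        pmf_binary=est(vb, sb, interaction, "binary"),
        pmf_ternary=est(vt, st_, interaction, "ternary"),
        mwu_u=0.0, mwu_p=p)


def exact_two_sided_p(a, b):
    """Enumeration oracle: exact two-sided MWU p-value for tiny samples."""
    pooled = list(a) + list(b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) \
        + 0.5 * sum(1 for x in a for y in b if x == y)
    mean_u = n_a * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in grp for y in rest if x > y) \
            + 0.5 * sum(1 for x in grp for y in rest if x == y)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        u, p, sig = mann_whitney_screen([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        assert not sig

    def test_fully_separated_tiny_samples_exact(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        u, p, sig = mann_whitney_screen(a, b)
        assert u == 0.0  # U of the first sample: no a exceeds any b
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(exact_two_sided_p(a, b), abs=1e-12)
        assert not sig

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            a = list(rng.normal(0, 1, 4).round(2))
            b = list(rng.normal(0.8, 1, 5).round(2))
            if len(set(a + b)) < 9:
                continue  # exact method only without ties
            _, p, _ = mann_whitney_screen(a, b)
            assert p == pytest.approx(exact_two_sided_p(a, b), abs=1e-9)

    def test_all_tied_degenerate(self):
        u, p, sig = mann_whitney_screen([2.0] * 5, [2.0] * 7)
        assert p == 1.0
        assert not sig

    def test_large_shift_always_detected(self):
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(50):
            a = rng.normal(0.0, 1.0, 25)
            b = rng.normal(3.0, 1.0, 25)  # 3σ shift
            hits += mann_whitney_screen(a, b)[2]
        assert hits == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_screen([], [1.0])


class TestCorrelationScreen:
    def test_identical_vectors_one_exclusion(self):
        v = [3.9, 4.1, 4.0, 4.3, 3.8]
        report = correlation_screen({"a": v, "b": list(v)},
                                    deltas={"a": 2.0, "b": 1.0})
        assert report.pairs[0][2] == pytest.approx(1.0)
        assert report.excluded_ids == ("b",)  # smaller |delta| dropped

    def test_tie_drops_lexicographically_later(self):
        v = [3.9, 4.1, 4.0, 4.3, 3.8]
        report = correlation_screen({"beta": v, "alpha": list(v)})
        assert report.excluded_ids == ("beta",)

    def test_three_way_cascade_excludes_two(self):
        rng = np.random.default_rng(5)
        base = rng.normal(4.0, 0.3, 25)
        records = {name: base + rng.normal(0, 0.05, 25)
                   for name in ("a", "b", "c")}
        report = correlation_screen(
            records, deltas={"a": 3.0, "b": 2.0, "c": 1.0})
        assert len(report.excluded_ids) == 2
        assert "a" not in report.excluded_ids  # largest |delta| retained

    def test_never_excludes_both_members(self):
        rng = np.random.default_rng(9)
        records = {f"i{k}": rng.normal(4, 0.3, 25) for k in range(4)}
        base = rng.normal(4, 0.3, 25)
        records["j0"] = base + rng.normal(0, 0.02, 25)
        records["j1"] = base + rng.normal(0, 0.02, 25)
        report = correlation_screen(records)
        for a, b, r in report.pairs:
            if abs(r) > report.threshold:
                assert not (a in report.excluded_ids and b in report.excluded_ids)

    def test_zero_variance_pair_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            report = correlation_screen({"a": [4.0] * 5,
                                         "b": [3.9, 4.1, 4.0, 4.2, 3.8]})
        assert report.pairs == ()
        assert report.excluded_ids == ()

    def test_mismatched_replicates_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            correlation_screen({"a": [1, 2, 3], "b": [1, 2]})

    def test_exclusion_report_validates_membership(self):
        with pytest.raises(ValueError):
            ExclusionReport(pairs=(("a", "b", 0.2),), excluded_ids=("a",))


class TestAggregation:
    def test_sum_matches_published_binary_footer(self):
        comparisons = [
            comparison("w400", 1.3, 0.2, 7.0, 0.3, 0.001),
            comparison("h357", 2.7, 0.3, 6.3, 0.3, 0.001),
            comparison("n351", 3.2, 0.3, 9.0, 0.1, 0.001),
        ]
        table = aggregate(comparisons)
        total, sd = table.sigma("binary")
        assert round_half_away(total) == 7.2
        assert round_half_away(sd) == 0.5
        t_total, t_sd = table.sigma("ternary")
        assert round_half_away(t_total) == 22.3
        assert round_half_away(t_sd) == 0.4
        d, ds = table.delta_sigma("ternary")
        assert round_half_away(d) == 15.1
        assert round_half_away(ds) == 0.6

    def test_non_significant_rows_stay_out_of_footer(self):
        comparisons = [
            comparison("strong", 2.0, 0.2, 5.0, 0.2, 0.001),
            comparison("weak", 1.0, 0.2, 1.1, 0.2, 0.8),
        ]
        table = aggregate(comparisons)
        assert [r.interaction_id for r in table.included_rows()] == ["strong"]
        assert table.sigma("binary")[0] == pytest.approx(2.0)

    def test_single_interaction_identical_conditions(self):
        table = aggregate([comparison("only", 2.5, 0.2, 2.5, 0.2, 0.01)])
        d, _ = table.delta_sigma("ternary")
        assert d == pytest.approx(0.0)

    def test_zero_included_renders_notice(self):
        table = aggregate([comparison("weak", 1.0, 0.2, 1.1, 0.2, 0.9)])
        text = render_table(table)
        assert "no interactions retained" in text


class TestRendering:
    def test_reference_markdown_contains_published_footer(self):
        text = render_table(load_reference_table("crbn_sall4"))
        assert "∑PMF_HB_break" in text
        assert "7.2 ± 0.5" in text
        assert "22.3 ± 0.4" in text
        assert "+15.1 ± 0.6" in text

    def test_deterministic_bytes(self):
        table = load_reference_table("cbd_sensor")
        assert render_table(table) == render_table(table)
        assert render_table(table, "tsv") == render_table(table, "tsv")

    def test_unknown_format(self):
        with pytest.raises(ValueError):
            render_table(load_reference_table("cbd_sensor"), "html")


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (2.45, 2.5), (-2.45, -2.5), (0.05, 0.1), (-0.05, -0.1),
        (1.04, 1.0), (1.25, 1.3),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestReferenceTables:
    def test_loader_round_trips_values(self):
        reference, frame = load_reference_values("ssbp4_14_3_3")
        assert reference == "14-3-3s-SSBP4"
        assert len(frame) == 8
        assert set(frame.columns) == {"interaction_id", "condition", "value", "sd"}

    def test_summary_from_estimates_missing_condition(self):
        with pytest.raises(ValueError, match="missing estimate"):
            summary_from_estimates(
                "s", "binary", ["ternary"],
                {("a", "binary"): (1.0, 0.1)})

    def test_unknown_system(self):
        with pytest.raises(KeyError):
            load_reference_table("nope")
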