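"""Jarzynski estimator, rupture rule, profiles, and bootstrap errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbpmf import (
    KB_KCAL_MOL_K,
    ReplicateSet,
    bootstrap_sd,
    estimate_pmf,
    jarzynski_estimate,
    pmf_profile,
    rupture_work,
    sample_gaussian_works,
)

from conftest import make_trace

KBT298 = KB_KCAL_MOL_K * 298.0


def brute_force_rupture(work):
    """Independent oracle: max over all indices at/after the global minimum."""
    work = list(work)
    i_min = work.index(min(work))
    tail = work[i_min:]
    j = i_min + tail.index(max(tail))
    return work[j], j


class TestRuptureRule:
    @pytest.mark.parametrize("work,expected_w,expected_idx", [
        ([0.0, 1.0, 2.0, 3.0], 3.0, 3),      # monotone: min at 0, max at end
        ([0.0, -1.0, 4.0, 3.0], 4.0, 2),     # min at 1, max after it
        ([0.0, 2.0, -1.0, 1.0], 1.0, 3),     # early peak ignored: min at 2
    ])
    def test_hand_cases(self, work, expected_w, expected_idx):
        trace = make_trace(work)
        rec = rupture_work(trace)
        assert rec.rupture_work == pytest.approx(expected_w)
        assert rec.rupture_distance == pytest.approx(trace.cv_value[expected_idx])
        assert rec.rupture_time == pytest.approx(trace.time[expected_idx])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force(self, tail):
        work = [0.0] + tail
        expected_w, _ = brute_force_rupture(work)
        assert rupture_work(make_trace(work)).rupture_work == pytest.approx(expected_w)

    def test_all_nan_rejected(self):
        trace = make_trace([0.0, 1.0, 2.0])
        bad = make_trace([0.0, 1.0, 2.0])
        object.__setattr__(bad, "work", np.array([np.nan] * 3))
        with pytest.raises(ValueError):
            rupture_work(bad)


class TestJarzynskiEstimate:
    def test_constant_works_identity(self):
        assert jarzynski_estimate([2.7] * 25, 298.0) == pytest.approx(2.7, abs=1e-12)
        assert jarzynski_estimate([0.0, 0.0], 77.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_value_hand_case(self):
        # direct two-term evaluation at 298 K
        expected = -KBT298 * math.log(
            (math.exp(-1.0 / KBT298) + math.exp(-3.0 / KBT298)) / 2.0)
        got = jarzynski_estimate([1.0, 3.0], 298.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.39, abs=5e-3)

    def test_gaussian_closed_form(self):
        works = sample_gaussian_works(5.0, 1.0, 10 ** 5, seed=123)
        expected = 5.0 - 1.0 / (2.0 * KBT298)
        assert jarzynski_estimate(works, 298.0) == pytest.approx(expected, abs=0.05)

    def test_low_temperature_limit_is_min(self):
        works = [1.0, 3.0, 0.4, 2.2]
        assert jarzynski_estimate(works, 1e-6) == pytest.approx(0.4, abs=1e-6)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=40),
           st.floats(-10, 10))
    @settings(derandomize=True, max_examples=200)
    def test_shift_covariance_and_jensen(self, works, c):
        base = jarzynski_estimate(works, 298.0)
        shifted = jarzynski_estimate([w + c for w in works], 298.0)
        assert shifted == pytest.approx(base + c, abs=1e-9)
        assert base <= np.mean(works) + 1e-9

    @given(st.lists(st.floats(-20, 20), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_logsumexp_matches_naive_sum(self, works):
        naive = -KBT298 * math.log(
            sum(math.exp(-w / KBT298) for w in works) / len(works))
        assert jarzynski_estimate(works, 298.0) == pytest.approx(naive, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_estimate([], 298.0)


class TestBootstrap:
    def test_all_equal_gives_zero(self):
        assert bootstrap_sd([3.3] * 10, 298.0, seed=1) == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        works = sample_gaussian_works(4.0, 0.8, 25, seed=5)
        a = bootstrap_sd(works, 298.0, seed=99)
        b = bootstrap_sd(works, 298.0, seed=99)
        assert a == b
        assert a > 0

    def test_gaussian_sd_near_delta_method(self):
        """Bootstrap sd within a factor 2 of the analytic delta-method sd.

        For Gaussian work, exp(-W/kBT) is lognormal and the delta method
        gives sd(ĜN) ≈ kBT sqrt((exp(σ²/kBT²) − 1)/N).
        """
        sigma, n = 1.0, 25
        beta = 1.0 / KBT298
        delta_sd = KBT298 * math.sqrt((math.exp(sigma ** 2 * beta ** 2) - 1) / n)
        sds = [bootstrap_sd(sample_gaussian_works(5.0, sigma, n, seed=s),
                            298.0, n_bootstrap=50, seed=s + 1)
               for s in range(10)]
        ratio = np.mean(sds) / delta_sd
        assert 0.5 < ratio < 2.0

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            bootstrap_sd([1.0], 298.0)


class TestProfiles:
    def test_identical_traces_reproduce_work_profile(self):
        trace = make_trace([0.0, -0.5, 2.0, 3.5, 3.0])
        rset = ReplicateSet("x", "binary", [trace] * 5)
        prof = pmf_profile(rset, 298.0, seed=3)
        np.testing.assert_allclose(prof.pmf, trace.work, atol=1e-12)
        np.testing.assert_allclose(prof.bootstrap_sd, 0.0, atol=1e-12)

    def test_final_point_equals_jarzynski_of_final_works(self):
        traces = [make_trace([0.0, 0.5, w]) for w in (1.0, 2.0, 4.0)]
        rset = ReplicateSet("x", "binary", traces)
        prof = pmf_profile(rset, 298.0)
        assert prof.pmf[-1] == pytest.approx(
            jarzynski_estimate([1.0, 2.0, 4.0], 298.0), abs=1e-12)

    def test_two_replicate_hand_profile(self):
        # hand-computed three-point profile from two replicates
        w1, w2 = [0.0, 1.0, 3.0], [0.0, 2.0, 2.0]
        rset = ReplicateSet("x", "binary",
                            [make_trace(w1), make_trace(w2)])
        prof = pmf_profile(rset, 298.0)
        expected = [jarzynski_estimate([a, b], 298.0) for a, b in zip(w1, w2)]
        np.testing.assert_allclose(prof.pmf, expected, atol=1e-12)

    def test_estimate_pmf_jensen_and_fields(self, binary_set):
        est, records = estimate_pmf(binary_set, seed=11)
        works = [r.rupture_work for r in records]
        assert est.value <= np.mean(works) + 1e-9
        assert est.n_replicates == 25
        assert est.n_bootstrap == 50
        assert est.bootstrap_sd > 0
        assert len(records) == 25
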