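"""Agreement statistics: CCC, empirical/parametric TDI, coverage, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gfragree.agreement import (
    agreement_statistics,
    bootstrap_bound,
    ccc,
    coverage_probability,
    coverage_probability_parametric,
    percent_differences,
    tdi_empirical,
    tdi_parametric,
)


class TestPercentDifferences:
    def test_hand_values(self):
        d = percent_differences([50, 100], [55, 90])
        assert d.d == pytest.approx([10.0, -10.0])

    def test_equal_series_all_zero(self):
        d = percent_differences([60, 70], [60, 70])
        assert np.all(d.d == 0)

    def test_forty_percent_error(self):
        assert percent_differences([60], [84]).d == pytest.approx([40.0])

    def test_log_scale(self):
        d = percent_differences([60], [84], scale="log")
        assert d.d == pytest.approx([100 * np.log(84 / 60)])

    def test_nonpositive_mgfr_rejected(self):
        with pytest.raises(ValueError):
            percent_differences([0.0, 60], [50, 60])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_differences([60], [50, 60])


class TestCcc:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ccc(x, x) == pytest.approx(1.0)

    def test_worked_four_point_example(self):
        # 2*1.25 / (1.25 + 1.25 + 1) with divisor-n moments
        assert ccc([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.7143, abs=5e-5)

    def test_perfect_reversal_is_minus_one(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        assert ccc(x, -x) == pytest.approx(-1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            ccc([3.0, 3.0], [3.0, 3.0])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_bounded_by_pearson(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=30)
        y = 0.5 * x + r.normal(size=30)
        assert abs(ccc(x, y)) <= abs(stats.pearsonr(x, y)[0]) + 1e-12

    def test_scale_invariance_but_not_shift(self):
        r = np.random.default_rng(5)
        x, y = r.normal(50, 10, 40), r.normal(50, 10, 40)
        assert ccc(3.7 * x, 3.7 * y) == pytest.approx(ccc(x, y), rel=1e-10)
        assert ccc(x + 25.0, y) != pytest.approx(ccc(x, y), rel=1e-3)


class TestTdiEmpirical:
    def test_all_zero(self):
        assert tdi_empirical(np.zeros(10)) == 0.0

    def test_order_statistic_convention(self):
        # ceil(0.9*10) = 9th smallest of |d| = 1..10
        assert tdi_empirical(np.arange(1.0, 11.0), p=0.9) == 9.0

    def test_large_normal_sample_matches_closed_form(self):
        r = np.random.default_rng(7)
        d = r.normal(0, 10, 100_000)
        assert tdi_empirical(d, 0.9) == pytest.approx(16.449, rel=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tdi_empirical([])

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000), st.integers(5, 60))
    def test_nondecreasing_in_p(self, seed, n):
        d = np.random.default_rng(seed).normal(0, 5, n)
        tdis = [tdi_empirical(d, p) for p in (0.5, 0.7, 0.9, 0.95)]
        assert tdis == sorted(tdis)


class TestTdiParametric:
    @pytest.mark.parametrize(
        "mean,sd,p,expected",
        [(0, 10, 0.90, 16.449), (0, 10, 0.50, 6.745)],
    )
    def test_zero_mean_reduces_to_normal_quantile(self, mean, sd, p, expected):
        assert tdi_parametric(mean, sd, p) == pytest.approx(expected, abs=5e-4)

    def test_sd_zero_limit_is_abs_mean(self):
        assert tdi_parametric(-3.0, 0.0, 0.9) == 3.0

    def test_agrees_with_empirical_on_large_normal(self):
        r = np.random.default_rng(11)
        d = r.normal(2.0, 8.0, 10_000)
        emp = tdi_empirical(d, 0.9)
        par = tdi_parametric(float(d.mean()), float(d.std()), 0.9)
        assert emp == pytest.approx(par, rel=0.02)


class TestCoverage:
    def test_all_within(self):
        assert coverage_probability(np.zeros(5), 10.0) == 1.0

    def test_half_within(self):
        assert coverage_probability([5.0, 15.0], 10.0) == 0.5

    def test_parametric_normal_identity(self):
        assert coverage_probability_parametric(0, 10, 16.449) == pytest.approx(0.90, abs=1e-3)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_duality_with_empirical_tdi(self, seed):
        """coverage at the empirical TDI(p) is >= p, with equality when p*n
        is an integer (continuous data, no ties)."""
        r = np.random.default_rng(seed)
        n = 10 * r.integers(1, 12)
        d = r.normal(0, 10, n)
        kappa = tdi_empirical(d, 0.9)
        cov = coverage_probability(d, kappa)
        assert cov >= 0.9
        assert cov == pytest.approx(0.9, abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 10_000))
    def test_nondecreasing_in_kappa(self, seed):
        d = np.random.default_rng(seed).normal(0, 10, 37)
        covs = [coverage_probability(d, k) for k in (5, 10, 20, 40)]
        assert covs == sorted(covs)


class TestBootstrap:
    def test_determinism(self, rng):
        pairs = rng.normal(60, 20, size=(50, 2))

        def stat(pr):
            return ccc(pr[:, 0], pr[:, 1])

        a = bootstrap_bound(stat, pairs, B=200, seed=99)
        b = bootstrap_bound(stat, pairs, B=200, seed=99)
        assert a == b

    def test_degenerate_data_bound_equals_estimate(self):
        d = np.full(20, 7.5)
        est, bound = bootstrap_bound(lambda x: float(np.mean(np.abs(x))), d, B=150, seed=1,
                                     side="upper")
        assert est == bound == 7.5

    def test_requires_seed_and_minimum_n(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_bound(np.mean, np.ones(10), B=100, seed=None)
        with pytest.raises(ValueError, match="n = 3"):
            bootstrap_bound(np.mean, np.ones(3), B=100, seed=1)

    def test_matches_explicit_loop_oracle(self):
        """Percentile bound on a fixed 50-pair fixture equals a second,
        independently-written resampling loop bit-for-bit."""
        r = np.random.default_rng(314)
        pairs = np.column_stack([r.uniform(20, 110, 50), r.uniform(20, 110, 50)])

        def stat(pr):
            return ccc(pr[:, 0], pr[:, 1])

        est, bound = bootstrap_bound(stat, pairs, B=400, seed=2718, side="lower")

        # oracle: same generator contract, separate implementation
        rng2 = np.random.default_rng(2718)
        vals = []
        for _ in range(400):
            idx = rng2.integers(0, 50, size=50)
            sub = pairs[idx]
            vals.append(ccc(sub[:, 0], sub[:, 1]))
        assert est == pytest.approx(ccc(pairs[:, 0], pairs[:, 1]), abs=1e-15)
        assert bound == pytest.approx(float(np.quantile(vals, 0.05)), abs=1e-12)


class TestAgreementStatistics:
    def test_perfect_agreement(self, rng):
        m = rng.uniform(20, 110, 40)
        res = agreement_statistics(m, m.copy(), B=150, seed=4)
        assert res.ccc == pytest.approx(1.0)
        assert res.tdi == pytest.approx(0.0, abs=1e-9)
        assert res.cp == pytest.approx(100.0)

    def test_bound_directions(self, rng):
        m = rng.uniform(20, 110, 60)
        e = m * np.exp(rng.normal(0, 0.2, 60))
        res = agreement_statistics(m, e, B=300, seed=8)
        assert res.ccc_bound <= res.ccc
        assert res.tdi_bound >= res.tdi
        assert res.cp_bound <= res.cp
        assert 0 <= res.cp <= 100
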