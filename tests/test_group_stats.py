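"""Automatic test selection, Box-Cox gating, partial correlations, corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynconn.group_stats import (
    bh_fdr,
    bonferroni_fwe,
    boxcox_if_nonnormal,
    choose_and_run_test,
    dap_bonferroni,
    partial_correlation,
    summary_stat_tests,
)


class TestChooseAndRunTest:
    def test_sex_contingency_chi_square(self):
        # 96 EP (58 M / 38 F) vs 56 HC (37 M / 19 F)
        res = choose_and_run_test(table=[[58, 38], [37, 19]])
        assert res.test == "chi2"
        assert res.statistic == pytest.approx(0.483, abs=0.005)
        assert res.df == 1

    def test_identical_samples_give_zero_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, 40)
        res = choose_and_run_test(x, x.copy())
        assert res.test in ("student-t", "welch-t")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1.2, 60)
        y = rng.lognormal(0.5, 1.2, 60)
        res = choose_and_run_test(x, y)
        assert res.test == "mannwhitney"
        assert min(res.detail["shapiro_p"]) < 0.05

    def test_unequal_variances_route_to_welch(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1.0, 80)
        y = rng.normal(0, 4.0, 80)
        res = choose_and_run_test(x, y)
        assert res.test == "welch-t"
        assert res.detail["levene_p"] < 0.05

    def test_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            choose_and_run_test(np.ones(10), np.ones(10))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_nulls = 500
        for _ in range(n_nulls):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0, 1, 15)
            rejections += choose_and_run_test(x, y).p_value < 0.05
        rate = rejections / n_nulls
        assert 0.02 <= rate <= 0.08  # binomial band around 0.05


class TestSummaryStats:
    def test_welch_from_printed_summaries(self):
        # right-striatum connectivity summaries: printed value 5.11 reflects
        # unrounded data; recomputation from rounded summaries gives ~5.13
        res = summary_stat_tests(5.78, 0.96, 96, 5.09, 0.69, 56, flavor="welch")
        assert res.test == "welch-t"
        assert res.statistic == pytest.approx(5.11, rel=0.02)

    def test_student_from_printed_summaries(self):
        res = summary_stat_tests(3.48, 0.67, 96, 4.05, 0.67, 56, flavor="student")
        assert res.statistic == pytest.approx(-5.03, rel=0.02)
        assert res.direction == -1

    def test_equal_means_zero_t(self):
        res = summary_stat_tests(5.0, 1.0, 30, 5.0, 2.0, 40, flavor="welch")
        assert res.statistic == 0.0

    def test_doubling_n_scales_t_by_sqrt2(self):
        t1 = summary_stat_tests(1.0, 1.0, 20, 0.5, 1.0, 20).statistic
        t2 = summary_stat_tests(1.0, 1.0, 40, 0.5, 1.0, 40).statistic
        assert t2 == pytest.approx(np.sqrt(2) * t1)


class TestBoxCox:
    def test_normal_data_left_alone(self):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 5, 100)
        res = boxcox_if_nonnormal(x)
        assert res.lmbda is None
        assert np.array_equal(res.values, x)

    def test_lognormal_normalized(self):
        successes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(0, 1, 200)
            res = boxcox_if_nonnormal(x)
            assert res.lmbda is not None
            assert abs(res.lmbda) < 0.5  # log is the right transform family
            successes += res.shapiro_after > 0.05
        assert successes >= 9

    def test_nonpositive_values_shifted(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, 100) - 5.0
        res = boxcox_if_nonnormal(x)
        assert res.shift == pytest.approx(1.0 - x.min())
        assert np.isfinite(res.values).all()

    def test_transform_monotone(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 1.5, 150)
        res = boxcox_if_nonnormal(x)
        order = np.argsort(x)
        assert (np.diff(res.values[order]) >= 0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            boxcox_if_nonnormal(np.full(20, 3.0))


class TestPartialCorrelation:
    def test_orthogonal_nuisance_equals_plain_correlation(self):
        rng = np.random.default_rng(7)
        n = 200
        x = rng.standard_normal(n)
        y = 0.4 * x + rng.standard_normal(n)
        nuis = rng.standard_normal(n)
        span = np.column_stack([np.ones(n), x, y])  # orthogonalize jointly
        nuis -= span @ np.linalg.lstsq(span, nuis, rcond=None)[0]
        res = partial_correlation(x, y, nuis)
        assert res.statistic == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_collinear_outcome_flagged(self):
        rng = np.random.default_rng(8)
        nuis = rng.standard_normal(100)
        x = rng.standard_normal(100)
        with pytest.warns(UserWarning, match="collinear"):
            res = partial_correlation(x, nuis.copy(), nuis)
        assert res.statistic == 0.0 and res.detail["collinear"]

    def test_planted_negative_effect_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 96
            nuis = rng.standard_normal(n)
            x = rng.standard_normal(n)
            y = -0.5 * x + nuis + rng.standard_normal(n)
            res = partial_correlation(x, y, nuis)
            hits += res.statistic < 0
        assert hits >= 19  # >= 95% of seeds

    def test_spearman_flavor_rank_invariance(self):
        rng = np.random.default_rng(9)
        n = 80
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        nuis = rng.standard_normal(n)
        r1 = partial_correlation(x, y, nuis, flavor="spearman").statistic
        r2 = partial_correlation(np.exp(x), y, nuis, flavor="spearman").statistic
        assert r1 == pytest.approx(r2, abs=1e-12)  # monotone map of x changes nothing


class TestDapBonferroni:
    def test_perfectly_correlated_endpoints_identity(self):
        p = np.array([0.01, 0.04, 0.2])
        corr = np.ones((3, 3))
        assert np.allclose(dap_bonferroni(p, corr), p, atol=1e-12)

    def test_independent_endpoints_sidak(self):
        p = np.array([0.05] * 4)
        out = dap_bonferroni(p, np.eye(4))
        assert out[0] == pytest.approx(1 - 0.95**4, abs=1e-12)
        assert out[0] == pytest.approx(0.1855, abs=1e-4)

    def test_half_correlation_closed_form(self):
        m = 4
        corr = np.full((m, m), 0.5)
        np.fill_diagonal(corr, 1.0)
        out = dap_bonferroni(np.array([0.05] * m), corr)
        # m_eff = 4^(1-0.5) = 2 -> 1 - 0.95^2 = 0.0975
        assert out[0] == pytest.approx(0.0975, abs=1e-12)

    def test_single_endpoint_identity(self):
        assert dap_bonferroni([0.03], np.eye(1))[0] == 0.03

    @given(
        st.integers(2, 8),
        st.floats(0.0, 1.0),
        st.integers(0, 2**31 - 1),
    )
    @settings(deadline=None, max_examples=60)
    def test_bounded_between_raw_and_sidak(self, m, pval, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, (m, m))
        corr = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(corr, 1.0)
        p = np.full(m, pval)
        out = dap_bonferroni(p, corr)
        sidak = 1 - (1 - pval) ** m
        assert (out >= p - 1e-12).all()
        assert (out <= sidak + 1e-12).all()


class TestBhAndBonferroni:
    def test_step_up_rejects_all_when_all_below_line(self):
        padj, reject = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        padj, reject = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.allclose(padj, 1.0)

    def test_single_p_unchanged(self):
        padj, _ = bh_fdr([0.03])
        assert padj[0] == pytest.approx(0.03)

    def test_bonferroni_closed_form(self):
        out = bonferroni_fwe([0.004] * 10)
        assert out[0] == pytest.approx(0.04)
        assert bonferroni_fwe([0.2])[0] == pytest.approx(0.2)
        p = np.linspace(0, 0.3, 7)
        assert (bonferroni_fwe(p) >= p).all()
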