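"""Repeated-measures inference and intraclass-correlation estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

import funcgrad as fg
from funcgrad.reliability import format_threshold, icc_simulation_study


def sums_of_squares_icc_oracle(y):
    """Brute-force one-way random-effects mean squares, written with explicit
    loops, independent of the implementation under test."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.sum() / (n * k)
    bms = 0.0
    for i in range(n):
        mi = y[i].sum() / k
        bms += k * (mi - grand) ** 2
    bms /= n - 1
    ems = 0.0
    for i in range(n):
        mi = y[i].sum() / k
        for j in range(k):
            ems += (y[i, j] - mi) ** 2
    ems /= n * (k - 1)
    return bms, ems, (bms - ems) / (bms + (k - 1) * ems)


class TestRmAnova:
    def test_identical_conditions_give_zero_f(self):
        x = np.arange(10.0)
        res = fg.rm_anova_two_condition(x, x)
        assert res.f == 0.0
        assert res.p == 1.0

    def test_f_equals_squared_paired_t(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        res = fg.rm_anova_two_condition(a, b)
        t = stats.ttest_rel(a, b)
        assert res.f == pytest.approx(t.statistic**2, abs=1e-10)
        assert res.p == pytest.approx(t.pvalue, abs=1e-10)
        assert (res.df1, res.df2) == (1, 29)

    def test_covariate_consumes_one_degree_of_freedom(self, rng):
        n = 145
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        cov = rng.normal(size=n)
        res = fg.rm_anova_two_condition(a, b, covariate=cov)
        assert (res.df1, res.df2) == (1, 143)
        assert res.covariate_adjusted

    def test_covariate_equals_ancova_on_differences(self, rng):
        # cross-check against an explicit OLS fit of d ~ 1 + centred covariate
        n = 40
        a, b, cov = rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        res = fg.rm_anova_two_condition(a, b, covariate=cov)
        d = a - b
        x = np.column_stack([np.ones(n), cov - cov.mean()])
        beta, res_ss = np.linalg.lstsq(x, d, rcond=None)[:2]
        s2 = res_ss[0] / (n - 2)
        var_int = s2 * np.linalg.inv(x.T @ x)[0, 0]
        assert res.f == pytest.approx(beta[0] ** 2 / var_int, rel=1e-10)

    def test_constant_nonzero_difference_reports_infinite_f(self):
        a = np.arange(5.0)
        with pytest.warns(UserWarning, match="zero variance"):
            res = fg.rm_anova_two_condition(a + 1.0, a)
        assert res.f == np.inf
        assert res.p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fg.rm_anova_two_condition(np.zeros(5), np.zeros(6))


class TestBonferroni:
    def test_single_comparison_keeps_alpha(self):
        assert fg.bonferroni_threshold(0.05, 1) == 0.05

    def test_fourteen_comparisons_display(self):
        thr = fg.bonferroni_threshold(0.05, 14)
        assert thr == pytest.approx(0.05 / 14)
        assert format_threshold(thr) == ".0036"

    def test_strictly_decreasing_in_m(self):
        values = [fg.bonferroni_threshold(0.05, m) for m in range(1, 20)]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_threshold_times_m_recovers_alpha(self):
        for m in (1, 7, 14, 100):
            assert fg.bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)


class TestAnovaIcc:
    def test_identical_sessions_give_one(self):
        y = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert fg.anova_icc(y).icc == pytest.approx(1.0)

    def test_perfect_subject_separation(self):
        y = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        res = fg.anova_icc(y)
        assert res.ems == 0.0
        assert res.icc == 1.0

    def test_matches_sums_of_squares_oracle(self, rng):
        y = np.array([[1.0, 1.2], [2.0, 1.7], [3.0, 3.4]])
        res = fg.anova_icc(y)
        bms, ems, icc = sums_of_squares_icc_oracle(y)
        assert res.bms == pytest.approx(bms, abs=1e-12)
        assert res.ems == pytest.approx(ems, abs=1e-12)
        assert res.icc == pytest.approx(icc, abs=1e-12)

    def test_monte_carlo_half_reliability(self, rng):
        # sigma_b = sigma_e, K = 2 -> ICC = 0.5
        n = 5000
        b = rng.normal(size=(n, 1))
        y = b + rng.normal(size=(n, 2))
        assert abs(fg.anova_icc(y).icc - 0.5) < 0.03

    def test_missing_cells_rejected(self):
        y = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError, match="complete balanced"):
            fg.anova_icc(y)

    def test_scale_and_shift_invariance(self, rng):
        y = rng.normal(size=(20, 3))
        a = fg.anova_icc(y).icc
        b = fg.anova_icc(4.2 * y + 11.0).icc
        assert a == pytest.approx(b, abs=1e-10)


class TestRemlIcc:
    def test_identical_sessions_give_one(self):
        y = np.column_stack([np.arange(4.0), np.arange(4.0)])
        assert fg.reml_icc(y).icc == pytest.approx(1.0)

    def test_equals_anova_when_bms_exceeds_ems(self, rng):
        for _ in range(20):
            b = rng.normal(size=(15, 1)) * 2.0
            y = b + rng.normal(size=(15, 2))
            res_a = fg.anova_icc(y)
            if res_a.bms >= res_a.ems:
                assert fg.reml_icc(y).icc == pytest.approx(res_a.icc, abs=1e-12)

    def test_truncates_negative_anova_icc_to_zero(self):
        # anti-correlated sessions: BMS < EMS
        y = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0], [-1.5, 1.5]])
        res_a = fg.anova_icc(y)
        res_r = fg.reml_icc(y)
        assert res_a.icc < 0
        assert res_r.icc == 0.0
        assert res_r.sigma2_between == 0.0

    def test_variance_components_sum_to_total(self, rng):
        y = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1))
        res = fg.reml_icc(y)
        assert res.icc == pytest.approx(
            res.sigma2_between / (res.sigma2_between + res.sigma2_error)
        )


class TestCompareIccSets:
    def test_identical_sets_give_zero_f(self):
        x = np.linspace(0.1, 0.4, 7)
        assert fg.compare_icc_sets(x, x).f == 0.0

    def test_seven_networks_give_df_1_6(self, rng):
        res = fg.compare_icc_sets(rng.uniform(0, 0.5, 7), rng.uniform(0, 0.5, 7))
        assert (res.df1, res.df2) == (1, 6)

    def test_equals_squared_paired_t(self, rng):
        a, b = rng.uniform(0, 0.5, 7), rng.uniform(0, 0.5, 7)
        res = fg.compare_icc_sets(a, b)
        assert res.f == pytest.approx(stats.ttest_rel(a, b).statistic ** 2, abs=1e-10)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    y=hnp.arrays(
        float,
        shape=st.tuples(st.integers(3, 12), st.integers(2, 4)),
        elements=st.floats(-100, 100, allow_nan=False),
    ),
    scale=st.floats(0.01, 50),
    shift=st.floats(-100, 100),
)
def test_icc_invariant_to_affine_measurement_rescaling(y, scale, shift):
    """Both ICC estimators ignore the measurement units and origin."""
    bms, ems, _, _ = fg.reliability._mean_squares(y)
    if bms + ems < 1e-8:  # fully degenerate table: ICC undefined either way
        return
    a = fg.anova_icc(y).icc
    b = fg.anova_icc(scale * y + shift).icc
    assert a == pytest.approx(b, abs=1e-8)
    r1 = fg.reml_icc(y).icc
    r2 = fg.reml_icc(scale * y + shift).icc
    assert r1 == pytest.approx(r2, abs=1e-8)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    d=hnp.arrays(float, st.integers(3, 40), elements=st.floats(-50, 50)),
    base=st.floats(-10, 10),
)
def test_rm_anova_matches_paired_t_for_any_paired_sample(d, base):
    a = base + d
    b = np.full_like(d, base)
    if np.var(d, ddof=1) < 1e-12:
        return  # degenerate-difference path tested separately
    res = fg.rm_anova_two_condition(a, b)
    t = stats.ttest_rel(a, b)
    assert res.f == pytest.approx(t.statistic**2, rel=1e-9, abs=1e-10)


class TestIccSimulationStudy:
    def test_near_perfect_reliability_limit(self):
        rep = icc_simulation_study(0.99, n=50, k=2, reps=200, seed=0)
        assert rep.mean_anova > 0.95
        assert rep.mean_reml > 0.95

    def test_estimator_sd_shrinks_with_sample_size(self):
        small = icc_simulation_study(0.4, n=21, k=2, reps=500, seed=1)
        large = icc_simulation_study(0.4, n=200, k=2, reps=500, seed=1)
        assert large.sd_anova < small.sd_anova

    def test_invalid_planted_value_rejected(self):
        with pytest.raises(ValueError):
            icc_simulation_study(1.0, n=10, k=2, reps=100, seed=0)
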