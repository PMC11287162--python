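"""Tests of exclusion rules, regressions, ANOVA, multiplicity procedures and ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lumiclock.panel_stats import (
    anova_oneway,
    bky_two_stage,
    ddct_expression,
    holm_sidak,
    linreg,
    run_panel_analysis,
    zscore_exclude,
)
from lumiclock.signal_model import PanelSpec, simulate_panel


class TestZscoreExclude:
    def test_identical_values_no_exclusions(self):
        assert not zscore_exclude(np.ones(5)).any()

    def test_single_extreme_self_masks_under_leave_in(self):
        # mean 2.8, SD 4.02 -> Z = 1.79: the extreme point hides itself
        flags = zscore_exclude(np.array([1, 1, 1, 1, 10.0]))
        assert not flags.any()
        # leave-one-out unmasks it
        assert zscore_exclude(np.array([1, 1, 1, 1, 10.0]), method="leave_one_out")[-1]

    def test_extreme_in_larger_panel_flagged(self):
        flags = zscore_exclude(np.array([1.0] * 9 + [20.0]))
        assert list(np.nonzero(flags)[0]) == [9]

    def test_one_sided_high_only(self):
        flags = zscore_exclude(np.array([20.0] + [100.0] * 9))
        assert not flags[0]  # low outlier is not excluded

    def test_needs_three_values(self):
        with pytest.raises(ValueError, match="3"):
            zscore_exclude(np.array([1.0, 2.0]))


class TestLinreg:
    def test_exact_fit(self):
        x = np.arange(5.0)
        r = linreg(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_and_t_oracle(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 3 - 0.5 * x + rng.standard_normal(20)
        r = linreg(x, y)
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.intercept == pytest.approx(beta[0], rel=1e-10)
        assert r.slope == pytest.approx(beta[1], rel=1e-10)
        resid = y - X @ beta
        sigma2 = resid @ resid / (20 - 2)
        se = np.sqrt(sigma2 / np.sum((x - x.mean()) ** 2))
        t = beta[1] / se
        assert r.t_stat == pytest.approx(t, rel=1e-10)
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-10)
        # R^2 equals squared Pearson correlation for simple regression
        assert r.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-12)

    def test_affine_rescaling_leaves_p_invariant(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 1 + x + rng.standard_normal(15)
        p0 = linreg(x, y).p_value
        p1 = linreg(100 * x - 7, 0.01 * y + 3).p_value
        assert p0 == pytest.approx(p1, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="var"):
            linreg(np.ones(5), np.arange(5.0))


class TestAnova:
    def test_degenerate_all_identical(self):
        res = anova_oneway(np.ones(4), np.ones(4))
        assert res.degenerate

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.standard_normal(8), 1 + rng.standard_normal(8)
        res = anova_oneway(a, b)
        t = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_sums_of_squares_oracle(self, rng):
        groups = [rng.uniform(0, 5, 8) for _ in range(3)]
        res = anova_oneway(*groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ss_between / 2) / (ss_within / 21)
        assert res.F == pytest.approx(F, rel=1e-10)

    def test_zero_within_variance_distinct_means(self):
        res = anova_oneway(np.ones(3), 2 * np.ones(3))
        assert res.p_value == 0.0


class TestHolmSidak:
    def test_single_p_unchanged(self):
        out = holm_sidak(np.array([0.03]))
        assert out.adjusted_p[0] == pytest.approx(0.03)

    def test_closed_form_three_values(self):
        out = holm_sidak(np.array([0.01, 0.04, 0.03]))
        # sorted (0.01, 0.03, 0.04): 1-(1-p)^(m-i+1) with running max
        assert out.adjusted_p[0] == pytest.approx(1 - 0.99**3)  # 0.029701
        assert out.adjusted_p[2] == pytest.approx(1 - 0.97**2)  # 0.0591
        assert out.adjusted_p[1] == pytest.approx(1 - 0.97**2)  # running max over 1-0.96

    def test_all_ones(self):
        out = holm_sidak(np.ones(4))
        assert np.all(out.adjusted_p == 1.0)
        assert not out.reject.any()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_adjusted_at_least_raw(self, ps):
        out = holm_sidak(np.array(ps))
        assert np.all(out.adjusted_p >= out.raw_p - 1e-12)
        assert np.all(out.adjusted_p <= 1.0)


class TestBky:
    def test_all_ones_no_rejections(self):
        assert not bky_two_stage(np.ones(5)).reject.any()

    def test_single_small_p_rejected(self):
        # stage 1 at q' = 0.05/1.05 = 0.0476; 0.01 <= 0.0476
        assert bky_two_stage(np.array([0.01]), q=0.05).reject[0]

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=15))
    def test_superset_of_stage1_bh(self, ps):
        p = np.array(ps)
        q = 0.05
        stage1 = multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0]
        mine = bky_two_stage(p, q).reject
        assert np.all(mine[stage1])  # every stage-1 rejection survives

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_monotone_in_q(self, ps):
        p = np.array(ps)
        r1 = bky_two_stage(p, 0.05).reject
        r2 = bky_two_stage(p, 0.10).reject
        assert np.all(r2[r1])

    def test_matches_statsmodels_two_stage(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 12))
            mine = bky_two_stage(p, 0.05).reject
            sm = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(mine, sm)


class TestDdct:
    def test_identities(self):
        assert ddct_expression(25.0, 25.0) == pytest.approx(1.0)
        assert ddct_expression(26.0, 25.0) == pytest.approx(0.5)
        assert ddct_expression(25.0 - 3.321928, 25.0) == pytest.approx(10.0, rel=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ddct_expression(float("nan"), 25.0)


def make_records(n=10, seed=0, amplitude_slope=0.08, rhythmic=None):
    sim = simulate_panel(PanelSpec(n_lines=n, amplitude_slope=amplitude_slope, seed=seed))
    rec = sim.panel.rename(columns={"metabolic_activity": "m"})
    rec["rhythmic"] = rhythmic if rhythmic is not None else True
    return rec[["line_id", "amplitude", "atp_linked", "basal_glycolysis", "rhythmic"]]


class TestRunPanelAnalysis:
    def test_negative_coupling_recovered(self):
        analysis = run_panel_analysis(make_records(n=10, seed=1))
        assert analysis.amplitude_vs_atp.slope < 0
        assert analysis.amplitude_vs_atp.p_value < 0.05

    def test_arrhythmic_line_absent_from_regression(self):
        rec = make_records(n=8, seed=2)
        rhythmic = [True] * 8
        rhythmic[3] = False
        rec["rhythmic"] = rhythmic
        analysis = run_panel_analysis(rec)
        assert analysis.amplitude_vs_atp.n == 7
        row = analysis.records.iloc[3]
        assert row["excluded"] and row["exclusion_reason"] == "arrhythmic"

    def test_amplitude_outlier_excluded_after_arrhythmic(self):
        rec = make_records(n=10, seed=3)
        rec.loc[0, "amplitude"] = 50.0  # far outside the panel's range
        analysis = run_panel_analysis(rec)
        assert analysis.records.loc[0, "exclusion_reason"] == "amplitude_outlier"
        assert analysis.amplitude_vs_atp.n == 9

    def test_too_few_survivors_rejected(self):
        rec = make_records(n=4, seed=4, rhythmic=[True, True, False, False])
        with pytest.raises(ValueError, match="3"):
            run_panel_analysis(rec)

    def test_slope_recovery_against_truth(self):
        # implied amplitude~atp slope is -amplitude_slope/atp_coupling
        spec = PanelSpec(n_lines=40, atp_noise_sd=1.0, amplitude_noise_sd=0.005, seed=5)
        sim = simulate_panel(spec)
        rec = sim.panel.copy()
        rec["rhythmic"] = True
        analysis = run_panel_analysis(rec)
        implied = -spec.amplitude_slope / spec.atp_coupling
        assert analysis.amplitude_vs_atp.slope == pytest.approx(implied, rel=0.15)
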