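"""Normality-gated paired tests, regressions and spline diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cmr_remodel.stats import (bonferroni_alpha, correlation_matrix,
                               durbin_watson_test, paired_compare,
                               rcs_nonlinearity, stepwise_multivariable,
                               univariable_screen, wilcoxon_signed_rank)


class TestPairedCompare:
    def test_t_branch_closed_form(self):
        # differences {2, 3, 4}: t = mean/(sd/sqrt(n)) = 5.196, df = 2
        res = paired_compare(np.zeros(3), np.array([2.0, 3.0, 4.0]),
                             force="t")
        assert res.statistic == pytest.approx(5.196, abs=1e-3)
        assert res.p == pytest.approx(0.0351, abs=1e-3)
        d = np.array([2.0, 3.0, 4.0])
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(t_direct)

    def test_wilcoxon_all_positive_exact(self):
        res = paired_compare(np.zeros(5), np.arange(1.0, 6.0),
                             force="wilcoxon")
        assert res.p == pytest.approx(0.0625)

    def test_identical_vectors_degenerate(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="zero"):
            res = paired_compare(x, x)
        assert res.p == 1.0
        assert not res.significant

    def test_shapiro_gate_routes_heavy_tails_to_wilcoxon(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(0, 1, 40)
        post = pre + rng.standard_cauchy(40) + 5  # grossly non-normal shift
        res = paired_compare(pre, post)
        assert res.test == "wilcoxon-signed-rank"
        assert res.shapiro_p < 0.05

    def test_gaussian_differences_take_t_branch(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(0, 1, 40)
        post = pre + rng.normal(2, 0.5, 40)
        res = paired_compare(pre, post)
        assert res.test == "paired-t"

    def test_significance_uses_adjusted_alpha(self):
        rng = np.random.default_rng(5)
        pre = rng.normal(0, 1, 10)
        post = pre + rng.normal(0.9, 1.0, 10)  # p around 0.01-0.05
        res = paired_compare(pre, post, alpha=0.05, m=20)
        if 0.0025 < res.p < 0.05:
            assert not res.significant

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            paired_compare(np.zeros(4), np.zeros(5))


class TestWilcoxonExact:
    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(0.3, 1.0, rng.integers(6, 16))
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(
                sps.wilcoxon(d, method="exact").pvalue, abs=1e-12)

    def test_zeros_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -3.0])
        _, p, n = wilcoxon_signed_rank(d)
        assert n == 3

    def test_large_n_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.35, 1.0, 40)
        _, p_approx, _ = wilcoxon_signed_rank(d, exact_limit=25)
        _, p_exact, _ = wilcoxon_signed_rank(d, exact_limit=60)
        assert p_approx == pytest.approx(p_exact, rel=0.15, abs=5e-4)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expect", [(0.05, 20, 0.0025),
                                                (0.05, 1, 0.05),
                                                (0.10, 4, 0.025)])
    def test_threshold(self, alpha, m, expect):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expect)

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestCorrelationMatrix:
    def test_perfect_linear_and_anti(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        r, p = correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert r.loc["x", "x"] == 1.0

    def test_hand_computed_half(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [2, 1, 3]})
        r, _ = correlation_matrix(df)
        assert r.loc["a", "b"] == pytest.approx(0.5)

    def test_zero_variance_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "c": [5.0, 5, 5]})
        r, _ = correlation_matrix(df)
        assert np.isnan(r.loc["a", "c"])


class TestUnivariableScreen:
    def test_recovers_strong_linear_effect(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        y = pd.Series(2 * x + rng.normal(0, 0.01, 100))
        table, kept = univariable_screen(y, pd.DataFrame({"x": x}))
        assert kept == ["x"]
        assert table["beta"].iloc[0] == pytest.approx(2.0, abs=0.01)
        assert table["ci_low"].iloc[0] < 2.0 < table["ci_high"].iloc[0]

    def test_empty_candidate_set(self):
        y = pd.Series(np.arange(5.0))
        table, kept = univariable_screen(y, pd.DataFrame(index=range(5)))
        assert kept == []
        assert len(table) == 0

    def test_constant_predictor_skipped(self):
        y = pd.Series(np.arange(5.0))
        with pytest.warns(UserWarning, match="constant"):
            table, kept = univariable_screen(
                y, pd.DataFrame({"c": np.ones(5)}))
        assert len(table) == 0


class TestStepwise:
    def test_recovers_planted_predictors(self):
        rng = np.random.default_rng(1000)
        X = pd.DataFrame(rng.normal(size=(200, 7)),
                         columns=[f"x{i}" for i in range(7)])
        y = 3 * X.x0 - 2 * X.x1 + rng.normal(0, 0.5, 200)
        res = stepwise_multivariable(y, X)
        assert set(res.selected) == {"x0", "x1"}
        betas = dict(zip(res.table.predictor, res.table.beta))
        assert betas["x0"] == pytest.approx(3.0, abs=0.15)
        assert betas["x1"] == pytest.approx(-2.0, abs=0.15)

    def test_collinear_duplicate_dropped(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        X = pd.DataFrame({"x": x, "x_dup": 2 * x})
        y = pd.Series(x + rng.normal(0, 0.1, 100))
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_multivariable(y, X)
        assert res.selected == ["x"]

    def test_pure_noise_selects_nothing_usually(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = pd.Series(rng.normal(size=50))
        res = stepwise_multivariable(y, X)
        # either empty or a single weak selection; never a strong claim
        assert len(res.selected) <= 1

    def test_on_line_observation_not_flagged(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=60)
        y = pd.Series(2 * x + rng.normal(0, 0.5, 60))
        # append a point exactly on the population line at average leverage
        x = np.append(x, 0.0)
        y = pd.concat([y, pd.Series([0.0])], ignore_index=True)
        res = stepwise_multivariable(y, pd.DataFrame({"x": x}))
        assert res.cooks_distance[-1] < 0.05
        assert 60 not in res.flagged


class TestDurbinWatson:
    def test_alternating_residuals_hand_value(self):
        # sum of squared successive differences 12 over sum of squares 4
        resid = np.array([1.0, -1.0, 1.0, -1.0])
        dw, _ = durbin_watson_test(resid, np.ones((4, 1)), n_sim=200, seed=0)
        assert dw == pytest.approx(3.0)

    def test_positive_autocorrelation_small_p(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 1 + 2 * x + 0.5 * np.cumsum(rng.normal(size=40))
        exog = sm.add_constant(x)
        fit = sm.OLS(y, exog).fit()
        dw, p = durbin_watson_test(np.asarray(fit.resid), np.asarray(exog),
                                   seed=3)
        assert dw < 1.5
        assert p < 0.05


class TestRcsNonlinearity:
    def test_linear_relationship_rarely_flagged(self):
        flags = 0
        for rep in range(50):
            rng = np.random.default_rng(2000 + rep)
            x = rng.normal(size=200)
            y = 1 + 2 * x + rng.normal(0, 1, 200)
            if rcs_nonlinearity(y, x).nonlinearity_p <= 0.05:
                flags += 1
        assert flags <= 5  # expect ~5% type-I rate

    def test_quadratic_strongly_flagged(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = x ** 2 + rng.normal(0, 0.01, 200)
        assert rcs_nonlinearity(y, x).nonlinearity_p < 1e-3

    def test_constant_outcome_degenerate(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        res = rcs_nonlinearity(np.ones(100), x)
        assert res.nonlinearity_p == pytest.approx(1.0)

    def test_knot_quantiles_conventional(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=500)
        res = rcs_nonlinearity(2 * x + rng.normal(0, 1, 500), x, n_knots=4)
        expect = np.quantile(x, [0.05, 0.35, 0.65, 0.95])
        assert np.allclose(res.knots, expect)

    def test_too_few_distinct_values_raise(self):
        x = np.repeat([1.0, 2.0], 15)
        with pytest.raises(ValueError):
            rcs_nonlinearity(np.arange(30.0), x)
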