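"""Tests for group summaries, tertiles, correlation and regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from iecvstage import (
    LinearOLS,
    LogisticIRLS,
    PerfectSeparationError,
    correlate,
    fit_linear,
    fit_logistic,
    summarize_groups,
    tertile_stratify,
)


class TestSummarizeGroups:
    def test_identical_groups_null_pvalues(self, rng):
        x = rng.normal(50, 5, 60)
        cat = np.repeat(["yes", "no"], 30)
        df = pd.DataFrame(
            {"grp": ["a"] * 60 + ["b"] * 60,
             "cont": np.concatenate([x, x]),
             "cat": np.concatenate([cat, cat])}
        )
        out = summarize_groups(df, "grp").set_index("variable")
        assert out.loc["cont", "p_value"] == pytest.approx(1.0)
        assert out.loc["cat", "p_value"] == pytest.approx(1.0)

    def test_binary_prevalence_percentage(self):
        df = pd.DataFrame(
            {"grp": ["as"] * 166 + ["ctrl"] * 37,
             "midwall": [1] * 44 + [0] * 122 + [0] * 37}
        )
        out = summarize_groups(df, "grp").set_index("variable")
        assert "44 (27%)" in out.loc["midwall", "summary_as"]

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"grp": ["a", "a", "b", "b"], "x": [1.0] * 4})
        out = summarize_groups(df, "grp").set_index("variable")
        assert "constant" in out.loc["x", "flag"]
        assert np.isnan(out.loc["x", "p_value"])

    def test_detects_known_mean_shift(self, rng):
        n = 2000
        df = pd.DataFrame(
            {"grp": ["a"] * n + ["b"] * n,
             "x": np.concatenate([rng.normal(0, 1, n), rng.normal(0.2, 1, n)])}
        )
        out = summarize_groups(df, "grp").set_index("variable")
        # power > 99.9% for d = 0.2 at n = 2000/group
        assert out.loc["x", "p_value"] < 0.01
        assert out.loc["x", "test"] == "t-test"

    def test_skewed_variable_uses_mann_whitney(self, rng):
        df = pd.DataFrame(
            {"grp": np.repeat(["a", "b"], 200),
             "x": rng.lognormal(0, 1.0, 400)}
        )
        out = summarize_groups(df, "grp").set_index("variable")
        assert out.loc["x", "test"] == "mann-whitney"
        assert "(" in out.loc["x", "summary_a"]  # median (IQR) format

    def test_three_group_tests(self, rng):
        df = pd.DataFrame(
            {"grp": np.repeat(["a", "b", "c"], 50), "x": rng.normal(0, 1, 150)}
        )
        out = summarize_groups(df, "grp").set_index("variable")
        assert out.loc["x", "test"] in ("anova", "kruskal-wallis")

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_groups(pd.DataFrame({"grp": ["a"], "x": [1.0]}), "grp")


class TestTertiles:
    def test_published_cohort_sizes(self, rng):
        vals = rng.permutation(np.linspace(10, 40, 161))
        res = tertile_stratify(pd.Series(vals))
        assert res.sizes == {"T1": 54, "T2": 54, "T3": 53}
        assert not res.degenerate

    def test_exact_thirds(self):
        res = tertile_stratify(pd.Series(np.arange(1, 10, dtype=float)))
        lab = res.labels
        assert (lab[:3] == "T1").all() and (lab[3:6] == "T2").all() and (lab[6:] == "T3").all()

    def test_all_equal_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = tertile_stratify(pd.Series([5.0] * 9))
        assert res.degenerate

    @pytest.mark.parametrize("n", [5, 7, 12, 100, 161, 200])
    def test_size_balance_distinct_values(self, n, rng):
        res = tertile_stratify(pd.Series(rng.permutation(np.arange(n, dtype=float))))
        sizes = list(res.sizes.values())
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            tertile_stratify(pd.Series([1.0, 2.0]))


class TestCorrelate:
    def test_identity_and_anti_identity(self):
        x = np.arange(10, dtype=float)
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_monotone(self):
        x = np.arange(1, 11, dtype=float)
        r, _ = correlate(x, np.exp(x), method="spearman")
        assert r == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])


def make_2x2(a, b, c, d):
    """Binary exposure/outcome data with a given 2x2 table."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return x, y


class TestLogisticIRLS:
    def test_matches_contingency_table_odds_ratio(self):
        a, b, c, d = 20, 12, 9, 25
        x, y = make_2x2(a, b, c, d)
        table = fit_logistic(x, y, names=["exposure"])
        assert table["odds_ratio"].iloc[0] == pytest.approx(
            (a * d) / (b * c), rel=1e-6
        )

    def test_loglik_beats_grid_search(self, rng):
        """MLE log-likelihood dominates a dense grid (n <= 30)."""
        x = rng.normal(0, 1, 25)
        y = (rng.random(25) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        model = LogisticIRLS().fit(x, y)
        b0s = np.linspace(model.coef_[0] - 2, model.coef_[0] + 2, 60)
        b1s = np.linspace(model.coef_[1] - 2, model.coef_[1] + 2, 60)
        B0, B1 = np.meshgrid(b0s, b1s)
        eta = B0[..., None] + B1[..., None] * x
        ll = (y * eta - np.log1p(np.exp(eta))).sum(axis=-1)
        assert model.loglik_ >= ll.max() - 1e-9

    def test_matches_statsmodels(self, rng):
        X = rng.normal(0, 1, (200, 3))
        eta = 0.5 - 0.8 * X[:, 0] + 0.3 * X[:, 2]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = LogisticIRLS().fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.coef_, ref.params, rtol=1e-6)
        np.testing.assert_allclose(ours.se_, ref.bse, rtol=1e-5)

    def test_perfect_separation_raises(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0, -3.0, 3.0])
        y = (x > 0).astype(float)
        with pytest.raises(PerfectSeparationError):
            LogisticIRLS().fit(x, y)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            LogisticIRLS().fit(np.ones(10), np.tile([0.0, 1.0], 5))

    def test_wald_ci_contains_point(self, rng):
        x, y = make_2x2(15, 10, 8, 20)
        t = fit_logistic(x, y)
        assert t["ci_low"].iloc[0] < t["odds_ratio"].iloc[0] < t["ci_high"].iloc[0]


class TestLinearOLS:
    def test_exact_noise_free_fit(self):
        x = np.arange(10, dtype=float)
        t = fit_linear(x, 2 * x + 1)
        assert t.set_index("term")["coef"].loc["intercept"] == pytest.approx(1.0)
        assert t.set_index("term")["coef"].loc["x1"] == pytest.approx(2.0)

    def test_orthogonal_predictors_equal_univariate_slopes(self, rng):
        n = 128
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = rng.normal(0, 1, n) + 0.7 * x1 - 0.3 * x2
        multi = LinearOLS().fit(np.column_stack([x1, x2]), y).coef_
        uni1 = LinearOLS().fit(x1, y).coef_[1]
        uni2 = LinearOLS().fit(x2, y).coef_[1]
        assert multi[1] == pytest.approx(uni1, rel=1e-10)
        assert multi[2] == pytest.approx(uni2, rel=1e-10)

    def test_residual_orthogonality(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = rng.normal(0, 1, 60)
        model = LinearOLS().fit(X, y)
        A = np.column_stack([np.ones(60), X])
        assert np.abs(A.T @ model.residuals_).max() < 1e-8

    def test_matches_statsmodels(self, rng):
        X = rng.normal(0, 1, (80, 2))
        y = 1.0 + X @ [0.5, -1.2] + rng.normal(0, 0.3, 80)
        ours = LinearOLS().fit(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(ours.coef_, ref.params, rtol=1e-8)
        np.testing.assert_allclose(ours.se_, ref.bse, rtol=1e-8)
        ci = ours.conf_int()
        np.testing.assert_allclose(
            ci[["ci_low", "ci_high"]].to_numpy(), ref.conf_int(), rtol=1e-8
        )

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            LinearOLS().fit(X, np.arange(10.0))
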