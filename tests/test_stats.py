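"""Agreement statistics: Bland-Altman, correlations, repeated measures,
forward stepwise regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import laaview as lv
from laaview.errors import ParameterError
from laaview.stats import repeated_measures_tests, stepwise_regression


class TestBlandAltman:
    def test_identical_vectors_degenerate_zero_bias(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = lv.bland_altman(a, a)
        assert rep.bias == 0.0
        assert rep.loa_upper == rep.loa_lower == 0.0
        assert rep.degenerate
        assert rep.fixed_bias_p == 1.0

    def test_constant_offset(self):
        b = np.linspace(10, 20, 10)
        rep = lv.bland_altman(b + 2.0, b)
        assert rep.bias == pytest.approx(2.0, abs=1e-12)
        assert rep.degenerate
        assert rep.fixed_bias_p == 0.0

    def test_monte_carlo_recovers_closed_form(self):
        """d ~ N(1, 2), n = 10^4: bias -> 1, upper LOA -> 1 + 1.96*2."""
        rng = np.random.default_rng(2024)
        d = rng.normal(1.0, 2.0, size=10_000)
        b = rng.normal(30.0, 3.0, size=10_000)
        rep = lv.bland_altman(b + d, b)
        assert abs(rep.bias - 1.0) < 0.06
        assert abs(rep.loa_upper - 4.92) < 0.1
        assert abs(rep.loa_lower - (1 - 3.92)) < 0.1

    def test_formulas_match_direct_computation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(25, 4, 20)
        b = a + rng.normal(0.5, 1.0, 20)
        rep = lv.bland_altman(a, b)
        d = a - b
        sd = np.std(d, ddof=1)
        assert rep.sd_diff == pytest.approx(sd, abs=1e-12)
        assert rep.loa_upper == pytest.approx(np.mean(d) + 1.96 * sd, abs=1e-12)
        t = sps.t.ppf(0.975, 19)
        assert rep.ci_bias[1] - rep.ci_bias[0] == pytest.approx(
            2 * t * sd / np.sqrt(20), abs=1e-12)
        assert rep.ci_loa_upper[1] - rep.ci_loa_upper[0] == pytest.approx(
            2 * t * sd * np.sqrt(3 / 20), abs=1e-12)
        assert rep.fixed_bias_p == pytest.approx(
            sps.ttest_1samp(d, 0).pvalue, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            lv.bland_altman([1.0, 2.0], [1.0, 2.0])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = lv.correlation(x, 3 * x + 2, "pearson")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_monotone_nonlinear(self):
        x = np.arange(1.0, 11.0)
        y = np.exp(x)
        rs, _ = lv.correlation(x, y, "spearman")
        r, _ = lv.correlation(x, y, "pearson")
        assert rs == pytest.approx(1.0)
        assert r < 1.0

    def test_fixture_matches_textbook_formula(self):
        x = np.array([2.1, 3.4, 1.2, 5.5, 4.4, 6.1, 0.3, 7.7, 2.9, 5.0])
        y = np.array([1.0, 2.2, 0.7, 4.9, 3.1, 5.5, 0.1, 6.3, 2.0, 4.1])
        r, _ = lv.correlation(x, y, "pearson")
        xc, yc = x - x.mean(), y - y.mean()
        direct = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_one_tailed_p_is_half_two_tailed_for_positive_r(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.8, size=30)
        _, p1 = lv.correlation(x, y, "pearson", alternative="greater")
        p2 = sps.pearsonr(x, y).pvalue
        assert p1 == pytest.approx(p2 / 2, rel=1e-9)

    def test_affine_and_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r0, _ = lv.correlation(x, y, "pearson")
        r1, _ = lv.correlation(2.5 * x - 7, y, "pearson")
        assert r0 == pytest.approx(r1, abs=1e-12)
        rs0, _ = lv.correlation(x, y, "spearman")
        rs1, _ = lv.correlation(np.exp(x), y, "spearman")
        assert rs0 == pytest.approx(rs1, abs=1e-12)

    def test_constant_input_flagged(self):
        r, p = lv.correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(r)


class TestRepeatedMeasures:
    def test_identical_columns_friedman_null(self):
        df = pd.DataFrame({c: np.arange(8.0) for c in "abcd"})
        out = repeated_measures_tests(df, kind="friedman")
        assert out["statistic"] == 0.0
        assert out["p"] == 1.0
        assert out["bonferroni_reference_p"] == pytest.approx(0.05 / 6)

    def test_friedman_matches_hand_computed_ranks(self):
        """One shifted column on an 8-case dataset: chi2 from the rank-sum
        formula computed independently."""
        rng = np.random.default_rng(0)
        base = rng.normal(20, 3, 8)
        df = pd.DataFrame({
            "a": base, "b": base + rng.normal(0, .1, 8),
            "c": base + rng.normal(0, .1, 8), "d": base + 5.0,
        })
        out = repeated_measures_tests(df, kind="friedman")
        ranks = df.rank(axis=1)
        R = ranks.sum(axis=0).to_numpy()
        n, k = df.shape
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3 * n * (k + 1)
        assert out["statistic"] == pytest.approx(chi2, abs=1e-9)
        posthoc = {tuple(sorted(p["pair"])): p for p in out["posthoc"]}
        assert posthoc[("a", "d")]["p"] < 0.05

    def test_ranova_runs_and_detects_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(25, 3, 12)
        df = pd.DataFrame({
            "a": base + rng.normal(0, .2, 12), "b": base + rng.normal(0, .2, 12),
            "c": base + rng.normal(0, .2, 12), "d": base + 2.0,
        })
        out = repeated_measures_tests(df, kind="ranova")
        assert out["p"] < 0.01
        assert out["statistic"] > 0

    def test_listwise_exclusion_of_missing(self):
        df = pd.DataFrame({"a": [1, 2, np.nan, 4.0], "b": [1, 2, 3, 4.0],
                           "c": [2, 1, 3, 5.0], "d": [1, 3, 2, 4.0]})
        out = repeated_measures_tests(df, kind="friedman")
        assert out["n"] == 3
        assert out["excluded"] == 1


class TestStepwise:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        noise = rng.normal(size=60)
        y = 2.0 * x + rng.normal(scale=1e-4, size=60)
        res = stepwise_regression(y, pd.DataFrame({"x": x, "noise": noise}))
        assert res.selected == ["x"]
        assert res.steps[0].b == pytest.approx(2.0, abs=1e-3)

    def test_null_predictors_enter_at_alpha_rate(self):
        """Two pure-noise candidates: P(any enters) ~ 1 - (1-alpha)^2."""
        rng = np.random.default_rng(11)
        entered = 0
        n_sim = 300
        for _ in range(n_sim):
            y = rng.normal(size=30)
            X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
            if stepwise_regression(y, X).selected:
                entered += 1
        rate = entered / n_sim
        expected = 1 - 0.95**2
        sd = np.sqrt(expected * (1 - expected) / n_sim)
        assert abs(rate - expected) < 4 * sd

    def test_r2_nondecreasing_delta_nonnegative(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = X["a"] * 1.5 - X["c"] * 0.8 + rng.normal(scale=0.5, size=80)
        res = stepwise_regression(y, X)
        r2s = [s.r2 for s in res.steps]
        assert all(d >= -1e-12 for d in np.diff(r2s))
        assert all(s.delta_r2 >= -1e-12 for s in res.steps)
        assert r2s[-1] == pytest.approx(sum(s.delta_r2 for s in res.steps), abs=1e-9)

    def test_entry_threshold_respected(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 2 * X["a"] + rng.normal(scale=0.1, size=40)
        res = stepwise_regression(y, X, entry_p=1e-12)
        assert all(s.p_entry < 1e-12 for s in res.steps)
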