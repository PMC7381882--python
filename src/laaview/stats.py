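"""Agreement and error-attribution statistics.

Implements the study's analysis toolkit: Pearson/Spearman correlation
with one-tailed p-values, Bland-Altman agreement with limits of
agreement (LOA) and their confidence intervals, fixed- and
proportional-bias tests, repeated-measures omnibus tests with
Bonferroni-corrected post-hoc pairs, and forward stepwise linear
regression with per-step R-squared increments.

Bland-Altman conventions: for paired samples (a, b) the differences are
d = a - b, bias = mean(d), LOA = bias +/- 1.96 sd(d) with the sample
(n-1) standard deviation.  The 95% CI of the bias uses the t
distribution; each LOA's standard error uses the standard approximation
se(LOA) = sd * sqrt(3/n).  Fixed bias is tested with a one-sample t-test
of d against zero, proportional bias by regressing d on the pair means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import ParameterError

__all__ = [
    "AgreementReport",
    "StepwiseResult",
    "bland_altman",
    "correlation",
    "repeated_measures_tests",
    "stepwise_regression",
    "bland_altman_plot",
]


@dataclass
class AgreementReport:
    """Bland-Altman agreement of one measurement pair."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    fixed_bias_p: float
    proportional_bias_slope: float
    proportional_bias_p: float
    degenerate: bool = False  # zero-variance differences

    @property
    def loa_width(self) -> float:
        return self.loa_upper - self.loa_lower


def bland_altman(a, b) -> AgreementReport:
    """Agreement between two paired measurement sets (differences a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("inputs must be equal-length 1D vectors")
    n = len(a)
    if n < 3:
        raise ParameterError("Bland-Altman needs n >= 3 pairs")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ParameterError("missing values are not allowed")
    d = a - b
    mean_pair = (a + b) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    degenerate = sd < 1e-12

    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    t_crit = float(sps.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    ci_bias = (bias - t_crit * se_bias, bias + t_crit * se_bias)
    ci_lo = (loa_lo - t_crit * se_loa, loa_lo + t_crit * se_loa)
    ci_hi = (loa_hi - t_crit * se_loa, loa_hi + t_crit * se_loa)

    if degenerate:
        fixed_p = 1.0 if abs(bias) < 1e-12 else 0.0
        slope, slope_p = 0.0, 1.0
    else:
        fixed_p = float(sps.ttest_1samp(d, 0.0).pvalue)
        if np.std(mean_pair) < 1e-12:
            slope, slope_p = 0.0, 1.0
        else:
            res = sps.linregress(mean_pair, d)
            slope, slope_p = float(res.slope), float(res.pvalue)
    return AgreementReport(
        n=n, bias=bias, sd_diff=sd, loa_lower=loa_lo, loa_upper=loa_hi,
        ci_bias=ci_bias, ci_loa_lower=ci_lo, ci_loa_upper=ci_hi,
        fixed_bias_p=fixed_p, proportional_bias_slope=slope,
        proportional_bias_p=slope_p, degenerate=degenerate)


def correlation(a, b, method: str = "pearson",
                alternative: str = "greater") -> tuple[float, float]:
    """Correlation coefficient with a one-tailed p-value by default
    (positive association), Pearson or Spearman."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3:
        raise ParameterError("correlation needs n >= 3")
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return float("nan"), float("nan")
    if method == "pearson":
        res = sps.pearsonr(a, b, alternative=alternative)
    elif method == "spearman":
        res = sps.spearmanr(a, b, alternative=alternative)
    else:
        raise ParameterError(f"unknown method '{method}'")
    return float(res.statistic), float(res.pvalue)


def repeated_measures_tests(data: pd.DataFrame,
                            kind: str = "friedman",
                            alpha: float = 0.05) -> dict:
    """Omnibus + post-hoc comparison of measurement strategies.

    ``data`` has one column per strategy, complete cases only (rows with
    missing cells are excluded listwise).  ``kind='ranova'`` runs a
    repeated-measures ANOVA; ``'friedman'`` the rank-based analogue.
    Post-hoc Wilcoxon signed-rank tests are reported for every column
    pair with the Bonferroni-corrected reference p (alpha / #pairs).
    """
    df = data.dropna(axis=0)
    cols = list(df.columns)
    k = len(cols)
    if k < 3:
        raise ParameterError("need at least three strategies")
    out: dict = {"n": len(df), "excluded": len(data) - len(df), "kind": kind}

    identical = all(np.allclose(df[c], df[cols[0]]) for c in cols[1:])
    if kind == "friedman":
        if identical:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.friedmanchisquare(*[df[c] for c in cols])
        out["statistic"] = float(stat)
        out["df"] = k - 1
        out["p"] = float(p)
    elif kind == "ranova":
        long = df.reset_index().melt(id_vars="index", var_name="strategy",
                                     value_name="value")
        from statsmodels.stats.anova import AnovaRM
        res = AnovaRM(long, "value", "index", within=["strategy"]).fit()
        row = res.anova_table.iloc[0]
        out["statistic"] = float(row["F Value"])
        out["df"] = (float(row["Num DF"]), float(row["Den DF"]))
        out["p"] = float(row["Pr > F"])
    else:
        raise ParameterError(f"unknown omnibus kind '{kind}'")

    pairs = [(cols[i], cols[j]) for i in range(k) for j in range(i + 1, k)]
    out["bonferroni_reference_p"] = alpha / len(pairs)
    posthoc = []
    for c1, c2 in pairs:
        diff = df[c1].to_numpy() - df[c2].to_numpy()
        if np.allclose(diff, 0):
            w, p = 0.0, 1.0
        else:
            w, p = sps.wilcoxon(df[c1], df[c2])
        posthoc.append({"pair": (c1, c2), "statistic": float(w), "p": float(p),
                        "significant": bool(p < out["bonferroni_reference_p"])})
    out["posthoc"] = posthoc
    return out


@dataclass
class StepwiseStep:
    predictor: str
    b: float
    se_b: float
    r2: float
    delta_r2: float
    p_entry: float


@dataclass
class StepwiseResult:
    outcome: str
    steps: list[StepwiseStep] = field(default_factory=list)
    condition_warning: bool = False

    @property
    def selected(self) -> list[str]:
        return [s.predictor for s in self.steps]

    def delta_r2_of(self, predictor: str) -> float:
        for s in self.steps:
            if s.predictor == predictor:
                return s.delta_r2
        return 0.0


def stepwise_regression(y, X: pd.DataFrame, entry_p: float = 0.05,
                        outcome_name: str = "y") -> StepwiseResult:
    """Forward stepwise OLS: at each step the candidate with the smallest
    entry p-value below ``entry_p`` joins the model; stops when none
    qualifies.  Reports the entered predictor's coefficient, its standard
    error, the model R-squared and its increment at each step.  No
    removal testing is performed (pure forward selection).
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 2:
        raise ParameterError("too few observations for stepwise selection")
    result = StepwiseResult(outcome=outcome_name)
    chosen: list[str] = []
    r2_prev = 0.0
    remaining = list(X.columns)
    while remaining:
        best = None
        for cand in remaining:
            exog = sm.add_constant(X[chosen + [cand]])
            fit = sm.OLS(y, exog).fit()
            p = float(fit.pvalues[cand])
            if best is None or p < best[0]:
                best = (p, cand, fit)
        p, cand, fit = best
        if p >= entry_p:
            break
        if np.linalg.cond(np.asarray(sm.add_constant(X[chosen + [cand]]))) > 1e8:
            result.condition_warning = True
        r2 = float(fit.rsquared)
        result.steps.append(StepwiseStep(
            predictor=cand, b=float(fit.params[cand]),
            se_b=float(fit.bse[cand]), r2=r2,
            delta_r2=r2 - r2_prev, p_entry=p))
        r2_prev = r2
        chosen.append(cand)
        remaining.remove(cand)
    return result


def bland_altman_plot(a, b, ax=None, title: str = ""):
    """Bland-Altman plot with bias, LOAs and their confidence bands."""
    import matplotlib.pyplot as plt

    rep = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean_pair = (a + b) / 2.0
    ax.scatter(mean_pair, a - b, s=18, color="#32557f", alpha=0.8)
    ax.axhline(rep.bias, color="k", lw=2)
    for y in (rep.loa_lower, rep.loa_upper):
        ax.axhline(y, color="k", lw=1)
    for ci in (rep.ci_loa_lower, rep.ci_loa_upper, rep.ci_bias):
        for y in ci:
            ax.axhline(y, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("mean of pair (mm)")
    ax.set_ylabel("difference (mm)")
    if title:
        ax.set_title(title)
    return ax, rep
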