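"""Paired cohort statistics.

Within-person pre/post comparisons are gated on normality of the paired
differences (Shapiro-Wilk at 0.05): normal differences get a paired
Student's t-test, otherwise a Wilcoxon signed-rank test (zeros dropped,
midranks for ties, exact sign-flip null for n <= 25, normal approximation
with continuity and tie correction beyond).  Significance across a family
of m tests uses the Bonferroni threshold alpha/m (0.05/20 by default).

Associations are screened per predictor by simple linear regression;
predictors with p < 0.05 enter a bidirectional p-value-driven stepwise
multivariable model (entry 0.05, removal 0.10) whose final fit is reported
with confidence intervals, a Durbin-Watson check of residual independence
(Monte-Carlo p), and per-observation influence diagnostics (externally
studentized residuals > 3, Cook's distance > 0.5).  Nonlinearity of a
single covariate is tested with restricted cubic splines (Harrell basis,
knots at conventional quantiles) via an F-test on the nonlinear terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "PairedTestResult",
    "RegressionResult",
    "SplineResult",
    "paired_compare",
    "bonferroni_alpha",
    "wilcoxon_signed_rank",
    "correlation_matrix",
    "univariable_screen",
    "stepwise_multivariable",
    "rcs_basis",
    "rcs_nonlinearity",
    "durbin_watson_test",
]


@dataclass
class PairedTestResult:
    metric: str
    test: str  # "paired-t" | "wilcoxon-signed-rank" | "degenerate"
    statistic: float
    p: float
    alpha_adjusted: float
    significant: bool
    n: int
    shapiro_p: float | None = None


@dataclass
class RegressionResult:
    outcome: str
    table: pd.DataFrame  # per-predictor beta, ci_low, ci_high, p
    selected: list[str]
    durbin_watson: float
    durbin_watson_p: float
    studentized_residuals: np.ndarray
    cooks_distance: np.ndarray
    flagged: np.ndarray  # indices of influential observations
    refit_excluding_flagged: pd.DataFrame | None = None
    n: int = 0


@dataclass
class SplineResult:
    outcome: str
    covariate: str
    knots: np.ndarray
    nonlinearity_p: float
    f_statistic: float


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact sign-flip null
# ---------------------------------------------------------------------------

def _signed_ranks(diffs: np.ndarray):
    """Midranks of |d| after dropping zeros; returns (ranks, signs)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return np.array([]), np.array([])
    ranks = sps.rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_min_tail_p(ranks: np.ndarray, w_plus: float) -> float:
    """P(min(W+, W-) <= observed min) under the 2^n sign-flip null.

    Midranks are half-integer at worst, so doubling them gives an integer
    rank-sum distribution computed by dynamic programming.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.rint(2 * w_plus))
    m = min(w2, total - w2)
    # P(W2 <= m) + P(W2 >= total - m); the two tails coincide when m = total/2
    lower = dist[: m + 1].sum()
    upper = dist[total - m:].sum()
    p = lower + upper if m < total - m else 1.0
    return float(min(1.0, p))


def wilcoxon_signed_rank(diffs: np.ndarray, exact_limit: int = 25):
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; ties get midranks.  For n <= ``exact_limit`` the
    p-value is exact under the sign-flip null (defined as the probability
    that min(W+, W-) is at most the observed min); beyond that a normal
    approximation with continuity and tie correction is used.
    Returns ``(w_plus, p, n_used)``.
    """
    ranks, signs = _signed_ranks(diffs)
    n = ranks.size
    if n == 0:
        return 0.0, 1.0, 0
    w_plus = float(ranks[signs > 0].sum())
    if n <= exact_limit:
        return w_plus, _exact_min_tail_p(ranks, w_plus), n
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the no-tie variance
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        return w_plus, 1.0, n
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * sps.norm.sf(abs(z)))), n


def paired_compare(pre: np.ndarray, post: np.ndarray, alpha: float = 0.05,
                   m: int = 20, metric: str = "", shapiro_alpha: float = 0.05,
                   force: str | None = None) -> PairedTestResult:
    """Normality-gated paired comparison of pre vs post values.

    ``force`` ("t" or "wilcoxon") bypasses the Shapiro-Wilk gate.  All-zero
    differences yield a degenerate result with p = 1 and a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    if pre.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(pre).any() or np.isnan(post).any():
        raise ValueError("missing pairs are not allowed")
    d = post - pre
    thr = bonferroni_alpha(alpha, m)
    if np.all(d == 0):
        warnings.warn(f"all paired differences are zero for {metric or 'metric'}",
                      stacklevel=2)
        return PairedTestResult(metric, "degenerate", 0.0, 1.0, thr, False,
                                pre.size)
    shapiro_p = None
    if force is None:
        if np.ptp(d) == 0:  # constant nonzero differences: SW undefined
            branch = "wilcoxon"
        else:
            shapiro_p = float(sps.shapiro(d).pvalue)
            branch = "t" if shapiro_p >= shapiro_alpha else "wilcoxon"
    else:
        branch = force
    if branch == "t":
        res = sps.ttest_rel(post, pre)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "paired-t"
        n = pre.size
    elif branch == "wilcoxon":
        stat, p, n = wilcoxon_signed_rank(d)
        test = "wilcoxon-signed-rank"
    else:
        raise ValueError(f"unknown test branch {branch!r}")
    return PairedTestResult(metric, test, stat, p, thr, p < thr, n,
                            shapiro_p=shapiro_p)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlation_matrix(df: pd.DataFrame):
    """Pairwise-complete Pearson r and p matrices.

    Zero-variance columns (and pairs with fewer than 3 complete rows)
    report NaN.  Diagonal r is 1 where the column varies.
    """
    cols = list(df.columns)
    k = len(cols)
    r = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    p = r.copy()
    for i, a in enumerate(cols):
        for j, b in enumerate(cols[i:], start=i):
            sub = df[[a, b]].dropna() if a != b else df[[a]].dropna()
            if a == b:
                if len(sub) >= 2 and sub[a].std() > 0:
                    r.iloc[i, i] = 1.0
                    p.iloc[i, i] = 0.0
                continue
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                continue
            rr, pp = sps.pearsonr(sub[a], sub[b])
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
    return r, p


# ---------------------------------------------------------------------------
# Regression: univariable screen + stepwise multivariable + diagnostics
# ---------------------------------------------------------------------------

def _fit_table(model_fit, predictors: list[str]) -> pd.DataFrame:
    ci = model_fit.conf_int()
    return pd.DataFrame({
        "predictor": predictors,
        "beta": [model_fit.params[p] for p in predictors],
        "ci_low": [ci.loc[p, 0] for p in predictors],
        "ci_high": [ci.loc[p, 1] for p in predictors],
        "p": [model_fit.pvalues[p] for p in predictors],
    })


def univariable_screen(y: pd.Series, X: pd.DataFrame,
                       alpha: float = 0.05):
    """One simple linear regression per candidate predictor.

    Returns ``(table, retained)`` where ``table`` has beta/CI/p per
    candidate and ``retained`` lists predictors with p < alpha.  Constant
    predictors are skipped with a warning.
    """
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    rows = []
    retained = []
    for col in X.columns:
        x = X[col]
        if np.ptp(x.to_numpy(dtype=float)) == 0:
            warnings.warn(f"constant predictor {col!r} skipped", stacklevel=2)
            continue
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        tab = _fit_table(fit, [col])
        rows.append(tab)
        if tab["p"].iloc[0] < alpha:
            retained.append(col)
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["predictor", "beta", "ci_low",
                                        "ci_high", "p"]))
    return table, retained


def durbin_watson_test(resid: np.ndarray, exog: np.ndarray,
                       n_sim: int = 2000, seed: int = 0):
    """Durbin-Watson statistic with a Monte-Carlo p-value.

    The null distribution of DW depends on the design matrix, so it is
    simulated by refitting Gaussian noise on the same regressors.  The
    reported p is one-sided against positive autocorrelation,
    P(DW_null <= DW_observed).
    """
    dw = float(durbin_watson(resid))
    rng = np.random.default_rng(seed)
    n = exog.shape[0]
    hat = exog @ np.linalg.pinv(exog)  # projection onto the column space
    annihilator = np.eye(n) - hat
    sims = rng.standard_normal((n_sim, n))
    resid_null = sims @ annihilator.T
    num = np.sum(np.diff(resid_null, axis=1) ** 2, axis=1)
    den = np.sum(resid_null ** 2, axis=1)
    dw_null = num / den
    p = float((np.count_nonzero(dw_null <= dw) + 1) / (n_sim + 1))
    return dw, p


def stepwise_multivariable(y: pd.Series, X: pd.DataFrame,
                           entry_p: float = 0.05, removal_p: float = 0.10,
                           outcome: str = "outcome",
                           criterion: str = "pvalue",
                           dw_seed: int = 0) -> RegressionResult:
    """Bidirectional stepwise OLS starting from the empty model.

    With the default p-value criterion a candidate enters when its p in the
    augmented model is the smallest and <= ``entry_p``, and an included
    predictor leaves when its p > ``removal_p``.  ``criterion="aic"``
    switches to AIC-improvement steps.  The final model is refit for
    coefficients and 95% CIs, with Durbin-Watson and influence diagnostics.
    """
    if X.shape[1] == 0:
        raise ValueError("no candidate predictors")
    n = len(y)
    if n <= X.shape[1] + 2:
        warnings.warn("few observations relative to candidates", stacklevel=2)

    # drop perfectly collinear duplicates (keep the earlier column)
    Xc = X.copy()
    corr = Xc.corr().abs()
    drop = set()
    cols = list(Xc.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if b not in drop and np.isclose(corr.loc[a, b], 1.0):
                warnings.warn(f"predictor {b!r} collinear with {a!r}; dropped",
                              stacklevel=2)
                drop.add(b)
    Xc = Xc.drop(columns=list(drop))

    def _fit(cols_):
        return sm.OLS(y, sm.add_constant(Xc[cols_])).fit()

    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in Xc.columns if c not in selected]
        if n - (len(selected) + 2) < 2:
            remaining = []  # keep at least 2 residual degrees of freedom
        if remaining:
            if criterion == "pvalue":
                pvals = {}
                for c in remaining:
                    fit = _fit(selected + [c])
                    pvals[c] = fit.pvalues[c]
                best = min(pvals, key=pvals.get)
                if pvals[best] <= entry_p:
                    selected.append(best)
                    changed = True
            elif criterion == "aic":
                cur_aic = _fit(selected).aic if selected else sm.OLS(
                    y, np.ones((n, 1))).fit().aic
                aics = {c: _fit(selected + [c]).aic for c in remaining}
                best = min(aics, key=aics.get)
                if aics[best] < cur_aic:
                    selected.append(best)
                    changed = True
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
        if selected and criterion == "pvalue":
            fit = _fit(selected)
            worst = max(selected, key=lambda c: fit.pvalues[c])
            if fit.pvalues[worst] > removal_p:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    if not selected:
        empty = pd.DataFrame(columns=["predictor", "beta", "ci_low",
                                      "ci_high", "p"])
        return RegressionResult(outcome, empty, [], float("nan"), float("nan"),
                                np.array([]), np.array([]), np.array([]), n=n)

    final = _fit(selected)
    table = _fit_table(final, selected)
    exog = np.asarray(sm.add_constant(Xc[selected]))
    dw, dw_p = durbin_watson_test(np.asarray(final.resid), exog, seed=dw_seed)
    infl = OLSInfluence(final)
    stud = np.asarray(infl.resid_studentized_external)
    cooks = np.asarray(infl.cooks_distance[0])
    flagged = np.flatnonzero((np.abs(stud) > 3) | (cooks > 0.5))

    refit_tab = None
    if flagged.size and flagged.size < n - len(selected) - 2:
        keep = np.setdiff1d(np.arange(n), flagged)
        refit = sm.OLS(y.iloc[keep],
                       sm.add_constant(Xc[selected].iloc[keep])).fit()
        refit_tab = _fit_table(refit, selected)

    return RegressionResult(outcome, table, selected, dw, dw_p, stud, cooks,
                            flagged, refit_excluding_flagged=refit_tab, n=n)


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

#: conventional knot quantiles (Harrell)
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Nonlinear restricted-cubic-spline basis columns (Harrell form).

    For K knots returns K-2 columns; together with the linear term they
    span the space of natural cubic splines with those knots.  Columns are
    normalized by (k_K - k_1)^2 so coefficients stay on a sane scale.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = k.size
    if K < 3:
        raise ValueError("need at least 3 knots")
    norm = (k[-1] - k[0]) ** 2

    def cube(u):
        return np.clip(u, 0, None) ** 3

    cols = []
    for j in range(K - 2):
        term = (cube(x - k[j])
                - cube(x - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
                + cube(x - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)


def rcs_nonlinearity(y: np.ndarray, x: np.ndarray, n_knots: int = 4,
                     outcome: str = "outcome",
                     covariate: str = "covariate") -> SplineResult:
    """Joint F-test that all nonlinear spline coefficients are zero.

    Knots sit at the conventional quantiles of ``x`` (e.g. 5/35/65/95th
    percentiles for 4 knots).  A small p indicates the outcome-covariate
    relationship departs from linearity.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ValueError("y and x must have equal length")
    if y.size < 20:
        raise ValueError("need at least 20 observations for spline fitting")
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError("knot count must be one of 3, 4, 5")
    knots = np.quantile(x, _KNOT_QUANTILES[n_knots])
    if np.unique(knots).size < n_knots:
        raise ValueError("too few distinct covariate values for knot placement")
    Z = rcs_basis(x, knots)
    exog = sm.add_constant(np.column_stack([x, Z]))
    fit = sm.OLS(y, exog).fit()
    # joint test on the nonlinear columns (indices 2..)
    R = np.zeros((Z.shape[1], exog.shape[1]))
    for i in range(Z.shape[1]):
        R[i, 2 + i] = 1.0
    if fit.ssr <= np.finfo(float).eps * np.abs(fit.centered_tss + 1):
        # degenerate perfect fit (e.g. constant outcome)
        return SplineResult(outcome, covariate, knots, 1.0, 0.0)
    ftest = fit.f_test(R)
    return SplineResult(outcome, covariate, knots,
                        float(ftest.pvalue), float(ftest.fvalue))
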