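"""Non-twin statistics: chance-level tests, effect sizes, skewness,
cluster-robust linear associations, and FDR step-up correction.

The association model is a linear regression estimated as a generalized
estimating equation with an independence working correlation — point
estimates are ordinary least squares; standard errors come from the
cluster-sandwich estimator over twin pairs, so related infants do not
masquerade as independent observations.  Continuous variables are scaled
to unit variance so slopes are standardized; binary sex stays 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ChanceTestResult",
    "GeeResult",
    "test_against_chance",
    "effect_size_d",
    "skewness",
    "gee_fit",
    "fdr_stepup",
]


# ---------------------------------------------------------------------------
# Tests against chance
# ---------------------------------------------------------------------------

@dataclass
class ChanceTestResult:
    test: str                 # "t" or "wilcoxon"
    statistic: float
    p: float
    d: float
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    shapiro_p: float
    n: int


def effect_size_d(values: np.ndarray, chance: float) -> float:
    """Standardized deviation from chance: (mean - chance) / s.d.

    A constant vector sitting exactly at chance has d = 0 by convention;
    a constant vector away from chance has no defined effect size.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    diff = values.mean() - chance
    if sd == 0:
        if diff == 0:
            return 0.0
        raise ValueError("effect size undefined: zero variance away from chance")
    return float(diff / sd)


def test_against_chance(
    values,
    chance: float = 0.2,
    normality_alpha: float = 0.05,
) -> ChanceTestResult:
    """One-sample two-sided test of a looking measure against chance.

    Shapiro-Wilk decides the branch: a t-test when normality is not
    rejected, a Wilcoxon signed-rank test otherwise (values equal to chance
    are dropped before ranking, the standard signed-rank convention).  The
    effect size d is (mean - chance) / s.d. in either branch.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values identical")
    shapiro_p = float(stats.shapiro(values).pvalue)
    mean, sd = values.mean(), values.std(ddof=1)
    d = effect_size_d(values, chance)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    ci = (mean - tcrit * se, mean + tcrit * se)
    if shapiro_p >= normality_alpha:
        res = stats.ttest_1samp(values, chance)
        test, statistic, p = "t", float(res.statistic), float(res.pvalue)
    else:
        diffs = values - chance
        diffs = diffs[diffs != 0]
        res = stats.wilcoxon(diffs, alternative="two-sided")
        # report V = sum of positive-difference ranks (the R convention),
        # not scipy's min(V+, V-); the p-value is identical
        ranks = stats.rankdata(np.abs(diffs))
        v_plus = float(ranks[diffs > 0].sum())
        test, statistic, p = "wilcoxon", v_plus, float(res.pvalue)
    return ChanceTestResult(test=test, statistic=statistic, p=p, d=d,
                            mean=float(mean), sd=float(sd),
                            ci_lower=float(ci[0]), ci_upper=float(ci[1]),
                            shapiro_p=shapiro_p, n=n)


def skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if values.std() == 0:
        raise ValueError("zero variance")
    return float(stats.skew(values, bias=False))


# ---------------------------------------------------------------------------
# Cluster-robust linear association
# ---------------------------------------------------------------------------

@dataclass
class GeeResult:
    table: pd.DataFrame        # per-predictor beta, se, ci, p
    delta_r2: float
    r2: float
    r2_null: float
    cluster: str
    n: int
    n_clusters: int


def _find_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    base: list[int] = []
    for j in range(X.shape[1]):
        cols = base + [j]
        if np.linalg.matrix_rank(X[:, cols]) < len(cols):
            bad.append(names[j])
        else:
            base.append(j)
    return bad


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    if np.std(fitted) == 0:
        return 0.0
    return float(np.corrcoef(y, fitted)[0, 1] ** 2)


def gee_fit(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: tuple[str, ...] = ("age_days", "sex"),
    cluster: str = "pair_id",
    standardize: bool = True,
    binary_cols: tuple[str, ...] = ("sex",),
) -> GeeResult:
    """Linear association with pair-clustered sandwich standard errors.

    All predictors (and covariates) enter one simultaneous model.  The
    sandwich uses no small-sample correction, so with singleton clusters it
    coincides with the HC0 heteroskedasticity-robust estimator.  The effect
    size ``delta_r2`` compares the squared correlation between fitted and
    observed outcome against a covariates-only null model (a conventional
    pseudo-R^2; estimating equations have no canonical likelihood R^2).
    CIs are beta +/- 1.96 se; p-values are normal-reference two-sided.
    """
    cols = list(predictors) + [c for c in covariates if c not in predictors]
    use = data[[outcome, cluster, *cols]].dropna().reset_index(drop=True)
    n = len(use)
    if use[cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters")

    def col(c: str) -> np.ndarray:
        v = use[c].to_numpy(dtype=float)
        if standardize and c not in binary_cols:
            s = v.std(ddof=0)
            if s > 0:
                v = (v - v.mean()) / s
        return v

    y = col(outcome)
    X = np.column_stack([np.ones(n)] + [col(c) for c in cols])
    names = ["intercept"] + cols
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design; collinear columns: "
                         f"{_find_collinear(X, names)}")
    groups = use[cluster].to_numpy()
    res = sm.OLS(y, X).fit(
        cov_type="cluster",
        cov_kwds={"groups": pd.factorize(groups)[0],
                  "use_correction": False, "df_correction": False},
    )
    beta, se = np.asarray(res.params), np.asarray(res.bse)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "predictor": names, "beta": beta, "se": se,
        "ci_lower": beta - 1.96 * se, "ci_upper": beta + 1.96 * se, "p": p,
    })
    r2_full = _r2(y, np.asarray(res.fittedvalues))
    null_cols = [c for c in covariates if c in cols]
    if null_cols:
        Xn = np.column_stack([np.ones(n)] + [col(c) for c in null_cols])
        fit_null = sm.OLS(y, Xn).fit()
        r2_null = _r2(y, np.asarray(fit_null.fittedvalues))
    else:
        r2_null = 0.0
    return GeeResult(table=table, delta_r2=r2_full - r2_null, r2=r2_full,
                     r2_null=r2_null, cluster=cluster, n=n,
                     n_clusters=int(use[cluster].nunique()))


# ---------------------------------------------------------------------------
# FDR step-up (Benjamini-Hochberg)
# ---------------------------------------------------------------------------

def fdr_stepup(p_values, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over one family of tests.

    p-values are ranked ascending; the rank-i threshold is i*q/m and every
    test up to the largest i with p_(i) <= i*q/m is declared significant.
    The returned frame is in input order with each test's rank-assigned
    threshold (the per-test FDR threshold as conventionally tabulated).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D p-value collection")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    thresholds = ranks * q / m
    sorted_p = p[order]
    passing = np.flatnonzero(sorted_p <= np.arange(1, m + 1) * q / m)
    cutoff_rank = int(passing.max() + 1) if passing.size else 0
    significant = ranks <= cutoff_rank
    return pd.DataFrame({"p": p, "rank": ranks, "fdr_threshold": thresholds,
                         "significant": significant})
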