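"""Two-group comparison and association statistics for clamp cohorts.

The routing mirrors common metabolic-study practice: each variable is
checked for normality per group (Shapiro-Wilk at alpha = 0.05, both groups
must pass); failures are log10-transformed and re-checked; variables that
remain skewed fall through to the Mann-Whitney U test. Normal-route
contrasts are pooled-variance Student t mean differences with 95% CIs;
lognormal-route contrasts are geometric-mean ratios (t interval on the
log10 scale, back-transformed). Contrasts are ordered first group minus
(or over) second group. No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "Route",
    "CohortComparison",
    "route_variable",
    "mean_difference_ci",
    "mean_difference_from_summary",
    "geometric_ratio_ci",
    "mann_whitney",
    "pearson_r",
    "adjusted_group_effect",
    "interaction_test",
    "compare_variable",
]


class Route(str, enum.Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    NONPARAMETRIC = "nonparametric"


@dataclass
class CohortComparison:
    """One variable's two-group contrast, with the routing that produced it."""

    variable: str
    route: Route
    n: tuple[int, int]
    summary_a: tuple
    summary_b: tuple
    contrast: float          # mean difference (normal) or GM ratio (lognormal)
    ci95: tuple[float, float] | None
    p: float
    test: str
    shapiro_p: tuple[float, float] | None = None


def route_variable(a, b, alpha: float = 0.05) -> tuple[Route, tuple[float, float]]:
    """Decide the analysis route for one variable.

    Returns the route and the Shapiro-Wilk p-values (per group) of the
    scale on which the route was accepted (raw scale for normal/
    nonparametric, log10 scale for lognormal).
    """
    a = _clean(a)
    b = _clean(b)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group to assess normality")
    pa, pb = sps.shapiro(a).pvalue, sps.shapiro(b).pvalue
    if pa >= alpha and pb >= alpha:
        return Route.NORMAL, (pa, pb)
    if np.all(a > 0) and np.all(b > 0):
        pla, plb = sps.shapiro(np.log10(a)).pvalue, sps.shapiro(np.log10(b)).pvalue
        if pla >= alpha and plb >= alpha:
            return Route.LOGNORMAL, (pla, plb)
        return Route.NONPARAMETRIC, (pla, plb)
    # non-positive values: log transform unavailable, skip to nonparametric
    return Route.NONPARAMETRIC, (pa, pb)


def mean_difference_ci(a, b, conf: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Pooled-variance Student t contrast: (mean_a - mean_b, 95% CI, p)."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    return mean_difference_from_summary(
        a.size, float(np.mean(a)), float(np.std(a, ddof=1)),
        b.size, float(np.mean(b)), float(np.std(b, ddof=1)),
        conf=conf,
    )


def mean_difference_from_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    conf: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Pooled t contrast from group summaries (closed form).

    Lets printed n/mean/SD summaries be turned back into the mean
    difference, CI and p that a raw-data pooled t test would give.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = mean1 - mean2
    tcrit = sps.t.ppf(0.5 + conf / 2.0, df)
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        return diff, (diff, diff), p
    tstat = diff / se
    p = 2.0 * sps.t.sf(abs(tstat), df)
    return diff, (diff - tcrit * se, diff + tcrit * se), p


def geometric_ratio_ci(a, b, conf: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Geometric-mean ratio a/b with back-transformed t interval and p."""
    a, b = _clean(a), _clean(b)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("geometric-mean ratio requires strictly positive values")
    la, lb = np.log10(a), np.log10(b)
    diff, ci, p = mean_difference_ci(la, lb, conf=conf)
    return 10 ** diff, (10 ** ci[0], 10 ** ci[1]), p


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's 'auto' policy).
    """
    a, b = _clean(a), _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def adjusted_group_effect(outcome, group, covariates) -> tuple[float, tuple[float, float], float]:
    """Group effect adjusted for covariates by least squares.

    ``group`` is a 0/1 indicator (1 = first group); ``covariates`` a
    2-D array (n, k). Complete cases only. Returns the coefficient on the
    indicator with its t-based 95% CI and p. Rank-deficient designs raise,
    naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(y) & np.isfinite(g) & np.all(np.isfinite(X), axis=1)
    y, g, X = y[ok], g[ok], X[ok]
    design = sm.add_constant(np.column_stack([g, X]))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(design[:, 1:], rowvar=False)
        dup = np.argwhere(np.triu(np.isclose(np.abs(corr), 1.0), k=1))
        raise ValueError(f"rank-deficient design; collinear columns (0=group): {dup.tolist()}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()[1]
    return float(fit.params[1]), (float(ci[0]), float(ci[1])), float(fit.pvalues[1])


def interaction_test(outcome, predictor, group) -> float:
    """p-value of the group x predictor interaction in a linear model.

    Fits outcome ~ predictor + group + predictor:group and returns the
    two-sided p of the product term.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    g = np.asarray(group, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(g)
    y, x, g = y[ok], x[ok], g[ok]
    if np.unique(g).size < 2:
        raise ValueError("both groups must be represented")
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, design).fit()
    return float(fit.pvalues[3])


def compare_variable(name: str, a, b, alpha: float = 0.05) -> CohortComparison:
    """Route one variable and run the matching contrast."""
    a, b = _clean(a), _clean(b)
    route, shapiro_p = route_variable(a, b, alpha=alpha)
    if route is Route.NORMAL:
        diff, ci, p = mean_difference_ci(a, b)
        return CohortComparison(
            variable=name, route=route, n=(a.size, b.size),
            summary_a=(float(np.mean(a)), float(np.std(a, ddof=1))),
            summary_b=(float(np.mean(b)), float(np.std(b, ddof=1))),
            contrast=diff, ci95=ci, p=p, test="Student t (pooled)",
            shapiro_p=shapiro_p,
        )
    if route is Route.LOGNORMAL:
        ratio, ci, p = geometric_ratio_ci(a, b)
        return CohortComparison(
            variable=name, route=route, n=(a.size, b.size),
            summary_a=_gm_ci(a), summary_b=_gm_ci(b),
            contrast=ratio, ci95=ci, p=p,
            test="Student t (pooled) on log10",
            shapiro_p=shapiro_p,
        )
    p = mann_whitney(a, b)
    return CohortComparison(
        variable=name, route=route, n=(a.size, b.size),
        summary_a=_median_iqr(a), summary_b=_median_iqr(b),
        contrast=float(np.median(a) - np.median(b)), ci95=None, p=p,
        test="Mann-Whitney U", shapiro_p=shapiro_p,
    )


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


def _gm_ci(x, conf: float = 0.95) -> tuple[float, float, float]:
    lx = np.log10(x)
    m, se = np.mean(lx), np.std(lx, ddof=1) / math.sqrt(lx.size)
    tcrit = sps.t.ppf(0.5 + conf / 2.0, lx.size - 1)
    return (10 ** m, 10 ** (m - tcrit * se), 10 ** (m + tcrit * se))


def _median_iqr(x) -> tuple[float, float, float]:
    return (float(np.median(x)), float(np.percentile(x, 25)), float(np.percentile(x, 75)))
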