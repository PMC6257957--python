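"""Shared statistical kernels.

Thin, oracle-checkable wrappers around scipy/statsmodels plus the
continuity-corrected proportion tests (the R ``prop.test`` forms) that
statsmodels does not expose directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """A statistic, its p-value, and method-specific extras."""

    statistic: float
    pvalue: float
    method: str
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.pvalue}")


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (empty-safe)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def prop_test_1sample(x: int, n: int, p0: float = 0.5) -> TestResult:
    """Chi-squared test of one proportion against p0, Yates-corrected.

    Equivalent to R's ``prop.test(x, n, p=p0, correct=TRUE)`` statistic:
    chi2 = (max(|x - n p0| - 1/2, 0))^2 / (n p0 (1 - p0)), df = 1.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    num = max(abs(x - n * p0) - 0.5, 0.0)
    chi2 = num**2 / (n * p0 * (1 - p0))
    p = sps.chi2.sf(chi2, df=1)
    return TestResult(chi2, p, "1-sample proportion test with continuity correction",
                      aux={"x": x, "n": n, "p0": p0, "estimate": x / n})


def prop_test_2sample(x1: int, n1: int, x2: int, n2: int,
                      conf_level: float = 0.95) -> TestResult:
    """Two-sample test of equal proportions with continuity correction.

    Matches R's two-sample ``prop.test``: Yates-corrected chi-squared on the
    2x2 table, and a Wald confidence interval for p1 - p2 widened by the
    continuity term (1/(2 n1) + 1/(2 n2)).
    """
    for n in (n1, n2):
        if n <= 0:
            raise ValueError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    ppool = (x1 + x2) / (n1 + n2)
    denom = ppool * (1 - ppool) * (1 / n1 + 1 / n2)
    if denom == 0:
        chi2, p = 0.0, 1.0
    else:
        num = max(abs(p1 - p2) - 0.5 * (1 / n1 + 1 / n2), 0.0)
        chi2 = num**2 / denom
        p = sps.chi2.sf(chi2, df=1)
    z = sps.norm.ppf(1 - (1 - conf_level) / 2)
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    cc = 0.5 * (1 / n1 + 1 / n2)
    half = z * se + cc
    diff = p1 - p2
    return TestResult(chi2, p, "2-sample proportion test with continuity correction",
                      aux={"estimate": (p1, p2), "diff": diff,
                           "ci": (max(diff - half, -1.0), min(diff + half, 1.0)),
                           "conf_level": conf_level})


def binom_test_2sided(x: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p by tail doubling: min(1, 2*min(lower, upper))."""
    if not 0 <= x <= n:
        raise ValueError("x out of range")
    lower = sps.binom.cdf(x, n, p0)
    upper = sps.binom.sf(x - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def logistic_fit(y: np.ndarray, x: np.ndarray) -> TestResult:
    """Logistic regression of binary y on a single regressor (plus intercept).

    Returns the slope, its Wald p, and aux fields: standard error, intercept,
    McFadden pseudo-R2, and a ``separation`` flag raised when the fit is
    (quasi-)separable, in which case the Wald output is unreliable.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    X = sm.add_constant(x)
    separation = False
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # separation or singular Hessian
            separation = True
            for alpha in (1e-4, 1e-2, 1.0):
                try:
                    fit = sm.Logit(y, X).fit_regularized(alpha=alpha, disp=0,
                                                         maxiter=500)
                    break
                except Exception:
                    continue
    if fit is None:
        # fully degenerate: report the sign of the empirical association
        hi = y[x > np.median(x)].mean() if np.any(x > np.median(x)) else y.mean()
        lo = y[x <= np.median(x)].mean()
        return TestResult(np.inf * np.sign(hi - lo) if hi != lo else 0.0, 1.0,
                          "logistic regression (degenerate)",
                          aux={"se": np.nan, "intercept": np.nan,
                               "mcfadden_r2": np.nan, "separation": True,
                               "z": np.nan})
    coef = float(fit.params[1])
    se = float(fit.bse[1]) if hasattr(fit, "bse") else np.nan
    if not separation and (not np.isfinite(se) or se > 1e3 or abs(coef) > 30):
        separation = True
    pval = float(fit.pvalues[1]) if hasattr(fit, "pvalues") and np.isfinite(se) else np.nan
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            mcfadden = float(1 - fit.llf / fit.llnull)
    except Exception:
        mcfadden = np.nan
    return TestResult(coef, pval if np.isfinite(pval) else 1.0,
                      "logistic regression (Wald)",
                      aux={"se": se, "intercept": float(fit.params[0]),
                           "mcfadden_r2": mcfadden, "separation": separation,
                           "z": coef / se if se and np.isfinite(se) and se > 0 else np.nan})


def anova_tukey(values: np.ndarray, groups: np.ndarray) -> TestResult:
    """One-way ANOVA across groups with Tukey-HSD adjusted pairwise p-values."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = np.unique(groups)
    if names.size < 2:
        raise ValueError("ANOVA requires at least two groups")
    samples = [values[groups == g] for g in names]
    f, p = sps.f_oneway(*samples)
    aux: dict = {"groups": {str(g): float(np.mean(s)) for g, s in zip(names, samples)},
                 "n": {str(g): int(s.size) for g, s in zip(names, samples)}}
    from itertools import combinations

    tk = pairwise_tukeyhsd(values, groups)
    # statsmodels orders pairwise rows as combinations of the sorted groups
    aux["tukey"] = {
        f"{g1}|{g2}": float(padj)
        for (g1, g2), padj in zip(combinations(tk.groupsunique, 2),
                                  np.atleast_1d(tk.pvalues))
    }
    return TestResult(float(f), float(p), "one-way ANOVA with Tukey HSD", aux=aux)


def weighted_quantile_expand(values: np.ndarray, weights: np.ndarray,
                             n_points: int = 100_000) -> np.ndarray:
    """Deterministic expansion of a weighted discrete distribution.

    Evaluates the weighted quantile function at the n_points mid-grid
    probabilities (k + 1/2)/n; the empirical CDF of the result approximates
    the weighted CDF to within 1/n at every support point.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or not np.any(weights > 0):
        raise ValueError("need at least one positively weighted value")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    keep = w > 0
    v, w = v[keep], w[keep]
    cdf = np.cumsum(w) / np.sum(w)
    probs = (np.arange(n_points) + 0.5) / n_points
    idx = np.searchsorted(cdf, probs, side="left")
    return v[np.clip(idx, 0, v.size - 1)]
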