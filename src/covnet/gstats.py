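"""Covariate-adjusted group comparisons and summary-statistic tests.

The group analyses follow common neuroimaging practice: network scores are
compared between groups with a linear model that includes nuisance covariates
(age, sex), families of network tests are corrected with Benjamini–Hochberg
FDR, longitudinal contrasts use paired t-tests, and brain–behaviour
associations use partial correlation. Demographic tables that are published
only as mean ± SD per group are testable through the summary-statistic
t-test / one-way ANOVA / chi-square helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "GroupStatResult",
    "adjusted_two_sample_test",
    "paired_test",
    "bh_fdr",
    "partial_correlation",
    "summary_ttest",
    "summary_anova",
    "chisq_2x2",
]


@dataclass
class GroupStatResult:
    """Result of a single group-level test.

    ``effect`` is the adjusted group difference (regression coefficient of the
    group indicator, or the mean paired difference). ``q`` is filled in only
    once the result has been placed in a BH family via :func:`bh_fdr`.
    """

    effect: float
    t: float
    df: float
    p: float
    q: float | None = None
    family_size: int | None = None
    undefined: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.undefined and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _as_group_indicator(group) -> np.ndarray:
    """Map a two-level label vector to a 0/1 indicator (sorted label order)."""
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels.size}")
    return (group == levels[1]).astype(float)


def adjusted_two_sample_test(y, group, covariates=None) -> GroupStatResult:
    """Two-sample comparison of ``y`` between groups, adjusting for covariates.

    Fits the single linear model ``y ~ 1 + group + covariates`` by OLS and
    reports the t-test on the group coefficient (two-tailed).  With no
    covariates this is algebraically the pooled-variance two-sample t-test.

    Parameters
    ----------
    y : array-like, shape (n,)
        Outcome (e.g. a network integrity score or FNC value).
    group : array-like, shape (n,)
        Two-level group labels; the effect is level2 − level1 in sorted
        label order.
    covariates : array-like, shape (n, c), optional
        Nuisance regressors such as age and sex (numeric coding).
    """
    y = np.asarray(y, dtype=float)
    g = _as_group_indicator(group)
    cols = [g]
    n_cov = 0
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        n_cov = C.shape[1]
        cols.append(C)
    if y.size < n_cov + 3:
        raise ValueError("too few observations for the requested adjustment")
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear covariates?)")
    fit = sm.OLS(y, X).fit()
    return GroupStatResult(
        effect=float(fit.params[1]),
        t=float(fit.tvalues[1]),
        df=float(fit.df_resid),
        p=float(fit.pvalues[1]),
    )


def paired_test(baseline, followup) -> GroupStatResult:
    """Paired t-test (one-sample t on follow-up − baseline differences)."""
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape:
        raise ValueError("paired vectors must have equal length")
    n = baseline.size
    if n < 3:
        raise ValueError("paired test needs n >= 3")
    d = followup - baseline
    sd = d.std(ddof=1)
    # guard against float-rounding "almost constant" differences
    if sd <= 1e-12 * (abs(d.mean()) + 1.0):
        # Differences are constant: t undefined unless the constant is 0.
        if np.allclose(d, 0.0):
            return GroupStatResult(effect=0.0, t=0.0, df=n - 1, p=1.0)
        return GroupStatResult(
            effect=float(d.mean()), t=np.nan, df=n - 1, p=np.nan, undefined=True
        )
    t, p = stats.ttest_1samp(d, 0.0)
    return GroupStatResult(effect=float(d.mean()), t=float(t), df=n - 1, p=float(p))


def bh_fdr(pvals, alpha: float = 0.05):
    """Benjamini–Hochberg step-up FDR correction.

    Returns ``(qvals, rejected)`` where ``qvals`` are the monotone adjusted
    p-values and ``rejected`` flags the discoveries at level ``alpha``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return qvals, rejected


def partial_correlation(x, y, covariates):
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on ``covariates`` (plus an intercept) by
    OLS and the residuals are correlated.  The p-value uses
    ``t = r * sqrt((n − 2 − c) / (1 − r²))`` with ``n − 2 − c`` degrees of
    freedom, ``c`` the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != x.size:
        C = C.T
    n, c = C.shape
    if x.size != n or y.size != n:
        raise ValueError("x, y and covariates must have matching length")
    if n < c + 4:
        raise ValueError("too few observations for partial correlation")
    X = sm.add_constant(C)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate matrix")
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - c
    t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def summary_ttest(m1, sd1, n1, m2, sd2, n2):
    """Pooled-variance two-sample t-test from summary statistics.

    Reproduces demographic-table p-values published only as mean ± SD and n.
    Returns ``(t, df, p)`` with ``df = n1 + n2 − 2``, two-tailed p.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


def summary_anova(groups):
    """One-way ANOVA from per-group (mean, sd, n) summaries.

    Between-group sum of squares is computed from the group means, the
    within-group sum of squares from the SDs.  Returns ``(F, df1, df2, p)``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ms = np.array([g[0] for g in groups], dtype=float)
    sds = np.array([g[1] for g in groups], dtype=float)
    ns = np.array([g[2] for g in groups], dtype=float)
    if np.any(sds <= 0):
        raise ValueError("SDs must be positive")
    grand = float((ns * ms).sum() / ns.sum())
    ss_between = float((ns * (ms - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), p


def chisq_2x2(a, b, c, d):
    """Pearson chi-square for a 2×2 contingency table, df = 1.

    No continuity correction (matches the classic Pearson statistic
    ``n (ad − bc)² / (row and column margin products)``).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
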