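"""Statistical decision procedure and shared test primitives.

The group-comparison routing follows a fixed decision tree: D'Agostino-
Pearson normality on both samples; if both pass, an F-test chooses between
the pooled and the Welch t-test; if either fails (or a sample is too small
for the normality test), the Mann-Whitney U test is used.  All tests are
two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "GroupComparison",
    "normality_test",
    "compare_two_groups",
    "ks_two_sample",
    "fisher_exact",
    "bonferroni",
    "normalize_by_group_mean",
]

NORMALITY_MIN_N = 8  # minimum sample size supported by the omnibus K^2 test


@dataclass
class GroupComparison:
    """Outcome of the two-group decision procedure, with full trace."""

    test_used: str  # {"t", "t_welch", "mann_whitney"}
    p_value: float
    statistic: float
    normality_p_a: float  # nan when the gate could not run
    normality_p_b: float
    variance_equal: bool | None  # None when the t-family was not reached
    variance_p: float
    summary: dict  # per-group median and IQR
    warnings: list


def normality_test(sample) -> float:
    """D'Agostino-Pearson omnibus K^2 p-value (skewness + kurtosis)."""
    x = np.asarray(sample, dtype=float)
    if x.size < NORMALITY_MIN_N:
        raise InputError(
            f"normality test requires at least {NORMALITY_MIN_N} observations, got {x.size}"
        )
    return float(sps.normaltest(x).pvalue)


def _summary(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3)), "n": int(x.size)}


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equality of variances of two normal samples."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dist = sps.f(a.size - 1, b.size - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def compare_two_groups(
    a,
    b,
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
    always_welch: bool = False,
) -> GroupComparison:
    """Compare two samples with the normality-gated test choice.

    Samples smaller than the normality test's support (n < 8) are routed to
    Mann-Whitney with a warning.  ``always_welch`` skips the F-test gate and
    uses Welch whenever the t-family is selected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    notes: list[str] = []
    p_na = p_nb = float("nan")
    if min(a.size, b.size) < NORMALITY_MIN_N:
        notes.append("sample too small for normality test; nonparametric route")
        warnings.warn(notes[-1], stacklevel=2)
        both_normal = False
    else:
        p_na, p_nb = normality_test(a), normality_test(b)
        both_normal = p_na > alpha_normality and p_nb > alpha_normality

    variance_equal: bool | None = None
    p_var = float("nan")
    if both_normal:
        if always_welch:
            variance_equal = False
        else:
            p_var = _variance_f_test(a, b)
            variance_equal = p_var > alpha_variance
        if variance_equal:
            res = sps.ttest_ind(a, b, equal_var=True)
            used = "t"
        else:
            res = sps.ttest_ind(a, b, equal_var=False)
            used = "t_welch"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann_whitney"

    return GroupComparison(
        test_used=used,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        normality_p_a=p_na,
        normality_p_b=p_nb,
        variance_equal=variance_equal,
        variance_p=p_var,
        summary={"a": _summary(a), "b": _summary(b)},
        warnings=notes,
    )


def ks_two_sample(a, b) -> tuple:
    """Two-sample Kolmogorov-Smirnov statistic D and two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("KS test needs at least 2 observations per sample")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``; the p-value is the conditional
    hypergeometric sum of tables at least as extreme as observed.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InputError("Fisher test needs a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise InputError("counts must be non-negative integers")
    if np.any(t < 0):
        raise InputError("counts must be non-negative")
    odds, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(odds), float(p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, p * m)``; ``m`` defaults to len(p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise InputError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def normalize_by_group_mean(df, value_col: str, repeat_col: str, group_col: str, reference_group):
    """Divide values by their repeat's reference-group mean.

    Shared engine behind the per-repeat / per-day normalizations used for
    bleb metrics, track kinetics and ratiometric measurements.  Returns a
    copy of ``df`` with an added ``<value_col>_norm`` column.
    """
    out = df.copy()
    norm_col = f"{value_col}_norm"
    out[norm_col] = np.nan
    for rep, sub in df.groupby(repeat_col):
        ref = sub.loc[sub[group_col] == reference_group, value_col]
        if ref.empty:
            raise InputError(f"repeat {rep!r} has no {reference_group!r} reference values")
        ref_mean = ref.mean()
        if not np.isfinite(ref_mean) or ref_mean <= 0:
            raise InputError(f"repeat {rep!r} reference mean is not positive")
        out.loc[sub.index, norm_col] = sub[value_col] / ref_mean
    return out
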