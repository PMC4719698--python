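"""Method-comparison statistics for validating digital counts.

Agreement between counting methods (two human raters, or the reference
manual count vs the digital pixel-derived count) is summarised by the
intraclass correlation coefficient ICC(2,1) — two-way random effects,
single rater, absolute agreement — computed from the ANOVA mean squares,
with the F-distribution confidence interval of McGraw & Wong.
Bland-Altman bias and limits of agreement (mean difference +/- 1.96
sample SD) describe the scale of disagreement in count units.  Pearson,
Spearman and the nonparametric group tests delegate to scipy behind the
same surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AgreementReport:
    """Summary of one method-vs-method comparison on n paired counts."""

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    pearson_r: float
    spearman_rho: float
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _anova_mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the two-way, one-observation-per-cell layout."""
    n, k = ratings.shape
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    grand = ratings.mean()
    msr = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = ratings - row_means[:, None] - col_means[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(
    ratings: np.ndarray, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) with its F-based confidence interval.

    Parameters
    ----------
    ratings
        n subjects x k raters matrix, no missing cells, n >= 3, k >= 2.

    Returns
    -------
    (icc, (ci_low, ci_high))

    Identical rater columns (perfect agreement with subject variance)
    yield 1.0 with a warning; a fully constant matrix has no defined
    agreement and raises ``ValueError``.
    """
    M = np.asarray(ratings, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = M.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if np.isnan(M).any():
        raise ValueError("ratings must have no missing cells")
    if np.ptp(M) == 0:
        raise ValueError("all ratings identical: agreement undefined")
    msr, msc, mse = _anova_mean_squares(M)
    if msc == 0 and mse == 0:
        warnings.warn("identical rater columns: ICC defined as 1", stacklevel=2)
        return 1.0, (1.0, 1.0)
    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # Shrout-Fleiss / McGraw-Wong CI with Satterthwaite degrees of freedom
    alpha = 1.0 - confidence
    if mse == 0:
        return float(value), (float(value), float(value))
    fc = msc / mse
    vn = (k - 1) * (n - 1) * (k * value * fc + n * (1 + (k - 1) * value) - k * value) ** 2
    vd = (n - 1) * k**2 * value**2 * fc**2 + (n * (1 + (k - 1) * value) - k * value) ** 2
    v = vn / vd
    f_upper = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_lower = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = n * (msr - f_upper * mse) / (
        f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_lower * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_lower * msr
    )
    return float(value), (float(lower), float(upper))


def bland_altman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) for differences d = y - x.

    bias = mean(d); limits = bias +/- 1.96 * sample SD (n-1 denominator).
    About 95 % of normally distributed differences fall between the
    limits.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on n < 3 or zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation (Pearson on mid-ranks, average ranks for ties)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def compare_groups(
    values: Sequence[float], labels: Sequence
) -> tuple[float, float]:
    """Nonparametric location comparison across groups.

    Two groups (taken in sorted-label order): Mann-Whitney U of the
    first group (two-sided, asymptotic with tie
    correction).  Three or more: Kruskal-Wallis H.  Returns
    (statistic, p_value).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="asymptotic")
    else:
        res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def agreement_report(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Full comparison of method y against reference x on paired counts."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    value, (lo, hi) = icc(np.column_stack([x, y]))
    bias, loa_low, loa_high = bland_altman(x, y)
    return AgreementReport(
        icc=value,
        icc_ci_low=lo,
        icc_ci_high=hi,
        pearson_r=pearson_r(x, y),
        spearman_rho=spearman_rho(x, y),
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        n=int(x.size),
    )
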