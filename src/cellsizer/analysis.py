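"""Lineage statistics: sizer correlations, binned regression, size summaries.

These are the figure-level analyses applied to per-cycle records: the
Pearson correlation between division and birth size (a sizer shows none),
equal-count binned linear regression of ``V_d``, ``delta V`` or ``T_D``
against ``V_b``, and mean/CV summaries for wild-type-versus-mutant
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .lineage import CycleRecord

__all__ = [
    "BinnedFit",
    "MutantComparison",
    "SizeSummary",
    "pearson_with_ci",
    "binned_regression",
    "size_summary",
    "mutant_comparison",
]


@dataclass
class BinnedFit:
    """Equal-count binned means with an OLS line through them."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_sems: np.ndarray
    slope: float
    intercept: float
    n_bins: int


@dataclass
class MutantComparison:
    """Relative change of mean birth size and its CV, mutant vs wild type."""

    delta_mean: float
    delta_cv: float


@dataclass
class SizeSummary:
    mean: float
    sd: float
    cv: float


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input vector")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), (float(ci.low), float(ci.high))


def binned_regression(
    x: np.ndarray, y: np.ndarray, n_bins: int = 10
) -> BinnedFit:
    """OLS through equal-count bin means of y against x.

    Points are sorted by x (stable, so ties keep input order) and split
    into ``n_bins`` bins of equal count (+-1); the line is fit to the bin
    means, which is how lineage scatter plots are usually summarized.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < n_bins:
        raise ValueError("need at least one point per bin")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    splits_x = np.array_split(xs, n_bins)
    splits_y = np.array_split(ys, n_bins)
    centers = np.array([s.mean() for s in splits_x])
    means = np.array([s.mean() for s in splits_y])
    sems = np.array([s.std(ddof=1) / np.sqrt(s.size) if s.size > 1 else 0.0
                     for s in splits_y])
    fit = stats.linregress(centers, means)
    return BinnedFit(centers, means, sems, float(fit.slope), float(fit.intercept), n_bins)


def size_summary(values: Iterable[float] | Sequence[CycleRecord],
                 attr: str = "V_b") -> SizeSummary:
    """Sample mean, SD (n-1) and CV of a size quantity.

    Accepts raw values or cycle records (``attr`` selects V_b, V_d or T_D).
    """
    vals = list(values)
    if vals and isinstance(vals[0], CycleRecord):
        arr = np.array([getattr(r, attr) for r in vals], dtype=float)
    else:
        arr = np.asarray(vals, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two observations")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return SizeSummary(mean=mean, sd=sd, cv=sd / mean)


def mutant_comparison(
    wt: Sequence[CycleRecord] | Iterable[float],
    mutant: Sequence[CycleRecord] | Iterable[float],
) -> MutantComparison:
    """Relative changes ``(mean_mut - mean_wt)/mean_wt`` and same for CV."""
    w = size_summary(wt)
    m = size_summary(mutant)
    if w.mean == 0 or w.cv == 0:
        raise ZeroDivisionError("wild-type mean/CV must be nonzero")
    return MutantComparison(
        delta_mean=(m.mean - w.mean) / w.mean,
        delta_cv=(m.cv - w.cv) / w.cv,
    )
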