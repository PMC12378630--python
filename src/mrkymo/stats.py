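"""Reproducibility and comparison statistics.

Implements single-measure intraclass correlation coefficients from the
classical mean-squares decomposition with F-based 95% confidence bounds,
the exact (enumeration) two-sided Wilcoxon signed-rank test for paired
position comparisons, and Benjamini-Hochberg step-up adjustment for
multiple comparisons.

ICC models (single measures, McGraw & Wong nomenclature):

- ``oneway``              ICC(1):  (MSB - MSW) / (MSB + (k-1) MSW)
- ``twoway_agreement``    ICC(A,1) = ICC(2,1), two-way random effects,
  absolute agreement:     (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)
- ``twoway_consistency``  ICC(C,1) = ICC(3,1): (MSR - MSE) / (MSR + (k-1) MSE)

where MSB/MSW are the one-way between/within-subject mean squares and
MSR/MSC/MSE the two-way row (subject), column (rater), and residual mean
squares.  Negative ICCs are legitimate outputs (disagreement exceeding
chance) and are reported as computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps


class ICCModel(str, Enum):
    ONEWAY = "oneway"
    TWOWAY_AGREEMENT = "twoway_agreement"
    TWOWAY_CONSISTENCY = "twoway_consistency"


class Agreement(str, Enum):
    """Qualitative interpretation bands for an ICC value."""

    NEGATIVE = "negative/no agreement"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    NEAR_PERFECT = "near-perfect"


@dataclass
class RatingsMatrix:
    """``n_subjects x k_raters`` table of expansion measurements (mm)."""

    values: np.ndarray
    subject_labels: Sequence[str] | None = None
    rater_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2D table")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.isfinite(self.values).all():
            raise ValueError("ratings must not contain missing values")


@dataclass
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    model: ICCModel
    interpretation: Agreement | None
    degenerate: bool = False


def _mean_squares(x: np.ndarray) -> dict[str, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ss_within = ss_total - ss_rows
    return {
        "msr": ss_rows / (n - 1),
        "msc": ss_cols / (k - 1),
        "mse": ss_err / ((n - 1) * (k - 1)),
        "msw": ss_within / (n * (k - 1)),
    }


def icc(
    matrix: RatingsMatrix | np.ndarray,
    model: ICCModel = ICCModel.TWOWAY_AGREEMENT,
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measures ICC with F-distribution confidence bounds.

    A matrix with zero total variance has no defined ICC: the result is
    flagged degenerate (NaN value) rather than silently reported as 1.
    """
    if not isinstance(matrix, RatingsMatrix):
        matrix = RatingsMatrix(values=matrix)
    model = ICCModel(model)
    x = matrix.values
    n, k = x.shape
    if np.allclose(x, x.mean()):
        warnings.warn("zero total variance: ICC undefined")
        return ICCResult(float("nan"), float("nan"), float("nan"), model, None, degenerate=True)
    ms = _mean_squares(x)
    msr, msc, mse, msw = ms["msr"], ms["msc"], ms["mse"], ms["msw"]

    if model is ICCModel.ONEWAY:
        value = (msr - msw) / (msr + (k - 1) * msw)
        if msw <= 0:
            lo, hi = value, value
        else:
            f = msr / msw
            f_low = f / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
            f_up = f * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
            lo = (f_low - 1) / (f_low + k - 1)
            hi = (f_up - 1) / (f_up + k - 1)
    elif model is ICCModel.TWOWAY_CONSISTENCY:
        value = (msr - mse) / (msr + (k - 1) * mse)
        if mse <= 0:
            lo, hi = value, value
        else:
            f = msr / mse
            f_low = f / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            f_up = f * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (f_low - 1) / (f_low + k - 1)
            hi = (f_up - 1) / (f_up + k - 1)
    else:  # two-way random, absolute agreement: Satterthwaite approximation
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom
        if mse <= 0 and msc <= 0:
            lo, hi = value, value
        else:
            a = (k * value) / (n * (1 - value)) if value < 1 else float("inf")
            b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else float("inf")
            if not np.isfinite(a) or not np.isfinite(b):
                lo, hi = value, value
            else:
                v_num = (a * msc + b * mse) ** 2
                v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = v_num / v_den if v_den > 0 else 1.0
                f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f_star2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (n * (msr - f_star * mse)) / (
                    f_star * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi_num = n * (f_star2 * msr - mse)
                hi_den = k * msc + (k * n - k - n) * mse + n * f_star2 * msr
                hi = hi_num / hi_den

    value = float(value)
    lo = float(min(lo, value))
    hi = float(max(hi, value))
    interp = interpret_icc(value) if -1 <= value <= 1 else None
    return ICCResult(value, lo, hi, model, interp)


def interpret_icc(value: float) -> Agreement:
    """Map an ICC value onto qualitative agreement bands.

    Bands: 0.00-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate,
    0.61-0.80 substantial, 0.81-1.00 near-perfect.  Values below zero
    (disagreement beyond chance) fall in a distinct negative category.
    """
    if not -1 <= value <= 1:
        raise ValueError(f"ICC value {value} outside [-1, 1]")
    if value < 0:
        return Agreement.NEGATIVE
    for cut, band in (
        (0.20, Agreement.SLIGHT),
        (0.40, Agreement.FAIR),
        (0.60, Agreement.MODERATE),
        (0.80, Agreement.SUBSTANTIAL),
    ):
        if value <= cut + 1e-12:
            return band
    return Agreement.NEAR_PERFECT


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_wilcoxon_sf(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W (sum of positive ranks) by dynamic programming.

    Ranks may be mid-ranks; doubling makes them integers.  The returned
    array ``counts`` has ``counts[w]`` = number of sign assignments with
    doubled statistic ``w``; it enumerates all 2^n assignments implicitly.
    """
    doubled = np.round(ranks * 2).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact by enumeration of sign assignments for up to ``exact_max_n``
    nonzero differences; a normal approximation with continuity and tie
    correction beyond.  ``zero_method='wilcox'`` (default) drops zero
    differences before ranking; ``'pratt'`` ranks them but removes their
    ranks from the statistic.  If every difference is zero the p-value is
    1 with a warning.
    """
    d = np.array([float(a) - float(b) for a, b in pairs])
    if len(d) == 0:
        raise ValueError("no pairs given")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    nz = d != 0
    if not nz.any():
        warnings.warn("all differences are zero; p = 1")
        return 1.0
    if zero_method == "wilcox":
        d = d[nz]
        ranks = sps.rankdata(np.abs(d))
    else:
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[nz]
        d = d[nz]
    w_pos = ranks[d > 0].sum()
    n = len(d)
    if n <= exact_max_n:
        counts = _exact_wilcoxon_sf(ranks)
        total = counts.sum()
        w2 = int(round(w_pos * 2))
        cdf_low = counts[: w2 + 1].sum() / total
        cdf_high = counts[w2:].sum() / total
        return float(min(1.0, 2 * min(cdf_low, cdf_high)))
    mean = ranks.sum() / 2
    var = np.sum(ranks**2) / 4
    if var == 0:
        return 1.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    return float(min(1.0, 2 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adjusted_i = min_{j >= i} (m * p_(j) / j)`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class ComparisonResult:
    """Paired position comparison for one measurement direction."""

    direction: str
    p_raw: float
    p_adjusted: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1:
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


def compare_positions(
    paired_values: dict[str, Sequence[tuple[float, float]]],
) -> list[ComparisonResult]:
    """Wilcoxon tests per direction with BH adjustment across directions."""
    directions = list(paired_values)
    p_raw = [wilcoxon_signed_rank(paired_values[d]) for d in directions]
    p_adj = bh_adjust(p_raw)
    return [
        ComparisonResult(direction=d, p_raw=float(pr), p_adjusted=float(pa),
                         n_pairs=len(paired_values[d]))
        for d, pr, pa in zip(directions, p_raw, p_adj)
    ]
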