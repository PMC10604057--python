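"""Agreement statistics: success-rate curves, Bland-Altman, Pearson agreement, ICC(2,1).

These are the validation instruments used to compare two measurement
routes for the same quantity (e.g. detector output vs ground truth, or
equation-derived vs directly measured angles): the fraction of cases
whose absolute error falls below a threshold, Bland-Altman limits of
agreement, mean-absolute-error summaries with Pearson correlation, and
the two-way random-effects absolute-agreement single-measure intraclass
correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementSummary",
    "BlandAltmanResult",
    "SuccessCurve",
    "IccResult",
    "success_rate",
    "success_curve",
    "bland_altman",
    "agreement_summary",
    "icc_2_1",
    "DEFAULT_THRESHOLD_GRID",
]

#: Default threshold grid for success curves: 0.5 to 10 degrees in 0.5 steps.
DEFAULT_THRESHOLD_GRID = np.arange(0.5, 10.01, 0.5)


@dataclass(frozen=True)
class AgreementSummary:
    """MAE / SD-of-AE / Pearson agreement between two measurement routes.

    ``r`` and ``p_value`` are ``None`` when either input has zero
    variance, in which case the correlation is undefined rather than NaN.
    """

    mae: float
    sd_ae: float
    r: Optional[float]
    r2: Optional[float]
    p_value: Optional[float]
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD)."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


@dataclass(frozen=True)
class SuccessCurve:
    """Success rate as a function of error threshold."""

    thresholds: np.ndarray
    rates: np.ndarray

    def threshold_reaching(self, rate: float) -> Optional[float]:
        """Smallest grid threshold whose success rate is >= ``rate``, or None."""
        idx = np.nonzero(self.rates >= rate)[0]
        return float(self.thresholds[idx[0]]) if idx.size else None


@dataclass(frozen=True)
class IccResult:
    """ICC(2,1) point estimate with F-based 95% CI and p-value."""

    icc: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_subjects: int
    n_raters: int


def success_rate(
    errors: Sequence[float], threshold: float, inclusive: bool = False
) -> float:
    """Fraction of cases whose error falls below ``threshold``.

    The comparison is strict (``error < threshold``) by default; pass
    ``inclusive=True`` for ``<=``.  Errors must be non-negative.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error list")
    if np.any(e < 0):
        raise ValueError("errors must be non-negative")
    hits = e <= threshold if inclusive else e < threshold
    return float(np.count_nonzero(hits)) / e.size


def success_curve(
    errors: Sequence[float],
    thresholds: Optional[Sequence[float]] = None,
    inclusive: bool = False,
) -> SuccessCurve:
    """Evaluate the success rate over a threshold grid (monotone non-decreasing)."""
    grid = np.asarray(
        DEFAULT_THRESHOLD_GRID if thresholds is None else thresholds, dtype=float
    )
    rates = np.array([success_rate(errors, t, inclusive=inclusive) for t in grid])
    return SuccessCurve(thresholds=grid, rates=rates)


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements ``x`` and ``y``.

    Differences are ``x - y``; the limits of agreement are the mean
    difference +/- 1.96 sample standard deviations (n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n=x.size,
    )


def agreement_summary(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """MAE, SD of absolute error, Pearson r, R^2 and p for paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    ae = np.abs(x - y)
    mae = float(np.mean(ae))
    sd_ae = float(np.std(ae, ddof=1))
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return AgreementSummary(mae=mae, sd_ae=sd_ae, r=None, r2=None, p_value=None, n=x.size)
    r, p = sps.pearsonr(x, y)
    return AgreementSummary(
        mae=mae, sd_ae=sd_ae, r=float(r), r2=float(r) ** 2, p_value=float(p), n=x.size
    )


def icc_2_1(
    ratings: np.ndarray, alpha: float = 0.05
) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a complete subjects x raters matrix.  The estimate is
    built from the two-way ANOVA mean squares (rows MSR, columns MSC,
    error MSE)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the standard F-based 95% confidence interval and the p-value of
    the between-subject F test (MSR/MSE).  Zero between-subject variance
    is degenerate and raises.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings matrix must be complete and finite")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((m - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise ValueError("degenerate ratings: zero total variance, ICC undefined")
    if ssr == 0.0:
        raise ValueError("degenerate ratings: zero between-subject variance")
    icc = (msr - mse) / denom

    # F-based CI (two-way random effects, absolute agreement, single measure)
    if mse == 0.0:
        # perfect within-cell agreement up to rater offsets; ICC is exact
        ci_lo, ci_hi, p = icc, icc, 0.0
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (
            k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        vd = (n - 1) * k**2 * icc**2 * fj**2 + (
            n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        v = vn / vd
        f_upper = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_lower = sps.f.ppf(1 - alpha / 2, v, n - 1)
        ci_lo = n * (msr - f_upper * mse) / (
            f_upper * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_hi = n * (f_lower * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lower * msr
        )
        f_stat = msr / mse
        p = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
        ci_lo, ci_hi = float(ci_lo), float(ci_hi)

    return IccResult(
        icc=float(icc),
        ci_lower=min(ci_lo, float(icc)),
        ci_upper=max(ci_hi, float(icc)),
        p_value=float(p),
        n_subjects=n,
        n_raters=k,
    )
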