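"""Agreement statistics between the width-based and image-based estimates.

Method comparison on paired per-leaf areas: signed percent divergence of
wA_L from iA_L, zero-intercept (through-origin) least squares, and a
paired t-test with a Shapiro-Wilk normality check on the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateRegressionError, InvalidReferenceError


@dataclass(frozen=True)
class PairedTResult:
    """Paired t-test on differences, with the normality check alongside.

    ``degenerate`` flags a zero-variance difference vector, where the t
    statistic is undefined.
    """

    t: float
    p: float
    normality_p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementReport:
    """Summary of the agreement between paired area estimates."""

    n: int
    divergences: tuple[float, ...]  # signed %, per leaf
    max_abs_divergence: float
    slope_through_origin: float
    r_squared: float
    r_squared_about_zero: float
    paired_t: float
    paired_p: float
    normality_p: float
    t_degenerate: bool


def divergence_percent(wAL: float, iAL: float) -> float:
    """Signed divergence of the width-based from the image-based estimate:
    ``100 (wA_L - iA_L) / iA_L``."""
    if not iAL > 0:
        raise InvalidReferenceError(
            f"image-based reference area must be positive, got {iAL!r}"
        )
    return 100.0 * (wAL - iAL) / iAL


def regression_through_origin(x, y) -> tuple[float, float]:
    """Zero-intercept least squares ``y = b x``.

    ``slope = sum(x y) / sum(x^2)``.  R^2 is reported about the mean of y
    (the definition under which a near-one value is informative for areas
    clustered well away from zero); see
    :func:`regression_through_origin_verbose` for the about-zero variant.
    """
    slope, r2, _ = regression_through_origin_verbose(x, y)
    return slope, r2


def regression_through_origin_verbose(x, y) -> tuple[float, float, float]:
    """Through-origin slope plus both R^2 conventions
    (about the mean of y, and about zero)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise DegenerateRegressionError(
            f"need >= 2 paired points, got {x.size} and {y.size}"
        )
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise DegenerateRegressionError("all predictor values are zero")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    ss_res = float(np.sum(resid**2))
    ss_tot_mean = float(np.sum((y - y.mean()) ** 2))
    ss_tot_zero = float(np.sum(y**2))
    r2_mean = 1.0 - ss_res / ss_tot_mean if ss_tot_mean > 0 else (1.0 if ss_res == 0 else -math.inf)
    r2_zero = 1.0 - ss_res / ss_tot_zero if ss_tot_zero > 0 else 1.0
    return slope, r2_mean, r2_zero


def paired_t_test(a, b) -> PairedTResult:
    """Two-sided paired t-test of ``a`` vs ``b`` with Shapiro-Wilk on the
    differences.  Zero difference variance yields a degenerate result
    (t undefined, flagged) rather than an exception."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired samples differ in length: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError(f"paired t-test needs n >= 3, got n = {a.size}")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTResult(
            t=math.nan, p=math.nan, normality_p=math.nan, n=a.size, degenerate=True
        )
    t, p = stats.ttest_rel(a, b)
    _, shapiro_p = stats.shapiro(diff)
    return PairedTResult(
        t=float(t), p=float(p), normality_p=float(shapiro_p), n=int(a.size)
    )


def agreement_report(wAL, iAL) -> AgreementReport:
    """Full agreement summary between paired wA_L (estimates) and iA_L
    (reference): per-leaf divergences, through-origin fit of wA_L on iA_L,
    and the paired comparison."""
    wAL = np.asarray(wAL, dtype=float)
    iAL = np.asarray(iAL, dtype=float)
    divs = tuple(divergence_percent(w, i) for w, i in zip(wAL, iAL, strict=True))
    slope, r2_mean, r2_zero = regression_through_origin_verbose(iAL, wAL)
    ttest = paired_t_test(wAL, iAL)
    return AgreementReport(
        n=int(wAL.size),
        divergences=divs,
        max_abs_divergence=max(abs(d) for d in divs),
        slope_through_origin=slope,
        r_squared=r2_mean,
        r_squared_about_zero=r2_zero,
        paired_t=ttest.t,
        paired_p=ttest.p,
        normality_p=ttest.normality_p,
        t_degenerate=ttest.degenerate,
    )
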