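"""Method-agreement statistics: Bland-Altman, ICC(2,1), through-origin
regression.

These compare paired outputs of two processing routes (e.g. automated vs
reference-mask perfusion values per AHA segment).  The ICC form is fixed to
the two-way random-effects, absolute-agreement, single-measure coefficient
ICC(2,1) — forms differ numerically, so this is stated prominently.  The
through-origin R^2 uses the no-intercept convention (total sum of squares
about zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["bland_altman", "icc_agreement", "slope_through_origin", "BlandAltmanResult"]


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    sd: float
    n: int


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the paired differences ``x - y``.

    LoA = bias +/- 1.96 sd (sample sd, n-1 denominator).  The bias CI uses
    the t distribution; each LoA CI uses the ``sd sqrt(3/n)`` normal
    approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - 1.96 * sd
    loa_high = bias + 1.96 * sd
    t = stats.t.ppf(0.975, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_low=(loa_low - 1.96 * se_loa, loa_low + 1.96 * se_loa),
        ci_loa_high=(loa_high - 1.96 * se_loa, loa_high + 1.96 * se_loa),
        sd=sd,
        n=n,
    )


def icc_agreement(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Returns ``(icc, ci_low, ci_high)`` with the standard F-based 95%
    confidence interval.  ``x`` and ``y`` are the two raters' values over
    the same subjects.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    data = np.stack([x, y], axis=1)  # n subjects x k raters
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based interval for ICC(A,1)
    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        denom_l = f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        lower = n * (msr - f_l * mse) / denom_l
        denom_u = k * msc + (k * n - k - n) * mse + n * f_u * msr
        upper = n * (f_u * msr - mse) / denom_u
    else:
        lower = upper = 1.0
    return float(icc), float(lower), float(upper)


def slope_through_origin(x, y) -> tuple[float, float]:
    """No-intercept least-squares slope and its R^2.

    ``slope = sum(xy)/sum(x^2)``; ``R^2 = 1 - sum((y - slope x)^2)/sum(y^2)``
    (total sum of squares about zero, the no-intercept convention).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1D arrays with n >= 2")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all-zero x")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    r2 = 1.0 - float(np.sum((y - slope * x) ** 2)) / syy if syy > 0 else 1.0
    return slope, float(r2)
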