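"""Method-comparison statistics for assay cross-validation.

Free eculizumab concentrations and classical-pathway (CP) activity were
each measured by two different ELISAs in this problem domain; agreement
between paired methods is assessed with Passing-Bablok regression (a
nonparametric, rank-based errors-in-both-variables regression) and
Bland-Altman limits of agreement.  A fixed linear conversion maps
"in-house" CP ELISA values onto the Wieslab ELISA scale
(``CP_inhouse = 6.33 + 1.05 * CP_wieslab``) before modelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["PairedMeasurements", "MethodComparisonResult",
           "passing_bablok", "bland_altman", "convert_cp_inhouse_to_wieslab"]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired values of the same quantity by two methods."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, float))
        object.__setattr__(self, "y", np.asarray(self.y, float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("missing/non-finite pairs are not allowed")


@dataclass(frozen=True)
class MethodComparisonResult:
    slope: float | None = None
    intercept: float | None = None
    slope_ci_95: tuple[float, float] | None = None
    intercept_ci_95: tuple[float, float] | None = None
    bias: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All pairwise slopes S_ij = (y_j - y_i)/(x_j - x_i), i < j.

    Following the original algorithm, slopes exactly equal to -1 are
    discarded and vertical pairs (dx = 0, dy != 0) count as +/-inf with
    the sign of dy; identical points contribute nothing.
    """
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = ~((dx == 0) & (dy == 0))
    dx, dy = dx[keep], dy[keep]
    s = np.where(dy > 0, np.inf, -np.inf)
    nz = dx != 0
    s[nz] = dy[nz] / dx[nz]
    return s[s != -1.0]


def passing_bablok(data: PairedMeasurements,
                   confidence: float = 0.95) -> MethodComparisonResult:
    """Passing-Bablok regression of method B (y) on method A (x).

    The slope is the offset median of the pairwise slopes (the offset K is
    the number of slopes below -1, making the estimator invariant to
    swapping the methods); the intercept is ``median(y - slope*x)``.
    Confidence bounds are the distribution-free rank-based intervals of
    the original procedure.
    """
    x, y = data.x, data.y
    n = x.size
    if n < 3:
        raise ValueError("Passing-Bablok regression needs at least 3 pairs")
    if np.all(x == x[0]):
        raise ValueError("degenerate data: all x identical")
    s = np.sort(_pairwise_slopes(x, y))
    big_n = s.size
    if big_n == 0:
        raise ValueError("degenerate data: no valid pairwise slopes")
    k = int(np.sum(s < -1.0))
    # offset median (1-indexed ranks shifted by K)
    if big_n % 2 == 1:
        slope = s[(big_n + 1) // 2 + k - 1]
    else:
        slope = 0.5 * (s[big_n // 2 + k - 1] + s[big_n // 2 + k])
    w = norm.ppf(0.5 + confidence / 2.0)
    c = w * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - c) / 2.0))
    m2 = big_n - m1 + 1
    lo = s[max(m1 + k - 1, 0)]
    hi = s[min(m2 + k - 1, big_n - 1)]
    intercept = float(np.median(y - slope * x))
    a_from_hi = float(np.median(y - hi * x))
    a_from_lo = float(np.median(y - lo * x))
    i_lo, i_hi = sorted((a_from_hi, a_from_lo))
    return MethodComparisonResult(slope=float(slope), intercept=intercept,
                                  slope_ci_95=(float(lo), float(hi)),
                                  intercept_ci_95=(i_lo, i_hi))


def bland_altman(data: PairedMeasurements) -> MethodComparisonResult:
    """Bland-Altman agreement: bias and 95% limits of agreement."""
    x, y = data.x, data.y
    if x.size < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return MethodComparisonResult(bias=bias,
                                  loa_low=bias - 1.96 * sd,
                                  loa_high=bias + 1.96 * sd)


# CP_inhouse = 6.33 + 1.05 * CP_wieslab  (Passing-Bablok cross-calibration)
_CP_INTERCEPT = 6.33
_CP_SLOPE = 1.05


def convert_cp_inhouse_to_wieslab(cp_inhouse):
    """Convert in-house CP ELISA activity (%) to the Wieslab ELISA scale.

    Inverts the fixed cross-calibration line; negative results are clipped
    to zero with a warning.  Accepts scalars or arrays.
    """
    cp = np.asarray(cp_inhouse, dtype=float)
    if np.any(cp < 0):
        raise ValueError("CP activity must be non-negative")
    out = (cp - _CP_INTERCEPT) / _CP_SLOPE
    if np.any(out < 0):
        warnings.warn("converted CP activity below 0 clipped to 0")
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out
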