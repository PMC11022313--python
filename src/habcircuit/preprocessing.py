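"""Per-trace cleanup: median filter, background subtraction, polynomial
detrend, z-scoring, rolling smoothing — in that fixed order.

All operations are length-preserving and deterministic; edge handling uses
reflection (median filter) or shrinking windows (rolling mean) so the
stimulus alignment never shifts.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "median_filter_trace", "subtract_background", "detrend_poly", "zscore",
    "rolling_smooth", "DegenerateTraceError", "TracePreprocessor",
]


class DegenerateTraceError(ValueError):
    """A trace has zero variance and cannot be z-scored."""


def _as1d(trace) -> np.ndarray:
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D trace")
    return x


def median_filter_trace(trace, width: int = 3) -> np.ndarray:
    """Sliding median of odd ``width``; edges handled by reflection."""
    x = _as1d(trace)
    width = int(width)
    if width % 2 == 0:
        raise ValueError("median filter width must be odd")
    if width < 1 or width > x.size:
        raise ValueError("median filter width must be in [1, len(trace)]")
    return median_filter(x, size=width, mode="reflect")


def subtract_background(trace, background) -> np.ndarray:
    """Subtract a scalar or per-timepoint background series."""
    x = _as1d(trace)
    bg = np.asarray(background, dtype=float)
    if bg.ndim == 0:
        return x - float(bg)
    if bg.shape != x.shape:
        raise ValueError(f"background length {bg.size} != trace length {x.size}")
    return x - bg


def detrend_poly(trace, order: int | None = None, allow_any_order: bool = False) -> np.ndarray:
    """Subtract a least-squares polynomial fit over the sample index axis.

    ``order`` must lie in [2, 5] (override with ``allow_any_order``, logged).
    When ``order`` is None, the order in {2..5} minimising the BIC of the
    polynomial fit is chosen per trace.
    """
    x = _as1d(trace)
    if order is None:
        order = _select_detrend_order(x)
        logger.debug("detrend_poly: BIC-selected order %d", order)
    order = int(order)
    if not 2 <= order <= 5:
        if not allow_any_order:
            raise ValueError("detrend order must be in [2, 5] "
                             "(pass allow_any_order=True to override)")
        logger.warning("detrend_poly: using out-of-range order %d", order)
    if x.size <= order + 1:
        raise ValueError("trace too short for requested polynomial order")
    t = np.arange(x.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, x, order)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def _select_detrend_order(x: np.ndarray, orders=range(2, 6)) -> int:
    n = x.size
    t = np.arange(n, dtype=float)
    best, best_bic = None, np.inf
    for p in orders:
        if n <= p + 1:
            break
        c = np.polynomial.polynomial.polyfit(t, x, p)
        resid = x - np.polynomial.polynomial.polyval(t, c)
        rss = float(np.sum(resid ** 2))
        # Gaussian BIC with p+1 regression coefficients
        bic = n * np.log(max(rss / n, 1e-300)) + (p + 1) * np.log(n)
        if bic < best_bic:
            best, best_bic = p, bic
    return best


def zscore(trace, ddof: int = 0) -> np.ndarray:
    """Standardise to mean 0, sd 1 (population sd by default)."""
    x = _as1d(trace)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateTraceError("zero-variance trace cannot be z-scored")
    return (x - x.mean()) / sd


def rolling_smooth(trace, window: int = 3) -> np.ndarray:
    """Centred moving average; the window shrinks at the edges.

    Output[i] is the mean of samples within ``window // 2`` of i that lie
    inside the trace, so the output has the same length as the input and a
    window of 1 is the identity.
    """
    x = _as1d(trace)
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError("window larger than trace")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


class TracePreprocessor(TransformerMixin, BaseEstimator):
    """Transformer applying the full cleanup pipeline row-wise.

    Order is fixed: median filter -> background subtraction -> polynomial
    detrend -> z-score -> rolling smoothing.  Cells whose trace is constant
    (zero variance at the z-score step) are either dropped with a log message
    (``on_degenerate='drop'``) or raise (``'raise'``).

    Parameters
    ----------
    median_width : odd int, default 3
    background : scalar or per-timepoint array, default 0.0
    detrend_order : int in [2, 5] or None (per-trace BIC selection), default 2
    smooth_window : int >= 1, default 3
    on_degenerate : {'raise', 'drop'}, default 'raise'

    Attributes
    ----------
    kept_mask_ : boolean array over input rows after the last ``transform``
        (False where a degenerate trace was dropped).
    """

    _steps = ("median", "background", "detrend", "zscore", "smooth")

    def __init__(self, median_width: int = 3, background=0.0,
                 detrend_order: int | None = 2, smooth_window: int = 3,
                 on_degenerate: str = "raise"):
        self.median_width = median_width
        self.background = background
        self.detrend_order = detrend_order
        self.smooth_window = smooth_window
        self.on_degenerate = on_degenerate

    def fit(self, X, y=None):
        if self.median_width % 2 == 0:
            raise ValueError("median_width must be odd")
        if self.detrend_order is not None and not 2 <= self.detrend_order <= 5:
            raise ValueError("detrend_order must be in [2, 5] or None")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.on_degenerate not in ("raise", "drop"):
            raise ValueError("on_degenerate must be 'raise' or 'drop'")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.n_features_in_ = X.shape[1]
        return self

    def transform_trace(self, trace) -> np.ndarray:
        x = median_filter_trace(trace, self.median_width)
        x = subtract_background(x, self.background)
        x = detrend_poly(x, self.detrend_order)
        x = zscore(x)
        return rolling_smooth(x, self.smooth_window)

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        rows, kept = [], []
        for i in range(X.shape[0]):
            try:
                rows.append(self.transform_trace(X[i]))
                kept.append(True)
            except DegenerateTraceError:
                if self.on_degenerate == "raise":
                    raise
                logger.warning("dropping degenerate (zero-variance) trace %d", i)
                kept.append(False)
        self.kept_mask_ = np.array(kept, dtype=bool)
        logger.info("preprocessing order: %s", " -> ".join(self._steps))
        return np.vstack(rows) if rows else np.empty((0, X.shape[1]))
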