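"""Time-series preprocessing: linear detrend + demean per region.

Both causal analyses operate on detrended, mean-removed ROI series; this
is the shared entry point.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import ROITimeSeries

__all__ = ["preprocess_timeseries", "detrend_demean"]


def detrend_demean(x: np.ndarray) -> np.ndarray:
    """Remove a least-squares linear trend and the mean from each column."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    A = np.column_stack([np.ones(n), t - t.mean()])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - A @ coef


def preprocess_timeseries(ts: ROITimeSeries) -> ROITimeSeries:
    """Detrend and demean every region series.

    Constant regions come back as zero series with a degenerate-input
    warning. The operation is a projection, hence idempotent.
    """
    const = np.ptp(ts.values, axis=0) == 0
    if const.any():
        bad = [ts.region_names[i] for i in np.flatnonzero(const)]
        warnings.warn(f"constant region series (degenerate input): {bad}")
    return ROITimeSeries(detrend_demean(ts.values), ts.region_names, ts.tr,
                         ts.subject_id, ts.group_label)
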