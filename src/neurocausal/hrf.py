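"""Hemodynamic response function (HRF) bases.

The BOLD signal is modelled as a linear convolution of a latent neuronal
signal with a region-specific HRF, expressed in a small basis: the canonical
double-gamma response plus its temporal derivative. A region's HRF is then
``b.T @ basis_matrix`` for a per-region weight vector ``b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["HRFBasis", "canonical_hrf", "build_hrf_basis"]

# double-gamma shape: response peak 6 s, undershoot peak 16 s,
# unit dispersions, peak/undershoot amplitude ratio 6 (SPM convention)
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDERSHOOT_DISP = 1.0
_RATIO = 6.0
_DERIV_DT = 0.1  # s, finite-difference step for the temporal derivative


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Normalised so that the peak value is 1. Zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, _PEAK_DELAY / _PEAK_DISP, scale=_PEAK_DISP)
    under = stats.gamma.pdf(t, _UNDERSHOOT_DELAY / _UNDERSHOOT_DISP, scale=_UNDERSHOOT_DISP)
    h = peak - under / _RATIO
    # normalize by the analytic peak on a fine grid (stable across TR choices)
    tf = np.arange(0.0, 32.0, 0.01)
    hf = stats.gamma.pdf(tf, _PEAK_DELAY, scale=_PEAK_DISP) - stats.gamma.pdf(
        tf, _UNDERSHOOT_DELAY, scale=_UNDERSHOOT_DISP) / _RATIO
    h = h / hf.max()
    return np.where(t >= 0, h, 0.0)


@dataclass(frozen=True)
class HRFBasis:
    """B x L matrix of HRF basis functions sampled on the lag grid.

    Rows are basis functions over ``n_lags`` lags spaced ``tr`` seconds
    apart (lag 0 first). Row 0 is the canonical double-gamma response, row 1
    its temporal derivative.
    """

    basis_matrix: np.ndarray
    tr: float
    warnings_: tuple = field(default_factory=tuple)

    def __post_init__(self):
        bm = np.asarray(self.basis_matrix, dtype=float)
        if bm.ndim != 2 or bm.shape[0] < 1:
            raise ValueError("basis_matrix must be a B x L matrix with B >= 1")
        if not np.all(np.isfinite(bm)):
            raise ValueError("basis_matrix must be finite")
        if np.linalg.matrix_rank(bm) < bm.shape[0]:
            raise ValueError("basis rows must be linearly independent")
        object.__setattr__(self, "basis_matrix", bm)

    @property
    def n_bases(self) -> int:
        return self.basis_matrix.shape[0]

    @property
    def n_lags(self) -> int:
        return self.basis_matrix.shape[1]

    @property
    def lag_times(self) -> np.ndarray:
        return np.arange(self.n_lags) * self.tr


def build_hrf_basis(tr: float, n_lags: int | None = None) -> HRFBasis:
    """Canonical + temporal-derivative HRF basis on a TR-spaced lag grid.

    Parameters
    ----------
    tr : sampling interval in seconds (> 0).
    n_lags : number of lags; defaults to ``ceil(32 s / tr)`` so the full
        HRF support (peak at ~6 s, undershoot out to ~30 s) is covered.
        A grid too short to reach the peak yields a warning recorded on
        the returned object.
    """
    if tr <= 0:
        raise ValueError(f"TR must be positive, got {tr}")
    if n_lags is None:
        n_lags = int(np.ceil(32.0 / tr))
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    t = np.arange(n_lags) * tr
    canon = canonical_hrf(t)
    deriv = (canonical_hrf(t) - canonical_hrf(t - _DERIV_DT)) / _DERIV_DT
    warns: list[str] = []
    if n_lags * tr < _PEAK_DELAY + 2.0:
        msg = (f"HRF basis support {n_lags * tr:.1f}s does not cover the "
               f"canonical peak (~{_PEAK_DELAY:.0f}s); onset/weight estimates "
               "will be unreliable")
        warnings.warn(msg)
        warns.append(msg)
    return HRFBasis(basis_matrix=np.vstack([canon, deriv]), tr=tr,
                    warnings_=tuple(warns))
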