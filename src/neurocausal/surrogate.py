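"""Surrogate time series for empirical null distributions.

Surrogates preserve each region's amplitude spectrum (hence its
autocorrelation and variance) while randomizing phases independently per
region, which destroys every cross-region temporal dependence. Used to
build the null distribution of causal-edge statistics under "no causal
interactions between regions".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ROITimeSeries

__all__ = ["NullDistribution", "phase_randomize", "surrogate_cohort",
           "SURROGATE_METHODS"]


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent-phase surrogate of each column of ``x``.

    The amplitude spectrum of every column is kept exactly; phases are
    drawn i.i.d. uniform per column, with the symmetry required for a real
    signal. Column variance is therefore preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    X = np.fft.rfft(x, axis=0)
    nf = X.shape[0]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(nf, x.shape[1]))
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    return np.fft.irfft(np.abs(X) * np.exp(1j * phases), n=n, axis=0)


def _aaft(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-adjusted Fourier transform surrogate per column."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        g = rng.standard_normal(len(col))
        g_sorted = np.sort(g)
        ranks = np.argsort(np.argsort(col))
        y = g_sorted[ranks]                       # Gaussianized series
        y_surr = phase_randomize(y[:, None], rng)[:, 0]
        ranks2 = np.argsort(np.argsort(y_surr))
        out[:, j] = np.sort(col)[ranks2]          # restore amplitudes
    return out


SURROGATE_METHODS = {"phase": phase_randomize, "aaft": _aaft}


def surrogate_cohort(
    cohort: list[ROITimeSeries],
    rng: np.random.Generator,
    method: str = "phase",
) -> list[ROITimeSeries]:
    """One surrogate copy of every subject's time series."""
    try:
        fn = SURROGATE_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown surrogate method '{method}'; supported: "
            f"{sorted(SURROGATE_METHODS)}") from None
    return [ROITimeSeries(fn(ts.values, rng), ts.region_names, ts.tr,
                          ts.subject_id, ts.group_label) for ts in cohort]


@dataclass
class NullDistribution:
    """Empirical distribution of a per-edge statistic under surrogates.

    ``values`` has shape (n_surrogates, M, M) in the row-=-target
    convention; entry [k, m, n] is surrogate k's statistic for edge n->m.
    """

    statistic_name: str
    values: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValueError("values must be (n_surrogates, M, M)")
        if v.shape[0] < 100:
            raise ValueError(
                f"need at least 100 surrogates, got {v.shape[0]}")
        self.values = v

    @property
    def n_surrogates(self) -> int:
        return self.values.shape[0]
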