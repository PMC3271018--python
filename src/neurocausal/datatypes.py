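"""Core data containers.

Matrix orientation convention, used for every M x M connection, influence
or strength matrix in this package: entry ``(m, n)`` is the strength of the
directed influence of region ``n`` on region ``m`` (row = target,
column = source). All I/O routines document and preserve this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "MDSParameters",
    "validate_behavior_table",
    "validate_structural_table",
]


@dataclass
class ROITimeSeries:
    """Per-subject BOLD signal matrix of shape (time, region)."""

    values: np.ndarray
    region_names: tuple[str, ...]
    tr: float
    subject_id: str = "sub-00"
    group_label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a (time, region) matrix")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains missing or non-finite samples")
        names = tuple(self.region_names)
        if len(names) != v.shape[1]:
            raise ValueError("region_names length must match the number of columns")
        if len(set(names)) != len(names):
            raise ValueError("region_names must be unique")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        self.values = v
        self.region_names = names

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def reorder(self, region_names: tuple[str, ...]) -> "ROITimeSeries":
        """Return a copy with columns permuted to the given region order."""
        if set(region_names) != set(self.region_names):
            raise ValueError("region sets differ; cannot reorder")
        idx = [self.region_names.index(r) for r in region_names]
        return ROITimeSeries(self.values[:, idx], tuple(region_names),
                             self.tr, self.subject_id, self.group_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.region_names))


@dataclass
class MDSParameters:
    """Parameters of the bilinear latent dynamics + HRF observation model.

    Latent dynamics: s(t) = sum_j v_j(t) C_j s(t-1) + D u(t) + w(t),
    w ~ N(0, Q). Observation: y_m(t) = b_m' Phi x_m(t) + e_m(t) with
    x_m(t) the embedding_lags past values of s_m and Phi the HRF basis.

    ``modulatory_matrices[j][m, n]`` is the causal strength of region n on
    region m under modulatory input j.
    """

    n_regions: int
    modulatory_matrices: np.ndarray  # (J, M, M)
    input_strengths: np.ndarray      # (M,) diagonal of D
    state_noise_cov: np.ndarray      # (M, M)
    hrf_basis_weights: np.ndarray    # (M, B)
    obs_noise_var: np.ndarray        # (M,)
    embedding_lags: int = 16

    def __post_init__(self):
        M = self.n_regions
        C = np.atleast_3d(np.asarray(self.modulatory_matrices, dtype=float))
        if C.ndim == 3 and C.shape[1:] != (M, M):
            if C.shape == (M, M, 1):  # single matrix passed as 2-D
                C = np.moveaxis(C, -1, 0)
            else:
                raise ValueError(f"modulatory matrices must be (J, {M}, {M})")
        self.modulatory_matrices = C
        D = np.asarray(self.input_strengths, dtype=float)
        if D.ndim == 2:
            D = np.diag(D)
        if D.shape != (M,):
            raise ValueError("input_strengths must give M diagonal entries")
        self.input_strengths = D
        Q = np.asarray(self.state_noise_cov, dtype=float)
        if Q.shape != (M, M):
            raise ValueError("state_noise_cov must be M x M")
        if not np.allclose(Q, Q.T, atol=1e-10):
            raise ValueError("state_noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(Q)) < -1e-10:
            raise ValueError("state_noise_cov must be positive semi-definite")
        self.state_noise_cov = Q
        b = np.atleast_2d(np.asarray(self.hrf_basis_weights, dtype=float))
        if b.shape[0] != M:
            raise ValueError("hrf_basis_weights must have one row per region")
        self.hrf_basis_weights = b
        r = np.broadcast_to(np.asarray(self.obs_noise_var, dtype=float), (M,)).copy()
        if np.any(r < 0):
            raise ValueError("obs_noise_var must be >= 0")
        self.obs_noise_var = r
        if self.embedding_lags < 1:
            raise ValueError("embedding_lags must be >= 1")
        for j, Cj in enumerate(self.modulatory_matrices):
            rho = np.max(np.abs(np.linalg.eigvals(Cj)))
            if rho >= 1.0:
                raise ValueError(
                    f"modulatory matrix {j} has spectral radius {rho:.3f} >= 1; "
                    "the simulated latent process would be non-stationary")

    @property
    def n_modulatory(self) -> int:
        return self.modulatory_matrices.shape[0]


_BEHAVIOR_COLS = {"subject_id", "group", "reaction_time", "accuracy"}
_STRUCT_COLS = {"subject_id", "group", "region_a", "region_b", "fiber_density", "mean_fa"}


def validate_behavior_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a per-subject behavior table (RT in ms, accuracy in [0, 1])."""
    missing = _BEHAVIOR_COLS - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    if (df["accuracy"] < 0).any() or (df["accuracy"] > 1).any():
        raise ValueError("accuracy must lie in [0, 1]")
    if (df["reaction_time"] <= 0).any():
        raise ValueError("reaction_time must be positive")
    return df


def validate_structural_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a per-subject, per-region-pair structural connectivity table."""
    missing = _STRUCT_COLS - set(df.columns)
    if missing:
        raise ValueError(f"structural table missing columns: {sorted(missing)}")
    if (df["mean_fa"] < 0).any() or (df["mean_fa"] > 1).any():
        raise ValueError("mean_fa must lie in [0, 1]")
    if (df["fiber_density"] < 0).any():
        raise ValueError("fiber_density must be >= 0")
    return df
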