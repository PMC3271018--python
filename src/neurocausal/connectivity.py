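"""Instantaneous functional connectivity and structure-function coupling.

Functional connectivity is the Pearson correlation between region pairs
after removing linear drift and user-supplied confound regressors. Group
comparisons run on Fisher-z transformed correlations; structure-function
coupling correlates a per-subject edge measure (FC r or causal strength)
with fiber density or mean FA across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ROITimeSeries, validate_structural_table

__all__ = ["functional_connectivity", "compare_fc_groups",
           "structure_function_correlation", "compare_structural"]


def functional_connectivity(ts: ROITimeSeries,
                            confounds: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Pearson correlation after drift + confound regression.

    Confounds (time x k), when given, are regressed out of every region
    series together with an intercept and linear drift before correlating.
    """
    x = ts.values
    n = x.shape[0]
    t = np.arange(n, dtype=float)
    reg = [np.ones(n), t - t.mean()]
    if confounds is not None:
        c = np.atleast_2d(np.asarray(confounds, dtype=float))
        if c.shape[0] != n:
            c = c.T
        if c.shape[0] != n:
            raise ValueError("confounds must have the same length as the series")
        reg.extend(c.T)
    A = np.column_stack(reg)
    beta, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ beta
    sd = resid.std(axis=0)
    degenerate = sd <= 1e-10 * np.maximum(x.std(axis=0), 1.0)
    if np.any(degenerate):
        bad = [ts.region_names[i] for i in np.flatnonzero(degenerate)]
        raise ValueError(f"constant series after residualization: {bad}; "
                         "correlation undefined")
    fc = np.corrcoef(resid.T)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


def compare_fc_groups(fcA: list[np.ndarray] | np.ndarray,
                      fcB: list[np.ndarray] | np.ndarray,
                      region_names: tuple[str, ...],
                      alpha: float = 0.01) -> pd.DataFrame:
    """Per-pair two-sample test on Fisher-z correlations, BH-FDR corrected.

    Positive ``mean_diff`` means group A exceeds group B on that pair.
    """
    A = np.asarray(fcA)
    B = np.asarray(fcB)
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    M = A.shape[1]
    rows = []
    for i in range(M):
        for j in range(i + 1, M):
            za, zb = _fisher_z(A[:, i, j]), _fisher_z(B[:, i, j])
            if np.ptp(za) == 0 and np.ptp(zb) == 0 and za.mean() == zb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(za, zb)
            rows.append({"region_a": region_names[i], "region_b": region_names[j],
                         "mean_diff": float(np.tanh(za.mean()) - np.tanh(zb.mean())),
                         "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    rej, q, *_ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["significant"] = rej
    return df


def structure_function_correlation(
    functional: pd.Series | np.ndarray,
    structure: pd.DataFrame,
    edge: tuple[str, str],
    measure: str = "fiber_density",
    subject_ids: list | None = None,
) -> tuple[float, float]:
    """Across-subject Pearson correlation between a functional edge
    measure and a structural measure (fiber density or mean FA).

    ``functional`` is indexed by subject_id (a Series, or an array paired
    with ``subject_ids``). Returns (r, p).
    """
    validate_structural_table(structure)
    a, b = edge
    sel = structure[((structure["region_a"] == a) & (structure["region_b"] == b))
                    | ((structure["region_a"] == b) & (structure["region_b"] == a))]
    sc = sel.set_index("subject_id")[measure]
    if isinstance(functional, pd.Series):
        f = functional
    else:
        if subject_ids is None:
            raise ValueError("subject_ids required when functional is an array")
        f = pd.Series(np.asarray(functional, dtype=float), index=subject_ids)
    common = f.index.intersection(sc.index)
    if len(common) < 5:
        raise ValueError(f"need >= 5 subjects with both measures, got {len(common)}")
    fv, sv = f[common].to_numpy(float), sc[common].to_numpy(float)
    if np.ptp(fv) == 0 or np.ptp(sv) == 0:
        raise ValueError("zero-variance measure: correlation undefined")
    r, p = stats.pearsonr(fv, sv)
    return float(r), float(p)


def compare_structural(structure: pd.DataFrame, edge: tuple[str, str],
                       groups: tuple[str, str] = ("adult", "child")
                       ) -> pd.DataFrame:
    """Two-sample group tests on fiber density and mean FA for one edge."""
    validate_structural_table(structure)
    a, b = edge
    sel = structure[((structure["region_a"] == a) & (structure["region_b"] == b))
                    | ((structure["region_a"] == b) & (structure["region_b"] == a))]
    rows = []
    for measure in ("fiber_density", "mean_fa"):
        ga = sel.loc[sel["group"] == groups[0], measure].to_numpy(float)
        gb = sel.loc[sel["group"] == groups[1], measure].to_numpy(float)
        if len(ga) < 3 or len(gb) < 3:
            raise ValueError("need at least 3 subjects per group")
        if np.ptp(ga) == 0 and np.ptp(gb) == 0 and ga.mean() == gb.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(ga, gb)
        rows.append({"measure": measure, "mean_a": ga.mean(), "mean_b": gb.mean(),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)
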