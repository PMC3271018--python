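"""Multivariate Granger causal analysis (MGCA).

Causal influence of region x on region y, conditional on all other
regions, is quantified by the log ratio of residual variances between the
vector-autoregressive model omitting x's lags when predicting y (reduced)
and the full model: F_{x->y} = ln(var_reduced / var_full) >= 0. The
difference-of-influence statistic doi = F_{x->y} - F_{y->x} assigns net
causal direction by its sign. Group inference compares mean statistics
against phase-randomized surrogate nulls with BH-FDR across edges.

Matrix convention: entry (m, n) of every influence/doi matrix refers to
the ordered edge n -> m (row = target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import ROITimeSeries
from .inference import CausalGraph, difference_null, edge_inference
from .surrogate import NullDistribution, surrogate_cohort

__all__ = ["VARFit", "GrangerCausality", "fit_var", "influence_terms",
           "doi_matrix", "surrogate_null_granger", "group_causal_graph",
           "compare_groups_doi", "select_var_order"]


@dataclass
class VARFit:
    """Least-squares VAR fit with per-target reduced-model variances.

    ``coefs[l]`` is the lag-(l+1) coefficient matrix, row = target.
    ``reduced_var[m, n]`` is region m's residual variance when region n's
    lags are omitted from its predictors (conditional on all others);
    its diagonal holds the full-model variances.
    """

    order: int
    coefs: np.ndarray            # (order, M, M)
    resid_cov: np.ndarray        # (M, M)
    full_var: np.ndarray         # (M,)
    reduced_var: np.ndarray      # (M, M)

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if np.any(self.full_var <= 0):
            raise ValueError("residual variances must be positive")
        # nesting: removing a predictor cannot reduce residual variance
        slack = self.reduced_var - self.full_var[:, None]
        if np.min(slack + 1e-9 * np.abs(self.full_var[:, None])) < 0:
            raise ValueError("reduced-model variance below full-model variance")


def _lagged(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Response rows and stacked lag predictors [x(t-1) ... x(t-p)]."""
    T = x.shape[0]
    Y = x[order:]
    X = np.hstack([x[order - l - 1:T - l - 1] for l in range(order)])
    return Y, X


def _resid_var(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    r = Y - X @ beta
    return (r ** 2).mean(axis=0)


def fit_var(ts: ROITimeSeries | np.ndarray, order: int = 1) -> VARFit:
    """Fit the full VAR and every leave-one-source-out reduced VAR.

    Requires length > 10 * order * M for identifiability; duplicated
    (perfectly collinear) regions are rejected rather than silently
    producing unstable estimates.
    """
    x = ts.values if isinstance(ts, ROITimeSeries) else np.asarray(ts, float)
    T, M = x.shape
    min_len = 10 * order * M
    if T <= min_len:
        raise ValueError(
            f"series length {T} too short for VAR({order}) on {M} regions; "
            f"need more than {min_len} samples")
    cc = np.corrcoef(x.T)
    iu = np.triu_indices(M, 1)
    if np.any(np.abs(cc[iu]) > 1 - 1e-10):
        raise ValueError("duplicated (perfectly collinear) region series")
    Y, X = _lagged(x, order)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    # beta rows are ordered lag-major: [lag1 all regions, lag2 ...]
    coefs = beta.reshape(order, M, M).transpose(0, 2, 1)
    resid_cov = np.cov(resid.T, bias=True)
    full_var = (resid ** 2).mean(axis=0)
    reduced_var = np.tile(full_var[:, None], (1, M))
    for n in range(M):
        keep = np.ones(order * M, dtype=bool)
        for l in range(order):
            keep[l * M + n] = False
        rv = _resid_var(Y, X[:, keep])
        reduced_var[:, n] = rv
        reduced_var[n, n] = full_var[n]
    return VARFit(order=order, coefs=coefs, resid_cov=np.atleast_2d(resid_cov),
                  full_var=full_var,
                  reduced_var=np.maximum(reduced_var, full_var[:, None]))


def influence_terms(ts: ROITimeSeries | np.ndarray, order: int = 1) -> np.ndarray:
    """Conditional Granger influence matrix F, F[m, n] = F_{n->m} >= 0."""
    fit = fit_var(ts, order)
    F = np.log(fit.reduced_var / fit.full_var[:, None])
    np.fill_diagonal(F, 0.0)
    return np.maximum(F, 0.0)


def doi_matrix(F: np.ndarray) -> np.ndarray:
    """Difference-of-influence: doi = F - F.T, exactly antisymmetric.

    doi[m, n] > 0 means the net influence runs n -> m.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("influence matrix must be finite")
    return F - F.T


def select_var_order(ts: ROITimeSeries | np.ndarray, max_order: int = 6) -> int:
    """BIC order selection for the full VAR."""
    x = ts.values if isinstance(ts, ROITimeSeries) else np.asarray(ts, float)
    T, M = x.shape
    best, best_bic = 1, np.inf
    for p in range(1, max_order + 1):
        if T <= 10 * p * M:
            break
        Y, X = _lagged(x, p)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        sigma = np.cov(resid.T, bias=True)
        n_eff = Y.shape[0]
        sign, logdet = np.linalg.slogdet(np.atleast_2d(sigma))
        bic = n_eff * logdet + p * M * M * np.log(n_eff)
        if bic < best_bic:
            best, best_bic = p, bic
    return best


class GrangerCausality(BaseEstimator):
    """Per-subject conditional Granger influence estimator.

    Parameters
    ----------
    order : VAR lag order (default 1, appropriate at TR-scale sampling).

    Attributes (after ``fit``)
    ----------
    var_fit_ : VARFit for the subject.
    influence_ : (M, M) conditional influence matrix F (row = target).
    doi_ : antisymmetric difference-of-influence matrix.
    """

    def __init__(self, order: int = 1):
        self.order = order

    def fit(self, ts: ROITimeSeries | np.ndarray, y=None) -> "GrangerCausality":
        self.var_fit_ = fit_var(ts, self.order)
        self.influence_ = influence_terms(ts, self.order)
        self.doi_ = doi_matrix(self.influence_)
        return self


def _group_mean_stat(cohort: list[ROITimeSeries], order: int,
                     statistic: str) -> np.ndarray:
    mats = []
    for ts in cohort:
        F = influence_terms(ts, order)
        mats.append(doi_matrix(F) if statistic == "doi" else F)
    return np.mean(mats, axis=0)


def surrogate_null_granger(
    cohort: list[ROITimeSeries],
    order: int = 1,
    n_surrogates: int = 199,
    method: str = "phase",
    seed: int | None = 0,
    statistic: str = "doi",
) -> NullDistribution:
    """Null distribution of the group-mean influence statistic.

    Each surrogate phase-randomizes every subject independently and
    recomputes the group-mean statistic (doi by default, or F).
    """
    if statistic not in ("doi", "F"):
        raise ValueError("statistic must be 'doi' or 'F'")
    rng = np.random.default_rng(seed)
    vals = np.empty((n_surrogates, cohort[0].n_regions, cohort[0].n_regions))
    for k in range(n_surrogates):
        surr = surrogate_cohort(cohort, rng, method=method)
        vals[k] = _group_mean_stat(surr, order, statistic)
    return NullDistribution(statistic_name=statistic, values=vals,
                            method=method, seed=seed)


def group_causal_graph(
    cohort: list[ROITimeSeries],
    order: int,
    null: NullDistribution,
    alpha: float = 0.01,
    fdr: bool = True,
) -> CausalGraph:
    """Significant directed edges from group-mean doi vs the surrogate null.

    An edge n -> m is kept when doi[m, n] > 0 and its one-sided empirical
    p-value survives BH-FDR at ``alpha`` (ties doi = 0 yield no edge).
    """
    if len(cohort) < 3:
        warnings.warn(f"group has only {len(cohort)} subject(s); "
                      "group inference is unreliable below 3")
    stat = _group_mean_stat(cohort, order, null.statistic_name)
    return edge_inference(cohort[0].region_names, stat, null, alpha=alpha,
                          fdr=fdr, alternative="greater",
                          require_positive=True, method="mgca")


def compare_groups_doi(
    cohortA: list[ROITimeSeries],
    cohortB: list[ROITimeSeries],
    order: int,
    null_of_differences: NullDistribution,
    alpha: float = 0.01,
) -> CausalGraph:
    """Per-edge group difference (A - B) in mean doi vs its surrogate null."""
    if cohortA[0].region_names != cohortB[0].region_names:
        raise ValueError("groups must share the same region set")
    stat_name = null_of_differences.statistic_name.replace("diff(", "").rstrip(")")
    diff = (_group_mean_stat(cohortA, order, stat_name)
            - _group_mean_stat(cohortB, order, stat_name))
    return edge_inference(cohortA[0].region_names, diff, null_of_differences,
                          alpha=alpha, alternative="two-sided",
                          method="mgca-diff")


def granger_difference_null(nullA: NullDistribution, nullB: NullDistribution,
                            rng=None) -> NullDistribution:
    return difference_null(nullA, nullB, rng=rng)
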