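"""Multivariate dynamical systems (MDS): bilinear state-space estimation
of causal interactions in latent neuronal signals.

Model (per subject, M regions, T samples):

    s(t) = sum_j v_j(t) C_j s(t-1) + D u(t) + w(t),   w ~ N(0, Q)
    y_m(t) = b_m' Phi x_m(t) + c_m + e_m(t),          e_m ~ N(0, r_m)

with x_m(t) the L past values of the latent signal s_m, Phi the HRF basis
(canonical + temporal derivative) and C_j the modulatory connection
matrices whose off-diagonal entry (m, n) is the causal strength of region
n on region m. The free per-region intercept c_m absorbs the constant
removed by detrending/demeaning the observed series (the latent process
itself has a nonzero task-driven mean), so the input strengths D stay on
the scale of the generative stimulus drive.

Estimation is variational EM. The E-step computes the exact Gaussian
posterior over the full latent trajectory: the joint precision over all
T*M latent variables is block-banded (bandwidth (L-1)*M), so one banded
Cholesky factorization plays the role of a Kalman forward-backward sweep,
and the posterior covariance band needed for the M-step comes from the
same factor. Because subjects in a group share parameters, the precision
(and covariance) is computed once per iteration and only the posterior
means are per subject. The M-step makes conditional MAP updates of
{C, D, Q, b, r} under weak conjugate priors (inverse-gamma on variances,
ridge on coefficients); each update is an exact conditional maximizer, so
the objective - the exact log marginal likelihood plus log prior - is
non-decreasing across iterations (ECM). After every iteration the HRF
weights are renormalized to unit length with positive canonical loading
(the latent scale is not identified separately from the HRF gain); this
reparameterization leaves the objective unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.linalg import cho_solve_banded, cholesky_banded
from sklearn.base import BaseEstimator

from .datatypes import ROITimeSeries
from .design import EventDesign
from .hrf import HRFBasis, build_hrf_basis
from .inference import CausalGraph, difference_null, edge_inference
from .surrogate import NullDistribution, surrogate_cohort

__all__ = ["MDSFit", "MDSModel", "fit_mds", "surrogate_null_mds",
           "significant_edges", "compare_groups_mds"]

# weak conjugate priors; kept fixed (not user-facing)
_IG_A = 1e-3
_IG_B = 1e-3
_RIDGE = 1e-4


@dataclass
class MDSFit:
    """Result of an MDS fit.

    ``connections[j, m, n]``: posterior-mean causal strength of region n on
    region m under modulatory input j (diagonal = self coupling, excluded
    from edge inference). ``elbo_trace`` is the per-iteration objective
    (log marginal likelihood + log prior), non-decreasing up to numerical
    tolerance.
    """

    region_names: tuple[str, ...]
    connections: np.ndarray          # (J, M, M)
    connection_spread: np.ndarray    # (J, M, M) posterior-sd summaries
    input_strengths: np.ndarray      # (M,)
    hrf_weights: np.ndarray          # (M, B)
    state_noise: np.ndarray          # (M,) diagonal of Q
    obs_noise: np.ndarray            # (M,)
    elbo_trace: np.ndarray
    converged: bool
    n_subjects: int
    per_subject_connections: dict = field(default_factory=dict)

    @property
    def strength(self) -> np.ndarray:
        """Edge-strength matrix of the first modulatory input."""
        return self.connections[0]


def _design_inputs(design: EventDesign, T: int, n_modulatory: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    box = design.boxcar(T)
    v = np.tile(box, (n_modulatory, 1))
    return v, box


@njit(cache=True)
def _takahashi_band(Lb: np.ndarray, bw: int) -> np.ndarray:
    """Band of the inverse of a banded SPD matrix from its Cholesky factor.

    ``Lb`` is the lower-banded Cholesky (Lb[d, j] = L[j+d, j]); returns
    ``zb`` with zb[d, i] = (A^-1)[i, i+d] for d = 0..bw. The classic
    backward recursion for Gaussian Markov random fields: only the band
    of the inverse is computed, at the same O(n bw^2) cost as the
    factorization itself.
    """
    n = Lb.shape[1]
    zb = np.zeros((bw + 1, n))
    for i in range(n - 1, -1, -1):
        dinv = 1.0 / Lb[0, i]
        kmax = min(bw, n - 1 - i)
        for dj in range(kmax, -1, -1):
            j = i + dj
            s = 0.0
            for dk in range(1, kmax + 1):
                k = i + dk
                if k >= j:
                    s += Lb[dk, i] * zb[k - j, j]
                else:
                    s += Lb[dk, i] * zb[j - k, k]
            val = -dinv * s
            if dj == 0:
                val += dinv * dinv
            zb[dj, i] = val
    return zb


class MDSModel(BaseEstimator):
    """Group-level MDS estimator (scikit-learn style).

    Parameters
    ----------
    n_lags : embedding/HRF lags L; default ``ceil(32 s / TR)``.
    n_modulatory : number of modulatory inputs J (default 1: the task-on
        regressor).
    max_iter, tol : EM stopping rule (relative objective change).
    self_init : initial self-coupling on the diagonal of C.

    Attributes (after ``fit``)
    ----------
    connections_ : (J, M, M) posterior-mean connection matrices.
    hrf_weights_ : (M, B) unit-norm HRF basis weights per region.
    state_noise_, obs_noise_ : noise variance estimates.
    elbo_trace_ : objective per iteration (non-decreasing).
    converged_ : whether the tolerance was reached before max_iter.
    """

    def __init__(self, n_lags: int | None = None, n_modulatory: int = 1,
                 max_iter: int = 500, tol: float = 1e-6,
                 self_init: float = 0.3, verbose: bool = False):
        self.n_lags = n_lags
        self.n_modulatory = n_modulatory
        self.max_iter = max_iter
        self.tol = tol
        self.self_init = self_init
        self.verbose = verbose

    # ---------------------------------------------------------------- fit
    def fit(self, cohort: list[ROITimeSeries] | ROITimeSeries,
            design: EventDesign, basis: HRFBasis | None = None) -> "MDSModel":
        if isinstance(cohort, ROITimeSeries):
            cohort = [cohort]
        regions = cohort[0].region_names
        tr = cohort[0].tr
        T = cohort[0].n_timepoints
        for ts in cohort:
            if ts.region_names != regions or ts.tr != tr or ts.n_timepoints != T:
                raise ValueError("all subjects must share region set, TR and length")
        M = len(regions)
        L = self.n_lags or int(np.ceil(32.0 / tr))
        if basis is None:
            basis = build_hrf_basis(tr, n_lags=L)
        Phi = basis.basis_matrix[:, :L]
        B = Phi.shape[0]
        J = self.n_modulatory
        v, box = _design_inputs(design, T, J)
        u = box  # same binary stimulus train for every region
        Y = np.stack([ts.values for ts in cohort])  # (S, T, M)
        S = Y.shape[0]

        # --- initialization
        C = np.zeros((J, M, M))
        C[0] += np.eye(M) * self.self_init
        D = np.ones(M) * 0.5
        q = np.ones(M)
        b = np.tile([1.0, 0.0] + [0.0] * (B - 2), (M, 1))
        c = np.zeros(M)
        drift = np.zeros(M)
        tnorm = np.linspace(-1.0, 1.0, T)
        r = Y.var(axis=(0, 1)) * 0.5 + 1e-6

        bw = max((L - 1) * M, 2 * M - 1)
        trace: list[float] = []
        converged = False
        gram_inv = None
        for it in range(self.max_iter):
            h = b @ Phi  # (M, L) per-region HRF kernels
            A = np.tensordot(v.T, C, axes=1)  # (T, M, M)
            Pb, rhs_dyn = self._build_dyn(A, D, q, u, T, M, bw)
            self._add_obs(Pb, h, r, T, M, L)
            try:
                cfac = cholesky_banded(Pb, lower=True)
            except np.linalg.LinAlgError:
                warnings.warn("singular precision; adding jitter")
                Pb[0] += 1e-6 * Pb[0].mean()
                cfac = cholesky_banded(Pb, lower=True)
            # RHS per subject: dynamics part shared + observation part
            rhs = np.tile(rhs_dyn[:, None], (1, S))
            for i in range(S):
                for m in range(M):
                    corr = np.correlate(Y[i, :, m] - c[m] - drift[m] * tnorm,
                                        h[m], mode="full")
                    rhs[m::M, i] += corr[L - 1:L - 1 + T] / r[m]
            mu = cho_solve_banded((cfac, True), rhs)  # (n, S)
            zb = _takahashi_band(np.ascontiguousarray(cfac), bw)
            obj = self._objective(cfac, mu, Y, A, D, q, u, h, c, drift,
                                  tnorm, r, C, b, T, M, L)
            trace.append(obj)
            if self.verbose:
                print(f"iter {it}: objective {obj:.4f}")
            if it >= 1:
                rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
                if abs(rel) < self.tol:
                    converged = True
            # --- M-step (conditional MAP updates)
            mu3 = mu.T.reshape(S, T, M)
            C, D, q, gram_inv = self._update_dynamics(mu3, zb, v, u, q,
                                                      T, M, J, S)
            b, c, drift, r = self._update_observation(mu3, zb, Y, Phi,
                                                      T, M, L, S, tnorm)
            # renormalize HRF gain (pure reparameterization)
            scale = np.linalg.norm(b, axis=1)
            scale = np.where(scale == 0, 1.0, scale)
            sign = np.where(b[:, 0] < 0, -1.0, 1.0)
            c_m = scale * sign
            b = b / c_m[:, None]
            D = D * c_m
            q = q * c_m ** 2
            C = C * (c_m[None, :, None] / c_m[None, None, :])
            if converged:
                break

        self.region_names_ = regions
        self.connections_ = C
        self.input_strengths_ = D
        self.state_noise_ = q
        self.hrf_weights_ = b
        self.obs_intercept_ = c
        self.obs_drift_ = drift
        self.obs_noise_ = r
        self.elbo_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_subjects_ = S
        # posterior-sd summary for C entries from the dynamics Gram
        spread = np.empty((J, M, M))
        dg = np.sqrt(np.maximum(np.diagonal(gram_inv)[:J * M], 0.0))
        for m in range(M):
            spread[:, m, :] = (dg * np.sqrt(q[m])).reshape(J, M)
        self.connection_spread_ = spread
        if not converged:
            warnings.warn(f"MDS fit did not converge in {self.max_iter} iterations")
        return self

    # -------------------------------------------------------- E-step parts
    @staticmethod
    def _build_dyn(A, D, q, u, T, M, bw):
        """Banded precision (lower form) + shared linear term from dynamics."""
        Pb = np.zeros((bw + 1, T * M))
        qi = 1.0 / q
        # diagonal blocks: Qi at every t, plus A_{t+1}' Qi A_{t+1} for t < T-1
        AtQA = np.einsum("tim,i,tin->tmn", A[1:], qi, A[1:])  # (T-1, M, M)
        for a in range(M):
            Pb[0, a::M] += qi[a]
        for a in range(M):
            for c in range(a, M):
                # lower triangle of symmetric block: P[tM+c, tM+a]
                Pb[c - a, a:(T - 1) * M:M] += AtQA[:, c, a]
        # off-diagonal blocks (t, t-1): -Qi A_t  -> P[tM+a, (t-1)M+c]
        QiA = qi[:, None] * A  # (T, M, M) rows scaled
        for a in range(M):
            for c in range(M):
                Pb[M + a - c, c:(T - 1) * M:M] += -QiA[1:, a, c]
        # linear term
        rhs = np.zeros(T * M)
        du = np.outer(u, D)  # (T, M)
        rhs += (du * qi).reshape(-1)
        contrib = -np.einsum("tim,i,ti->tm", A[1:], qi, du[1:])
        rhs[:(T - 1) * M] += contrib.reshape(-1)
        return Pb, rhs

    @staticmethod
    def _add_obs(Pb, h, r, T, M, L):
        """Add the HRF-convolution likelihood terms to the banded precision."""
        for m in range(M):
            hh = np.outer(h[m], h[m]) / r[m]
            for l in range(L):
                for lp in range(l, L):
                    k = lp - l
                    seg = Pb[k * M, m::M]
                    seg[:T - lp] += hh[l, lp]

    # -------------------------------------------------------------- M-step
    @staticmethod
    def _update_dynamics(mu3, zb, v, u, q, T, M, J, S):
        """Exact conditional MAP update of C, D, then Q."""
        # shared covariance blocks from the posterior band:
        # Sig00[t] = Cov(s(t), s(t)), Sig10[t] = Cov(s(t), s(t-1))
        Sig00 = np.empty((T, M, M))
        for a in range(M):
            for cc in range(a, M):
                Sig00[:, a, cc] = zb[cc - a, a::M]
                Sig00[:, cc, a] = Sig00[:, a, cc]
        Sig10 = np.zeros((T, M, M))
        for a in range(M):
            for cc in range(M):
                Sig10[1:, a, cc] = zb[M + a - cc, cc:(T - 1) * M:M]
        mu_prev = np.zeros_like(mu3)
        mu_prev[:, 1:] = mu3[:, :-1]
        Sig00_prev = np.zeros_like(Sig00)
        Sig00_prev[1:] = Sig00[:-1]

        P = J * M + 1
        G = np.zeros((P, P))
        vv = v * v[:, None] if v.ndim == 2 else None
        # E[prev prev'] summed with v_j v_k weights
        Epp_cov = Sig00_prev  # shared across subjects
        Epp_mean = np.einsum("stm,stn->tmn", mu_prev, mu_prev)
        Epp = S * Epp_cov + Epp_mean
        for j in range(J):
            for k in range(J):
                G[j * M:(j + 1) * M, k * M:(k + 1) * M] = np.einsum(
                    "t,tmn->mn", v[j] * v[k], Epp)
        mu_prev_sum = mu_prev.sum(axis=0)  # (T, M)
        for j in range(J):
            G[j * M:(j + 1) * M, -1] = np.einsum("t,tm->m", v[j] * u, mu_prev_sum)
            G[-1, j * M:(j + 1) * M] = G[j * M:(j + 1) * M, -1]
        G[-1, -1] = S * np.sum(u * u)
        # cross terms per target region
        Ecur_prev = S * Sig10 + np.einsum("stm,stn->tmn", mu3, mu_prev)
        cross = np.zeros((M, P))
        for j in range(J):
            cross[:, j * M:(j + 1) * M] = np.einsum("t,tmn->mn", v[j], Ecur_prev)
        cross[:, -1] = np.einsum("t,tm->m", u, mu3.sum(axis=0))
        Greg = G + _RIDGE * np.eye(P)
        try:
            gram_inv = np.linalg.inv(Greg)
        except np.linalg.LinAlgError:
            warnings.warn("singular dynamics Gram; adding jitter")
            gram_inv = np.linalg.inv(Greg + 1e-6 * np.trace(Greg) / P * np.eye(P))
        coefs = cross @ gram_inv  # (M, P)
        C = np.empty((J, M, M))
        for j in range(J):
            C[j] = coefs[:, j * M:(j + 1) * M]
        D = coefs[:, -1]
        # Q update from expected residuals
        Ecur = S * Sig00 + np.einsum("stm,stn->tmn", mu3, mu3)
        ss_cur = np.einsum("tmm->m", Ecur)
        resid = ss_cur - 2 * np.einsum("mp,mp->m", coefs, cross) \
            + np.einsum("mp,pq,mq->m", coefs, G, coefs)
        q_new = (np.maximum(resid, 0.0) + 2 * _IG_B) / (S * T + 2 * (_IG_A + 1))
        return C, D, np.maximum(q_new, 1e-8), gram_inv

    @staticmethod
    def _update_observation(mu3, zb, Y, Phi, T, M, L, S, tnorm):
        """Exact conditional MAP update of HRF weights b, then obs var r."""
        B = Phi.shape[0]
        b_new = np.empty((M, B))
        c_new = np.empty(M)
        d_new = np.empty(M)
        r_new = np.empty(M)
        for m in range(M):
            # covariance part of sum_t E[x x'], via diagonal cumsums
            W = np.zeros((L, L))
            for k in range(L):
                dk = zb[k * M, m::M][:T - k]  # Cov(s_m(tau), s_m(tau+k))
                ck = np.concatenate([[0.0], np.cumsum(dk)])
                for lp in range(k, L):
                    l = lp - k
                    # t from lp..T-1 -> tau = t-lp in [0, T-1-lp]
                    W[l, lp] = ck[T - lp]
                    W[lp, l] = W[l, lp]
            W *= S
            cr = np.zeros(L)
            sx = np.zeros(L)
            tx = np.zeros(L)
            ymm_ss = 0.0
            sy = 0.0
            ty = 0.0
            for i in range(S):
                pad = np.concatenate([np.zeros(L - 1), mu3[i, :, m]])
                win = np.lib.stride_tricks.sliding_window_view(pad, L)[:, ::-1]
                # win[t] = [s(t), s(t-1), ..., s(t-L+1)]
                W += win.T @ win
                cr += Y[i, :, m] @ win
                sx += win.sum(axis=0)
                tx += tnorm @ win
                sy += Y[i, :, m].sum()
                ty += tnorm @ Y[i, :, m]
                ymm_ss += np.sum(Y[i, :, m] ** 2)
            # joint (b, intercept, drift) normal equations; the intercept and
            # linear-drift columns mirror what detrending removed from y
            tt = float(tnorm @ tnorm)
            Gb = np.empty((B + 2, B + 2))
            Gb[:B, :B] = Phi @ W @ Phi.T
            Gb[:B, B] = Phi @ sx
            Gb[:B, B + 1] = Phi @ tx
            Gb[B, :B] = Gb[:B, B]
            Gb[B + 1, :B] = Gb[:B, B + 1]
            Gb[B, B] = S * T
            Gb[B, B + 1] = Gb[B + 1, B] = 0.0
            Gb[B + 1, B + 1] = S * tt
            cb = np.concatenate([Phi @ cr, [sy, ty]])
            sol = np.linalg.solve(Gb + _RIDGE * np.eye(B + 2), cb)
            b_new[m] = sol[:B]
            c_new[m] = sol[B]
            d_new[m] = sol[B + 1]
            resid = ymm_ss - 2 * sol @ cb + sol @ Gb @ sol
            r_new[m] = (np.maximum(resid, 0.0) + 2 * _IG_B) / (S * T + 2 * (_IG_A + 1))
        return b_new, c_new, d_new, np.maximum(r_new, 1e-10)

    # ----------------------------------------------------------- objective
    @staticmethod
    def _objective(cfac, mu, Y, A, D, q, u, h, c, drift, tnorm, r,
                   C, b, T, M, L):
        """Exact log marginal likelihood + log prior at current params."""
        S = Y.shape[0]
        n = T * M
        logdetP = 2.0 * np.sum(np.log(cfac[0]))
        total = 0.0
        du = np.outer(u, D)
        for i in range(S):
            m3 = mu[:, i].reshape(T, M)
            pred = np.einsum("tmn,tn->tm", A[1:], m3[:-1])
            res_dyn = np.empty((T, M))
            res_dyn[0] = m3[0] - du[0]
            res_dyn[1:] = m3[1:] - pred - du[1:]
            lp_s = -0.5 * np.sum(res_dyn ** 2 / q) - 0.5 * T * np.sum(
                np.log(2 * np.pi * q))
            yhat = np.empty((T, M))
            for m in range(M):
                yhat[:, m] = (np.convolve(m3[:, m], h[m])[:T]
                              + c[m] + drift[m] * tnorm)
            res_obs = Y[i] - yhat
            lp_y = -0.5 * np.sum(res_obs ** 2 / r) - 0.5 * T * np.sum(
                np.log(2 * np.pi * r))
            total += lp_y + lp_s - 0.5 * logdetP + 0.5 * n * np.log(2 * np.pi)
        # log prior (weak): inverse-gamma on q, r; ridge on C, D, b
        lprior = -np.sum((_IG_A + 1) * np.log(q) + _IG_B / q)
        lprior += -np.sum((_IG_A + 1) * np.log(r) + _IG_B / r)
        lprior += -0.5 * _RIDGE * (np.sum(C ** 2) + np.sum(D ** 2) + np.sum(b ** 2))
        return total + lprior

    # ----------------------------------------------------------- accessors
    def to_fit(self) -> MDSFit:
        return MDSFit(
            region_names=self.region_names_,
            connections=self.connections_,
            connection_spread=self.connection_spread_,
            input_strengths=self.input_strengths_,
            hrf_weights=self.hrf_weights_,
            state_noise=self.state_noise_,
            obs_noise=self.obs_noise_,
            elbo_trace=self.elbo_trace_,
            converged=self.converged_,
            n_subjects=self.n_subjects_,
        )


def fit_mds(
    cohort: list[ROITimeSeries],
    design: EventDesign,
    basis: HRFBasis | None = None,
    per_subject: bool = False,
    **config,
) -> MDSFit:
    """Fit the MDS model to a cohort (joint group fit by default).

    With ``per_subject=True`` each subject is fitted separately and the
    group-level connections are the across-subject mean; per-subject
    matrices are stored on the returned fit (used for brain-behavior
    regression).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        if not per_subject:
            return MDSModel(**config).fit(cohort, design, basis).to_fit()
        per_sub = {}
        fits = []
        for ts in cohort:
            f = MDSModel(**config).fit([ts], design, basis).to_fit()
            per_sub[ts.subject_id] = f.connections[0]
            fits.append(f)
    base = fits[0]
    return MDSFit(
        region_names=base.region_names,
        connections=np.mean([f.connections for f in fits], axis=0),
        connection_spread=np.mean([f.connection_spread for f in fits], axis=0),
        input_strengths=np.mean([f.input_strengths for f in fits], axis=0),
        hrf_weights=np.mean([f.hrf_weights for f in fits], axis=0),
        state_noise=np.mean([f.state_noise for f in fits], axis=0),
        obs_noise=np.mean([f.obs_noise for f in fits], axis=0),
        elbo_trace=base.elbo_trace,
        converged=all(f.converged for f in fits),
        n_subjects=len(fits),
        per_subject_connections=per_sub,
    )


def surrogate_null_mds(
    cohort: list[ROITimeSeries],
    design: EventDesign,
    basis: HRFBasis | None = None,
    n_surrogates: int = 100,
    method: str = "phase",
    seed: int | None = 0,
    surrogate_max_iter: int = 30,
    **config,
) -> NullDistribution:
    """Null distribution of MDS edge strengths from surrogate cohorts.

    Each surrogate preserves per-region spectra while destroying
    cross-region dependence; the same estimator is refitted (with a
    reduced iteration cap, sufficient for the point statistic) and the
    estimated connection matrix recorded.
    """
    rng = np.random.default_rng(seed)
    M = cohort[0].n_regions
    vals = np.empty((n_surrogates, M, M))
    config = {**config, "max_iter": surrogate_max_iter}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for k in range(n_surrogates):
            surr = surrogate_cohort(cohort, rng, method=method)
            vals[k] = MDSModel(**config).fit(surr, design, basis).connections_[0]
    return NullDistribution(statistic_name="mds_strength", values=vals,
                            method=method, seed=seed)


def significant_edges(fit: MDSFit, null: NullDistribution,
                      alpha: float = 0.01, fdr: bool = True) -> CausalGraph:
    """Edges whose strength is extreme relative to the surrogate null.

    Two-sided add-one empirical p per off-diagonal edge, BH-FDR at
    ``alpha``; the diagonal (self-coupling) is excluded.
    """
    return edge_inference(fit.region_names, fit.strength, null, alpha=alpha,
                          fdr=fdr, alternative="two-sided", method="mds")


def compare_groups_mds(fitA: MDSFit, fitB: MDSFit,
                       nullA: NullDistribution, nullB: NullDistribution,
                       alpha: float = 0.01) -> CausalGraph:
    """Per-edge group difference in strength vs the null of differences."""
    if fitA.region_names != fitB.region_names:
        raise ValueError("groups must share the same region set")
    diff = fitA.strength - fitB.strength
    null = difference_null(nullA, nullB)
    return edge_inference(fitA.region_names, diff, null, alpha=alpha,
                          alternative="two-sided", method="mds-diff")
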