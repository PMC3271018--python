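"""Synthetic two-group cohort generator.

Generates multi-subject datasets from the same bilinear state-space model
the estimators assume: latent dynamics
``s(t) = sum_j v_j(t) C_j s(t-1) + D u(t) + w(t)`` driven by a jittered
event-related design, observed as BOLD through per-region HRF convolution
plus white observation noise. On top of the time series it draws behavior
(reaction time, accuracy) as a linear function of each subject's true edge
strengths, and a structural-connectivity table whose fiber density is
correlated with a designated edge's strength in one group only. Ground
truth is returned for recovery testing.

Default parameter values encode the emulated study design: five regions
with a right-anterior-insula (rAI) outflow hub, a child group whose
rAI->rPPC edge is weakened, adults with faster/more accurate and less
noisy behavior, and structure-function coupling present in adults only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MDSParameters, ROITimeSeries
from .design import EventDesign, generate_event_design
from .hrf import HRFBasis, build_hrf_basis, canonical_hrf

__all__ = [
    "REGIONS",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "simulate_latent",
    "simulate_bold",
    "generate_cohort",
    "default_cohort_spec",
    "null_cohort_spec",
    "generate_leadlag_cohort",
]

REGIONS = ("rAI", "rVLPFC", "ACC", "rDLPFC", "rPPC")

# hub out-edges (source, target) -> strength; row=target convention applies
# to matrices, edges here are named (source, target) for readability
_DEFAULT_EDGES = {
    ("rAI", "rVLPFC"): 0.80,
    ("rAI", "ACC"): 0.80,
    ("rAI", "rDLPFC"): 0.80,
    ("rAI", "rPPC"): 1.10,
}


def simulate_latent(
    params: MDSParameters,
    design: EventDesign,
    n_timepoints: int | None = None,
    seed: int | np.random.Generator | None = 0,
    modulators: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the latent neuronal series s(t), shape (T, M).

    s(t) = sum_j v_j(t) C_j s(t-1) + D u(t) + w(t), w ~ N(0, Q), s(0) = 0.
    By default there is a single modulatory input equal to the task-on
    boxcar of the design, and u(t) drives every region with the same
    boxcar scaled by the diagonal input strengths D.
    """
    T = n_timepoints if n_timepoints is not None else design.n_timepoints
    M = params.n_regions
    J = params.n_modulatory
    box = design.boxcar(T)
    if modulators is None:
        v = np.tile(box, (J, 1))
    else:
        v = np.atleast_2d(np.asarray(modulators, dtype=float))
        if v.shape != (J, T):
            raise ValueError(f"modulators must have shape ({J}, {T})")
    u = box[:, None] * np.ones(M)  # binary stimulus indicator per region
    rng = np.random.default_rng(seed)
    if np.any(params.state_noise_cov):
        w = rng.multivariate_normal(np.zeros(M), params.state_noise_cov,
                                    size=T, method="cholesky")
    else:
        w = np.zeros((T, M))
    C = params.modulatory_matrices
    D = params.input_strengths
    s = np.zeros((T, M))
    prev = np.zeros(M)
    for t in range(T):
        A_t = np.tensordot(v[:, t], C, axes=1)  # sum_j v_j(t) C_j
        prev = A_t @ prev + D * u[t] + w[t]
        s[t] = prev
    return s


def _hrf_kernels(params: MDSParameters, basis: HRFBasis) -> np.ndarray:
    """Per-region HRF kernels h_m = b_m' Phi, shape (M, L)."""
    if params.hrf_basis_weights.shape[1] != basis.n_bases:
        raise ValueError(
            f"hrf_basis_weights has {params.hrf_basis_weights.shape[1]} bases "
            f"but the basis matrix has {basis.n_bases}")
    if params.embedding_lags > basis.n_lags:
        raise ValueError("embedding_lags exceeds the basis support length")
    return params.hrf_basis_weights @ basis.basis_matrix[:, :params.embedding_lags]


def simulate_bold(
    latent: np.ndarray,
    params: MDSParameters,
    basis: HRFBasis,
    seed: int | np.random.Generator | None = 0,
    region_names: tuple[str, ...] = REGIONS,
    subject_id: str = "sub-00",
    group_label: str = "",
) -> ROITimeSeries:
    """Observe latent series through HRF convolution plus white noise.

    y_m(t) = b_m' Phi x_m(t) + e_m(t) with x_m(t) the embedding_lags past
    values of s_m (zero-padded before run start) and e_m ~ N(0, var_m)
    independent of the state noise.
    """
    s = np.asarray(latent, dtype=float)
    T, M = s.shape
    if T <= params.embedding_lags:
        raise ValueError("latent series shorter than the embedding window")
    kern = _hrf_kernels(params, basis)
    rng = np.random.default_rng(seed)
    y = np.empty_like(s)
    for m in range(M):
        y[:, m] = np.convolve(s[:, m], kern[m])[:T]
    y += rng.standard_normal((T, M)) * np.sqrt(params.obs_noise_var)
    return ROITimeSeries(y, tuple(region_names[:M]), basis.tr, subject_id, group_label)


@dataclass
class GroupSpec:
    """Per-group settings layered on the cohort template."""

    n_subjects: int = 20
    # (source, target) -> additive change to the template edge strength
    edge_deltas: dict = field(default_factory=dict)
    rt_intercept: float = 1500.0   # ms
    rt_noise_sd: float = 30.0      # ms
    acc_intercept: float = 0.92
    acc_noise_sd: float = 0.03
    fiber_mean: float = 30.0       # fibers per unit area
    fiber_sd: float = 4.0
    fa_mean: float = 0.52
    fa_sd: float = 0.04
    structure_coupled: bool = False


@dataclass
class CohortSpec:
    """Full specification of a synthetic two-group cohort."""

    region_names: tuple[str, ...] = REGIONS
    base_edges: dict = field(default_factory=lambda: dict(_DEFAULT_EDGES))
    self_coupling: float = 0.50
    input_strength: float = 1.0
    state_noise_sd: float = 2.0
    snr: float = 2.0                # sd(noiseless BOLD) / sd(obs noise)
    perturb_sd: float = 0.06        # subject-level sd on nonzero template edges
    # (source, target) -> (weight on RT in ms, weight on accuracy) per unit strength
    behavior_coupling: dict = field(default_factory=lambda: {
        ("rAI", "rPPC"): (-800.0, 0.40),
        ("rAI", "ACC"): (-400.0, 0.50),
    })
    structure_edge: tuple[str, str] = ("rAI", "rPPC")
    structure_slope: float = 50.0   # fiber density per unit edge strength
    n_trials: int = 52
    stim_duration: float = 5.0
    iti_fixed: float = 1.0
    jitter_bounds: tuple[float, float] = (0.0, 3.5)
    tr: float = 2.0
    n_timepoints: int | None = 250
    embedding_lags: int | None = None  # default ceil(32 s / TR)
    groups: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            self.groups = {
                "adult": GroupSpec(),
                "child": GroupSpec(
                    edge_deltas={("rAI", "rPPC"): -0.50},
                    rt_intercept=2300.0, rt_noise_sd=60.0,
                    acc_intercept=0.84, acc_noise_sd=0.045,
                    fiber_mean=22.0, fa_mean=0.44,
                ),
            }
        if len(set(self.groups)) < 2 and len(self.groups) != 1:
            raise ValueError("group labels must be distinct")
        names = set(self.region_names)
        for src, tgt in list(self.base_edges) + list(self.behavior_coupling):
            if src not in names or tgt not in names:
                raise ValueError(f"edge ({src}, {tgt}) references unknown region")
        for g, gs in self.groups.items():
            if gs.n_subjects < 3:
                raise ValueError(
                    f"group '{g}' has {gs.n_subjects} subjects; need >= 3 "
                    "(group tests are undefined below that)")
            for src, tgt in gs.edge_deltas:
                if src not in names or tgt not in names:
                    raise ValueError(f"edge ({src}, {tgt}) references unknown region")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def template_matrix(self, group: str) -> np.ndarray:
        """Group-level connection matrix (row = target, column = source)."""
        M = self.n_regions
        idx = {r: i for i, r in enumerate(self.region_names)}
        C = np.eye(M) * self.self_coupling
        edges = dict(self.base_edges)
        for (src, tgt), delta in self.groups[group].edge_deltas.items():
            edges[(src, tgt)] = edges.get((src, tgt), 0.0) + delta
        for (src, tgt), w in edges.items():
            C[idx[tgt], idx[src]] = w
        return C


@dataclass
class Cohort:
    """A generated cohort with its ground truth."""

    timeseries: list          # ROITimeSeries per subject
    design: EventDesign
    behavior: pd.DataFrame
    structure: pd.DataFrame
    ground_truth: dict        # subject_id -> true (M, M) connection matrix
    group_templates: dict     # group -> template (M, M) matrix
    spec: CohortSpec
    latents: dict = field(default_factory=dict)

    def group_subjects(self, group: str) -> list:
        return [ts for ts in self.timeseries if ts.group_label == group]


def _stable(C: np.ndarray, limit: float = 0.95) -> np.ndarray:
    rho = np.max(np.abs(np.linalg.eigvals(C)))
    if rho >= limit:
        C = C * (limit / rho)
    return C


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort: time series, behavior, structure, ground truth.

    Per-subject connection matrices are the group template plus Gaussian
    perturbations (sd ``spec.perturb_sd``) on the nonzero template entries,
    rescaled if needed to keep the spectral radius below 0.95. Behavior is
    a linear function of the subject's true edge strengths plus noise;
    fiber density tracks the designated edge's strength only in groups
    flagged ``structure_coupled``.
    """
    ss = np.random.SeedSequence(spec.seed)
    design_seed, *_ = ss.spawn(1)
    design = generate_event_design(
        n_trials=spec.n_trials, stim_duration=spec.stim_duration,
        iti_fixed=spec.iti_fixed, jitter_bounds=spec.jitter_bounds,
        tr=spec.tr, seed=np.random.default_rng(design_seed))
    T = spec.n_timepoints or design.n_timepoints
    if T < design.n_timepoints:
        T = design.n_timepoints
    L = spec.embedding_lags or int(np.ceil(32.0 / spec.tr))
    basis = build_hrf_basis(spec.tr, n_lags=L)
    M = spec.n_regions
    idx = {r: i for i, r in enumerate(spec.region_names)}
    b_true = np.tile([1.0, 0.0], (M, 1))  # canonical HRF everywhere

    timeseries, truth, latents = [], {}, {}
    behavior_rows, structure_rows = [], []
    templates = {g: spec.template_matrix(g) for g in spec.groups}
    sub_counter = 0
    for group, gspec in spec.groups.items():
        tmpl = templates[group]
        mask = tmpl != 0
        np.fill_diagonal(mask, False)
        for k in range(gspec.n_subjects):
            sub_counter += 1
            sid = f"sub-{sub_counter:02d}"
            child = np.random.SeedSequence(spec.seed, spawn_key=(1, sub_counter))
            rng = np.random.default_rng(child)
            C = tmpl.copy()
            C[mask] += rng.normal(0.0, spec.perturb_sd, size=int(mask.sum()))
            C = _stable(C)
            params = MDSParameters(
                n_regions=M,
                modulatory_matrices=C[None],
                input_strengths=np.full(M, spec.input_strength),
                state_noise_cov=np.eye(M) * spec.state_noise_sd ** 2,
                hrf_basis_weights=b_true,
                obs_noise_var=np.zeros(M),
                embedding_lags=L,
            )
            s = simulate_latent(params, design, n_timepoints=T, seed=rng)
            clean = simulate_bold(s, params, basis, seed=rng,
                                  region_names=spec.region_names,
                                  subject_id=sid, group_label=group)
            sig_sd = clean.values.std(axis=0)
            noise_sd = sig_sd / spec.snr if spec.snr > 0 else np.zeros(M)
            y = clean.values + rng.standard_normal((T, M)) * noise_sd
            timeseries.append(ROITimeSeries(y, spec.region_names, spec.tr, sid, group))
            truth[sid] = C
            latents[sid] = s

            rt = gspec.rt_intercept + rng.normal(0.0, gspec.rt_noise_sd)
            acc = gspec.acc_intercept + rng.normal(0.0, gspec.acc_noise_sd)
            for (src, tgt), (w_rt, w_acc) in spec.behavior_coupling.items():
                dev = C[idx[tgt], idx[src]] - tmpl[idx[tgt], idx[src]]
                rt += w_rt * dev
                acc += w_acc * dev
            behavior_rows.append({
                "subject_id": sid, "group": group,
                "reaction_time": max(rt, 1.0),
                "accuracy": float(np.clip(acc, 0.0, 1.0)),
            })

            esrc, etgt = spec.structure_edge
            edge_strength = C[idx[etgt], idx[esrc]]
            for a in range(M):
                for b_ in range(a + 1, M):
                    ra, rb = spec.region_names[a], spec.region_names[b_]
                    is_edge = {ra, rb} == {esrc, etgt}
                    fd = gspec.fiber_mean + rng.normal(0.0, gspec.fiber_sd)
                    if is_edge and gspec.structure_coupled:
                        fd += spec.structure_slope * (
                            edge_strength - tmpl[idx[etgt], idx[esrc]])
                    fa = gspec.fa_mean + rng.normal(0.0, gspec.fa_sd)
                    structure_rows.append({
                        "subject_id": sid, "group": group,
                        "region_a": ra, "region_b": rb,
                        "fiber_density": max(fd, 0.0),
                        "mean_fa": float(np.clip(fa, 0.0, 1.0)),
                    })

    return Cohort(
        timeseries=timeseries, design=design,
        behavior=pd.DataFrame(behavior_rows),
        structure=pd.DataFrame(structure_rows),
        ground_truth=truth, group_templates=templates, spec=spec,
        latents=latents)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The emulated study design: adult group with full-strength hub
    out-edges and structure-function coupling, child group with a weakened
    rAI->rPPC edge, slower/less accurate behavior and uncoupled structure."""
    spec = CohortSpec(seed=seed, **overrides)
    spec.groups["adult"].structure_coupled = True
    return spec


def null_cohort_spec(seed: int = 0, n_subjects: int = 10, **overrides) -> CohortSpec:
    """Zero-coupling cohort: no off-diagonal edges in any group."""
    groups = {
        "adult": GroupSpec(n_subjects=n_subjects),
        "child": GroupSpec(n_subjects=n_subjects, rt_intercept=2300.0,
                           acc_intercept=0.84, fiber_mean=22.0, fa_mean=0.44),
    }
    return CohortSpec(base_edges={}, behavior_coupling={}, groups=groups,
                      seed=seed, **overrides)


def generate_leadlag_cohort(
    n_subjects: int = 12,
    lead: float = 2.0,
    region_names: tuple[str, ...] = REGIONS,
    hub: str = "rAI",
    tr: float = 2.0,
    n_trials: int = 30,
    noise_sd: float = 0.2,
    seed: int = 0,
    group_label: str = "adult",
    onset_jitter_sd: float = 0.1,
) -> tuple[list, EventDesign]:
    """Cohort in which the hub's evoked response leads the others.

    Each region's BOLD response is the canonical HRF convolved with the
    stimulus train; non-hub regions respond ``lead`` seconds later (one TR
    by default). Used for validating onset-latency ordering.
    """
    ss = np.random.SeedSequence(seed)
    design = generate_event_design(n_trials=n_trials, tr=tr,
                                   seed=np.random.default_rng(ss.spawn(1)[0]))
    T = design.n_timepoints
    upsample = 10
    dt = tr / upsample
    t_fine = np.arange(int(design.run_length / dt)) * dt
    out = []
    for k in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, k)))
        subj_shift = rng.normal(0.0, onset_jitter_sd)
        y = np.empty((T, len(region_names)))
        for i, r in enumerate(region_names):
            delay = 0.0 if r == hub else lead
            stim = np.zeros_like(t_fine)
            for onset, dur in zip(design.trial_onsets, design.trial_durations):
                o = onset + delay + subj_shift
                stim[(t_fine >= o) & (t_fine < o + dur)] = 1.0
            kern_fine = canonical_hrf(np.arange(0, 32.0, dt))
            resp = np.convolve(stim, kern_fine)[:len(t_fine)] * dt
            y[:, i] = resp[::upsample][:T] + rng.normal(0.0, noise_sd, T)
        out.append(ROITimeSeries(y, region_names, tr, f"sub-{k + 1:02d}", group_label))
    return out, design
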