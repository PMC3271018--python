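# Methods

`neurocausal` estimates directed causal interactions among a small set of
brain regions (by default the five salience/central-executive nodes rAI,
rVLPFC, ACC, rDLPFC, rPPC) from BOLD fMRI time series, and validates
every stage against a synthetic cohort generator built on the same
generative model. This note documents the models, the estimation
choices, and what the synthetic validation does and does not show.

## Generative model

Latent neuronal dynamics per subject, M regions, sampling interval TR:

    s(t) = Σ_j v_j(t) C_j s(t−1) + D u(t) + w(t),   w(t) ~ N(0, Q)

- `C_j` — M×M modulatory connection matrix for input j; entry (m, n) is
  the causal strength of region n on region m (**row = target**
  everywhere in this package). Default J = 1 with v₁(t) = the task-on
  boxcar; couplings act only while the task is on.
- `D` — diagonal stimulus gains; `u(t)` — binary stimulus indicator.
- `Q` — state-noise covariance (diagonal in the estimator).

Observation: BOLD in region m is a linear convolution of the last L
latent samples with a region-specific HRF expressed in a 2-basis
expansion (canonical double-gamma, peak 6 s, undershoot 16 s, peak:
undershoot ratio 6; plus its temporal derivative):

    y_m(t) = b_mᵀ Φ x_m(t) + c_m + d_m·t̃ + e_m(t),   e_m ~ N(0, r_m)

`Φ` is the 2×L basis matrix on the TR lag grid, L = ⌈32 s / TR⌉ so the
full HRF support is covered (TR defaults to 2 s, so L = 16). The
intercept `c_m` and linear drift `d_m` are free observation parameters:
the analysis convention is to detrend and demean each series before
modelling, which removes the task-locked mean response that `D u(t)`
generates; without these terms the estimator provably prefers a biased
optimum that reallocates the shared stimulus response into spurious
couplings. With them, recovery of C, D, Q and b is unbiased in
simulation.

## Estimation (variational EM)

Parameters {C, D, Q, b, c, drift, r} are shared across the subjects of a
group (a per-subject mode exists for brain–behavior regression); latent
trajectories are per subject.

- **E-step.** The joint posterior of the full latent trajectory
  (T·M Gaussian variables) is computed exactly. Its precision matrix is
  block-banded with bandwidth (L−1)·M, so one banded Cholesky
  factorization replaces a Kalman forward–backward sweep; posterior
  means for all subjects come from one batched triangular solve, and the
  covariance band needed by the M-step from the Takahashi
  selected-inverse recursion (numba-compiled, same O(n·bw²) cost as the
  factorization). Because parameters are shared, the covariance is
  computed once per iteration regardless of group size.
- **M-step.** Exact conditional MAP updates (ECM): weighted least squares
  for the rows of C and D, closed-form inverse-gamma updates for Q and
  r (weak priors, a = b = 10⁻³, plus a small ridge 10⁻⁴ on
  coefficients), joint least squares for (b_m, c_m, drift_m).
- **Identifiability.** The latent scale trades off against the HRF gain,
  so after each iteration b_m is renormalized to unit norm with positive
  canonical loading and the equivalent rescaling is applied to C, D, Q —
  a pure reparameterization that leaves the objective unchanged.
- **Objective.** The trace is the exact log marginal likelihood plus log
  prior, evaluated from the same Cholesky factor; EM guarantees it is
  non-decreasing (asserted in tests at 10⁻⁶ relative tolerance).
  Convergence: relative change < `tol` (10⁻⁶) or `max_iter` (500
  default; the validation experiments cap at 40–60, by which point the
  connection estimates are stable).

A converged group fit (10–20 subjects, ~250 samples) takes well under a
second, which is what makes honest per-dataset surrogate nulls feasible.

## Granger causality (MGCA)

Conditional influence from a full multivariate VAR (default order 1,
appropriate at TR-scale sampling; BIC selection available):
F_{x→y} = ln(reduced/full residual variance of y), reduced = the model
omitting x's lags while conditioning on all other regions. Nesting
guarantees F ≥ 0. The difference of influence doi = F − Fᵀ is exactly
antisymmetric; a directed edge x→y requires positive net doi.

## Surrogate nulls and inference

Surrogates are per-region independent phase randomizations (AAFT
available), preserving each region's amplitude spectrum — hence variance
and autocorrelation — while destroying all cross-region dependence and
stimulus locking. The group statistic (mean doi, or the MDS connection
strength refitted on the surrogate cohort) is recomputed per surrogate;
edge p-values are add-one empirical, (r+1)/(n+1), with
Benjamini–Hochberg FDR over the M(M−1) off-diagonal edges.

Two practical points follow from the empirical-p floor 1/(n+1):

- BH-FDR at q < 0.01 over 20 edges needs p ≤ 0.002 even when four edges
  are true, so Granger inference defaults to 999 surrogates. MDS refits
  are costlier; the topology-recovery experiment uses 100-surrogate
  nulls and tests hub edges at q < 0.05 (q < 0.01 is structurally
  unreachable at that surrogate count — not a property of the data).
- Group-difference nulls are built from all cross-pairs of the two
  groups' surrogate statistics (up to 250 each, ≥ ~40 000 differences),
  so single-edge differences can pass q < 0.01.

Surrogate refits of the MDS model cap EM at `surrogate_max_iter`
(default 12; 4–8 in the scaled experiments). Validation: the null sd of
the capped statistic on zero-coupling data (0.038 at 6 iterations)
matches the across-replicate sd of the fully converged statistic on
independent null cohorts (0.038); longer caps give slightly wider,
i.e. conservative, nulls.

## Onset latency

Event-related responses are fitted per subject and region by least
squares on canonical + derivative regressors built from the event table
(plus intercept and drift nuisance columns mirroring the detrending).
Fitted curves are reconstructed on a 10×-upsampled grid (step TR/10) and
averaged over events, then subjects. Onset is the earliest time where
the slope (central differences) reaches 10% of the extreme slope within
the initial limb, defined as the rising (or falling) limb of the
dominant peak — from the last slope sign change before the global-|max|
peak. Defining the limb up to the *first* local extremum fails on
delayed responses, whose two-basis approximation begins with a small
spurious dip. The relative-slope rule is scale-invariant and
shift-equivariant (asserted exactly on analytic curves). Within-group
comparisons are paired t-tests across regions; between-group per-region
tests are unpaired; each family is BH-FDR corrected.

## Graph metrics

Computed on the binarized significant graph: out/in-degree, net causal
outflow (out − in; sums to zero over nodes), and per-node shortest
directed path length to every other node normalized by (M−1) with unit
edge lengths. Unreachable targets contribute a finite penalty of M
(exceeding any realizable path) so means stay defined on sparse graphs;
an "exclude" mode is available. Hub tests compare each node's
per-subject metric vector against the pooled vector of the other nodes
(two-sample t, BH-FDR across nodes).

## Functional connectivity, structure–function, behavior

FC is the Pearson correlation after regression of intercept, linear
drift and any user-supplied confound columns; group comparison uses
two-sample t-tests on Fisher-z values with BH-FDR over the M(M−1)/2
pairs. Structure–function coupling is the across-subject Pearson
correlation between an edge's functional measure (FC r or causal
strength) and fiber density or mean FA. Behavior (reaction time,
accuracy) is regressed on the 10 unordered-pair net causal strengths by
cross-validated lasso (scikit-learn coordinate descent; 5-fold seeded
CV, minimum-CV-error penalty; elastic-net mixing exposed). Predictors
are standardized internally; unselected connections get exactly zero
coefficients; R² and MSE are reported on the standardized scale both
in-sample and cross-validated (the analysis convention reports the
in-sample pair).

## Synthetic cohorts: what they emulate

The generator reproduces the study design: 52 five-second arithmetic
stimuli in a jittered event-related design (fixed 1 s inter-trial
interval + Uniform(0, 3.5 s) jitter; jitter distribution chosen uniform
— only its range and mean are known), TR 2 s, ~250 samples; two groups
("adult", "child") of configurable size; a right-anterior-insula
outflow hub driving the other four regions; behavior linearly coupled
to designated edge strengths with group-specific noise (adults faster,
more accurate, less noisy — so causal strengths predict adult behavior
better); fiber density correlated with the hub→parietal strength in the
adult group only; FA and fiber density lower in the child group.

Default effect and noise scales (chosen once, as a realistic regime in
which the emulated effects are as statistically robust as the study
reports at its sample size): hub out-edges 0.8, hub→rPPC 1.1 weakened
by 0.5 in the child group, latent self-coupling 0.5, state-noise sd
2.0, observation SNR 2 (sd of noiseless BOLD / sd of observation
noise), between-subject edge perturbation sd 0.06 applied to nonzero
template edges (keeping per-subject matrices stable: the template is
triangular, so its spectral radius equals the self-coupling). The
parameter-recovery experiment overrides SNR to 1 — its stated, harder
condition.

What the generator does **not** emulate: volumetric data and spatial
preprocessing, physiological (colored) noise, HRF variability beyond
the two-basis family, inter-regional hemodynamic delay confounds beyond
what the basis expresses, nonstationary coupling within the task state,
and sampling variability of real ROI definitions. Passing recovery
tests therefore shows the estimators are correct and well calibrated
under the model class and realistic noise — not that real fMRI
satisfies that model class.

## Validation experiments (scales)

The `neurocausal.benchmarks` module and `scripts/acceptance.py` run:
parameter recovery (20 cohorts × 20 subjects, SNR 1); the bivariate
analytic Granger oracle (n = 2000, 20 replicates); null calibration (20
zero-coupling cohorts × 10 subjects; 299 Granger / 100 MDS surrogates
per replicate); topology and group-difference recovery (20 replicates; the Granger arm
at the emulated study's 20 subjects/group — detection power for the
group difference at q < 0.01 is only ~85% at half that size — and the
state-space arm scaled down to 10 subjects/group since its surrogate
refits dominate runtime; 499 Granger surrogates at q < 0.01, 100 MDS
surrogates at q < 0.05, cross-paired difference nulls at q < 0.01);
latency ordering on lead-lag cohorts (hub leads by one TR); graph-metric
oracle checks (100 random digraphs, M ≤ 8); lasso support recovery
(n = 100, SNR 3, 20 seeds) and a convex-optimization cross-check; and a
double run of the demo pipeline (5 subjects/group) compared byte for
byte. These scales are the package's validation design; each function
accepts larger values.

## Known limitations

- The MDS estimator reports MAP point estimates of parameters with a
  Gram-based spread summary, not full parameter posteriors.
- Q is estimated diagonally; correlated state noise is simulated but
  not estimated.
- Granger influences are computed on the BOLD scale; systematic
  inter-regional HRF differences can bias doi signs in principle (the
  state-space route is the cross-check, and on synthetic cohorts the
  two methods agree on the hub).
- With ~100-surrogate nulls the smallest achievable q is bounded below;
  see the empirical-p floor discussion above.
- The pipeline assumes one shared event design per cohort.
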