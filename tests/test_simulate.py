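import numpy as np
import pytest

from neurocausal.datatypes import MDSParameters
from neurocausal.simulate import (CohortSpec, GroupSpec, generate_cohort,
                                  null_cohort_spec, simulate_bold,
                                  simulate_latent)


def _params(C, M=2, q=0.0, obs=0.0, L=16, D=1.0):
    return MDSParameters(
        n_regions=M, modulatory_matrices=np.asarray(C)[None],
        input_strengths=np.full(M, D), state_noise_cov=np.eye(M) * q,
        hrf_basis_weights=np.tile([1.0, 0.0], (M, 1)),
        obs_noise_var=np.full(M, obs), embedding_lags=L)


class TestLatentDynamics:
    def test_unforced_noiseless_system_stays_zero(self, design):
        p = _params(np.zeros((2, 2)), D=0.0)
        s = simulate_latent(p, design, seed=0)
        assert np.all(s == 0.0)

    def test_one_step_echo_closed_form(self, design):
        # region 1 drives region 2 with weight 0.8 and one-step delay
        C = np.array([[0.0, 0.0], [0.8, 0.0]])
        p = _params(C, q=0.0, D=1.0)
        T = design.n_timepoints
        s = simulate_latent(p, design, seed=0)
        box = design.boxcar(T)
        v = design.boxcar(T)
        # closed form: s1(t) = box(t); s2(t) = v(t)*0.8*s1(t-1) + box(t)
        s1 = box.copy()
        s2 = box.copy()
        s2[1:] += v[1:] * 0.8 * s1[:-1]
        np.testing.assert_allclose(s[:, 0], s1, atol=1e-12)
        np.testing.assert_allclose(s[:, 1], s2, atol=1e-12)

    def test_hub_targets_lag_positive(self, design):
        C = np.eye(5) * 0.4
        C[1:, 0] = 0.8  # hub = region 0
        p = _params(C, M=5, q=1.0)
        # keep the modulatory input on for the whole (long) simulation
        s = simulate_latent(p, design, n_timepoints=4000, seed=1,
                            modulators=np.ones((1, 4000)))
        hub = s[:, 0]
        for m in range(1, 5):
            lag0 = np.corrcoef(hub, s[:, m])[0, 1]
            lag1 = np.corrcoef(hub[:-1], s[1:, m])[0, 1]
            assert lag1 > lag0  # target follows the hub

    def test_linearity_in_input_strength(self, design):
        C = np.eye(2) * 0.3
        sa = simulate_latent(_params(C, D=1.0), design, seed=0)
        sb = simulate_latent(_params(C, D=2.0), design, seed=0)
        np.testing.assert_allclose(sb, 2.0 * sa, atol=1e-10)

    def test_stationary_variance_split_half(self, design):
        C = np.eye(3) * 0.5
        C[1, 0] = 0.6
        p = _params(C, M=3, q=1.0)
        s = simulate_latent(p, design, n_timepoints=6000, seed=2)
        half = s.shape[0] // 2
        ratio = s[:half].var(axis=0) / s[half:].var(axis=0)
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_unstable_matrix_refused(self):
        with pytest.raises(ValueError, match="spectral radius"):
            _params(np.array([[1.05, 0.0], [0.0, 0.3]]))


class TestBOLDObservation:
    def test_impulse_gives_canonical_hrf(self, basis):
        # noiseless unit impulse in one region reproduces the kernel
        latent = np.zeros((60, 2))
        latent[0, 0] = 1.0
        p = _params(np.zeros((2, 2)))
        ts = simulate_bold(latent, p, basis, seed=0)
        np.testing.assert_allclose(ts.values[:16, 0],
                                   basis.basis_matrix[0], atol=1e-12)
        np.testing.assert_allclose(ts.values[:, 1], 0.0, atol=1e-12)

    def test_derivative_weight_matches_finite_difference(self, basis):
        latent = np.zeros((60, 2))
        latent[0, 0] = 1.0
        p = MDSParameters(
            n_regions=2, modulatory_matrices=np.zeros((1, 2, 2)),
            input_strengths=np.zeros(2), state_noise_cov=np.zeros((2, 2)),
            hrf_basis_weights=np.array([[0.0, 1.0], [1.0, 0.0]]),
            obs_noise_var=np.zeros(2), embedding_lags=16)
        ts = simulate_bold(latent, p, basis, seed=0)
        np.testing.assert_allclose(ts.values[:16, 0], basis.basis_matrix[1],
                                   atol=1e-12)

    def test_same_seed_bit_identical(self, basis, design):
        p = _params(np.eye(2) * 0.3, q=1.0, obs=0.5)
        s = simulate_latent(p, design, seed=3)
        a = simulate_bold(s, p, basis, seed=4)
        b = simulate_bold(s, p, basis, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_basis_lag_mismatch_raises(self, basis):
        p = _params(np.zeros((2, 2)), L=40)
        with pytest.raises(ValueError, match="embedding_lags"):
            simulate_bold(np.zeros((60, 2)), p, basis, seed=0)


class TestCohortGeneration:
    def test_ground_truth_group_delta(self):
        spec = CohortSpec(seed=3)
        spec.groups["adult"].n_subjects = 25
        spec.groups["child"].n_subjects = 25
        coh = generate_cohort(spec)
        idx = spec.region_names.index
        adult = np.mean([coh.ground_truth[ts.subject_id][idx("rPPC"), idx("rAI")]
                         for ts in coh.group_subjects("adult")])
        child = np.mean([coh.ground_truth[ts.subject_id][idx("rPPC"), idx("rAI")]
                         for ts in coh.group_subjects("child")])
        delta = spec.groups["child"].edge_deltas[("rAI", "rPPC")]
        assert abs((adult - child) - (-delta)) < 4 * spec.perturb_sd / np.sqrt(25)

    def test_zero_behavior_coupling_decorrelates(self):
        spec = null_cohort_spec(seed=4, n_subjects=30)
        coh = generate_cohort(spec)
        rt = coh.behavior.set_index("subject_id")["reaction_time"]
        for edge in [("rAI", "rPPC"), ("rAI", "ACC")]:
            idx = spec.region_names.index
            strengths = np.array([coh.ground_truth[s][idx(edge[1]), idx(edge[0])]
                                  for s in rt.index])
            if strengths.std() == 0:  # zero-coupling template has no edges
                continue
            assert abs(np.corrcoef(rt, strengths)[0, 1]) < 0.4

    def test_structure_coupling_only_in_flagged_group(self):
        spec = CohortSpec(seed=6)
        spec.groups["adult"].n_subjects = 40
        spec.groups["child"].n_subjects = 40
        spec.groups["adult"].structure_coupled = True
        coh = generate_cohort(spec)
        idx = spec.region_names.index
        rs = {}
        for g in ("adult", "child"):
            subs = [ts.subject_id for ts in coh.group_subjects(g)]
            strengths = [coh.ground_truth[s][idx("rPPC"), idx("rAI")]
                         for s in subs]
            sel = coh.structure[
                (coh.structure["subject_id"].isin(subs))
                & (coh.structure["region_a"] == "rAI")
                & (coh.structure["region_b"] == "rPPC")]
            fd = sel.set_index("subject_id").loc[subs, "fiber_density"]
            rs[g] = np.corrcoef(strengths, fd)[0, 1]
        assert rs["adult"] > 0.3
        assert abs(rs["child"]) < rs["adult"]

    def test_generation_is_pure_function_of_seed(self):
        a = generate_cohort(CohortSpec(seed=11))
        b = generate_cohort(CohortSpec(seed=11))
        np.testing.assert_array_equal(a.timeseries[0].values,
                                      b.timeseries[0].values)
        assert a.behavior.equals(b.behavior)

    def test_too_few_subjects_refused(self):
        with pytest.raises(ValueError, match=">= 3"):
            CohortSpec(groups={"g": GroupSpec(n_subjects=2)})

    def test_unknown_region_in_edge_refused(self):
        with pytest.raises(ValueError, match="unknown region"):
            CohortSpec(base_edges={("rAI", "nope"): 0.5})
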