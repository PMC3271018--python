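import numpy as np
import pandas as pd
import pytest

from neurocausal.connectivity import (compare_fc_groups, compare_structural,
                                      functional_connectivity,
                                      structure_function_correlation)
from neurocausal.datatypes import ROITimeSeries


def _ts(vals, names=None):
    names = names or tuple(f"r{i}" for i in range(vals.shape[1]))
    return ROITimeSeries(vals, names, 2.0)


class TestFunctionalConnectivity:
    def test_identical_series_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(300)
        fc = functional_connectivity(_ts(np.column_stack([x, x + 1e-12,
                                                          rng.standard_normal(300)])))
        assert fc[0, 1] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        fc = functional_connectivity(_ts(rng.standard_normal((2000, 4))))
        off = fc[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.06)

    def test_shared_trend_removed(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(500)
        b = rng.standard_normal(500)
        base = functional_connectivity(_ts(np.column_stack([a, b])))[0, 1]
        t = np.arange(500.0)
        trended = functional_connectivity(
            _ts(np.column_stack([a + 0.05 * t, b + 0.05 * t])))[0, 1]
        assert abs(trended - base) < 1e-10

    def test_confound_regression(self):
        rng = np.random.default_rng(3)
        conf = rng.standard_normal(400)
        a = rng.standard_normal(400) + 2 * conf
        b = rng.standard_normal(400) + 2 * conf
        raw = functional_connectivity(_ts(np.column_stack([a, b])))[0, 1]
        clean = functional_connectivity(_ts(np.column_stack([a, b])),
                                        confounds=conf[:, None])[0, 1]
        assert abs(clean) < abs(raw)

    def test_constant_after_residualization_rejected(self):
        t = np.arange(300.0)
        vals = np.column_stack([t, np.random.default_rng(0).standard_normal(300)])
        with pytest.raises(ValueError, match="undefined"):
            functional_connectivity(_ts(vals))

    def test_matrix_invariants(self):
        rng = np.random.default_rng(4)
        fc = functional_connectivity(_ts(rng.standard_normal((200, 5))))
        np.testing.assert_allclose(fc, fc.T)
        np.testing.assert_allclose(np.diag(fc), 1.0)
        assert np.all(np.abs(fc) <= 1.0)


class TestGroupComparison:
    def test_fisher_roundtrip(self):
        r = np.linspace(-0.999, 0.999, 21)
        np.testing.assert_allclose(np.tanh(np.arctanh(r)), r, atol=1e-12)

    def test_identical_groups_not_flagged(self):
        rng = np.random.default_rng(5)
        fc = np.stack([np.corrcoef(rng.standard_normal((4, 100)))
                       for _ in range(6)])
        out = compare_fc_groups(fc, fc, ("a", "b", "c", "d"), alpha=0.05)
        assert not out["significant"].any()
        np.testing.assert_allclose(out["mean_diff"], 0.0, atol=1e-12)

    def test_label_flip_changes_sign(self):
        rng = np.random.default_rng(6)
        fcA = np.stack([np.corrcoef(rng.standard_normal((3, 80)))
                        for _ in range(5)])
        fcB = np.stack([np.corrcoef(rng.standard_normal((3, 80)))
                        for _ in range(5)])
        ab = compare_fc_groups(fcA, fcB, ("a", "b", "c"))
        ba = compare_fc_groups(fcB, fcA, ("a", "b", "c"))
        np.testing.assert_allclose(ab["mean_diff"], -ba["mean_diff"],
                                   atol=1e-12)

    def test_weakened_hub_pairs_flagged(self, two_group_cohort):
        from neurocausal.preprocess import preprocess_timeseries
        fc = {}
        for g in ("adult", "child"):
            fc[g] = np.stack([
                functional_connectivity(preprocess_timeseries(ts))
                for ts in two_group_cohort.group_subjects(g)])
        out = compare_fc_groups(fc["adult"], fc["child"],
                                two_group_cohort.timeseries[0].region_names,
                                alpha=0.05)
        row = out[(out.region_a == "rAI") & (out.region_b == "rPPC")].iloc[0]
        assert row["mean_diff"] > 0  # adult rAI-rPPC coupling stronger

    def test_too_few_subjects_rejected(self):
        fc = np.stack([np.eye(3)] * 2)
        with pytest.raises(ValueError, match="3 subjects"):
            compare_fc_groups(fc, fc, ("a", "b", "c"))


class TestStructureFunction:
    def test_affine_function_gives_r_one(self, two_group_cohort):
        st = two_group_cohort.structure
        subs = st.loc[st.group == "adult", "subject_id"].unique()
        sel = st[(st.region_a == "rAI") & (st.region_b == "rPPC")
                 & (st.subject_id.isin(subs))]
        fd = sel.set_index("subject_id")["fiber_density"]
        functional = pd.Series(2.0 * fd + 1.0, index=fd.index)
        r, p = structure_function_correlation(functional, st, ("rAI", "rPPC"))
        assert r == pytest.approx(1.0)

    def test_coupled_group_detected_at_n40(self):
        from neurocausal.simulate import CohortSpec, generate_cohort
        spec = CohortSpec(seed=21)
        spec.groups["adult"].n_subjects = 40
        spec.groups["adult"].structure_coupled = True
        spec.groups["child"].n_subjects = 40
        coh = generate_cohort(spec)
        idx = spec.region_names.index
        rs = {}
        for g in ("adult", "child"):
            subs = [ts.subject_id for ts in coh.group_subjects(g)]
            strengths = pd.Series(
                [coh.ground_truth[s][idx("rPPC"), idx("rAI")] for s in subs],
                index=subs)
            sub_struct = coh.structure[coh.structure.subject_id.isin(subs)]
            rs[g] = structure_function_correlation(strengths, sub_struct,
                                                   ("rAI", "rPPC"))
        r_adult, p_adult = rs["adult"]
        assert r_adult > 0 and p_adult < 0.05
        assert abs(rs["child"][0]) < r_adult

    def test_zero_variance_rejected(self, two_group_cohort):
        st = two_group_cohort.structure
        subs = st["subject_id"].unique()[:6]
        flat = pd.Series(1.0, index=subs)
        with pytest.raises(ValueError, match="zero-variance"):
            structure_function_correlation(flat, st, ("rAI", "rPPC"))

    def test_too_few_common_subjects_rejected(self, two_group_cohort):
        st = two_group_cohort.structure
        f = pd.Series([1.0, 2.0, 3.0], index=["sub-01", "sub-02", "sub-03"])
        with pytest.raises(ValueError, match=">= 5"):
            structure_function_correlation(f, st, ("rAI", "rPPC"))


class TestStructuralComparison:
    def test_lower_density_child_group_flagged(self, two_group_cohort):
        out = compare_structural(two_group_cohort.structure, ("rAI", "rPPC"))
        fd = out[out.measure == "fiber_density"].iloc[0]
        assert fd["mean_a"] > fd["mean_b"] and fd["p"] < 0.05
        fa = out[out.measure == "mean_fa"].iloc[0]
        assert fa["mean_a"] > fa["mean_b"]

    def test_invalid_fa_rejected_before_testing(self, two_group_cohort):
        st = two_group_cohort.structure.copy()
        st.loc[st.index[0], "mean_fa"] = 1.5
        with pytest.raises(ValueError, match="mean_fa"):
            compare_structural(st, ("rAI", "rPPC"))
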