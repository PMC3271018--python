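import numpy as np
import pytest

from neurocausal.datatypes import ROITimeSeries
from neurocausal.hrf import canonical_hrf
from neurocausal.latency import (EventResponseModel, compare_latencies,
                                 onset_latency, subject_onsets)
from neurocausal.preprocess import preprocess_timeseries
from neurocausal.simulate import generate_leadlag_cohort
from neurocausal.design import generate_event_design


class TestPreprocess:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(200.0)
        vals = np.column_stack([3.0 + 0.5 * t, -1.0 + 2.0 * t])
        ts = ROITimeSeries(vals, ("a", "b"), 2.0)
        out = preprocess_timeseries(ts)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_output_means_zero_and_idempotent(self):
        rng = np.random.default_rng(0)
        ts = ROITimeSeries(rng.standard_normal((150, 3)) + 5.0,
                           ("a", "b", "c"), 2.0)
        once = preprocess_timeseries(ts)
        assert np.all(np.abs(once.values.mean(axis=0)) < 1e-10)
        twice = preprocess_timeseries(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_constant_region_warns_and_zeroes(self):
        vals = np.column_stack([np.ones(100), np.random.default_rng(1)
                                .standard_normal(100)])
        ts = ROITimeSeries(vals, ("const", "ok"), 2.0)
        with pytest.warns(UserWarning, match="const"):
            out = preprocess_timeseries(ts)
        np.testing.assert_allclose(out.values[:, 0], 0.0, atol=1e-12)


class TestEventResponseFit:
    def test_noiseless_weight_recovery(self):
        design = generate_event_design(n_trials=12, seed=0)
        from neurocausal.latency import _event_regressors
        T = design.n_timepoints
        X = _event_regressors(design, T, 2.0)
        true_w = np.array([[1.0, 0.0], [1.0, 0.5], [0.0, 0.0]])
        vals = X @ true_w.T
        ts = ROITimeSeries(vals, ("pure", "mixed", "flat"), 2.0)
        em = EventResponseModel().fit(ts, design)
        np.testing.assert_allclose(em.weights_[0, 0], [1.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(em.weights_[0, 1], [1.0, 0.5], atol=1e-6)
        np.testing.assert_allclose(em.weights_[0, 2], [0.0, 0.0], atol=1e-9)
        # positive derivative weight shifts the fitted peak earlier
        peak_pure = em.responses_["pure"].time_grid[
            np.argmax(em.responses_["pure"].fitted_values)]
        peak_mixed = em.responses_["mixed"].time_grid[
            np.argmax(em.responses_["mixed"].fitted_values)]
        assert peak_mixed < peak_pure

    def test_too_few_events_rejected(self):
        design = generate_event_design(n_trials=3, seed=0)
        ts = ROITimeSeries(np.zeros((design.n_timepoints, 2)) +
                           np.random.default_rng(0).standard_normal(
                               (design.n_timepoints, 2)),
                           ("a", "b"), 2.0)
        with pytest.raises(ValueError, match="events"):
            EventResponseModel().fit(ts, design)


class TestOnsetLatency:
    grid = np.arange(0.0, 24.0, 0.2)

    def test_scale_invariance(self):
        c = canonical_hrf(self.grid)
        base = onset_latency(c, self.grid)[0]
        for k in (0.1, 3.0, 250.0):
            assert onset_latency(k * c, self.grid)[0] == base

    def test_shift_equivariance_within_grid_step(self):
        base = onset_latency(canonical_hrf(self.grid), self.grid)[0]
        shifted = onset_latency(canonical_hrf(self.grid - 1.0), self.grid)[0]
        assert abs((shifted - base) - 1.0) <= 0.2 + 1e-12

    def test_descending_polarity(self):
        c = -canonical_hrf(self.grid)
        onset, ref, pol = onset_latency(c, self.grid)
        assert pol == "descending" and ref < 0
        assert onset == onset_latency(-c, self.grid)[0]

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(2)
        c = canonical_hrf(self.grid - rng.uniform(0, 2))
        onset, ref, pol = onset_latency(c, self.grid, threshold_frac=0.1)
        slope = np.gradient(c, self.grid)
        ipk = int(np.argmax(np.abs(c)))
        start = ipk
        while start > 0 and slope[start - 1] > 0:
            start -= 1
        # brute-force scan over grid points in the rising limb
        expected = None
        for i in range(start, ipk + 1):
            if slope[i] >= 0.1 * slope[start:ipk + 1].max():
                expected = self.grid[i]
                break
        assert onset == expected

    def test_flat_curve_and_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            onset_latency(np.ones(50), np.arange(50.0))
        with pytest.raises(ValueError, match="threshold"):
            onset_latency(canonical_hrf(self.grid), self.grid,
                          threshold_frac=1.2)


class TestLatencyComparison:
    def test_identical_onsets_give_p_one(self):
        import pandas as pd
        df = pd.DataFrame({
            "region": ["a"] * 4 + ["b"] * 4,
            "subject": list(range(4)) * 2,
            "onset": [1.0, 1.1, 0.9, 1.0] * 2,
        })
        out = compare_latencies({"g": df})
        assert np.all(out["within_group"]["p"] == 1.0)

    def test_constructed_group_shift_detected(self):
        import pandas as pd
        rng = np.random.default_rng(3)
        base = rng.normal(2.0, 0.1, size=(8, 3))
        rows = []
        for g, shift in (("a", 0.0), ("b", 0.5)):
            for s in range(8):
                for j, r in enumerate(("r1", "r2", "r3")):
                    rows.append({"region": r, "subject": s,
                                 "onset": base[s, j] + shift, "group": g})
        df = pd.DataFrame(rows)
        out = compare_latencies({g: df[df.group == g] for g in ("a", "b")})
        bt = out["between_group"]
        assert np.all(bt["significant"])
        np.testing.assert_allclose(bt["mean_diff"], -0.5, atol=1e-12)

    def test_leadlag_cohort_hub_orders_first(self):
        coh, design = generate_leadlag_cohort(n_subjects=6, lead=2.0, seed=1)
        pre = [preprocess_timeseries(ts) for ts in coh]
        resp = EventResponseModel().fit(pre, design).responses_
        onsets = subject_onsets(resp)
        means = onsets.groupby("region")["onset"].mean()
        assert means["rAI"] == means.min()

    def test_too_few_subjects_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"region": ["a", "b"], "subject": [0, 0],
                           "onset": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 subjects"):
            compare_latencies({"g": df})
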