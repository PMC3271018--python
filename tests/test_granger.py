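import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from neurocausal.granger import (GrangerCausality, doi_matrix, fit_var,
                                 influence_terms, select_var_order,
                                 surrogate_null_granger, group_causal_graph,
                                 compare_groups_doi)
from neurocausal.datatypes import ROITimeSeries
from neurocausal.inference import difference_null
from neurocausal.preprocess import preprocess_timeseries


def _var1(coef, n, seed, noise=1.0):
    rng = np.random.default_rng(seed)
    M = coef.shape[0]
    x = np.zeros((n, M))
    e = rng.standard_normal((n, M)) * noise
    for t in range(1, n):
        x[t] = coef @ x[t - 1] + e[t]
    return x


class TestVARFit:
    def test_coefficient_recovery(self):
        coef = np.array([[0.5, 0.0], [0.3, 0.4]])
        x = _var1(coef, 2000, seed=0)
        fit = fit_var(x, order=1)
        np.testing.assert_allclose(fit.coefs[0], coef, atol=0.05)

    def test_white_noise_cross_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2000, 3))
        fit = fit_var(x, order=1)
        se = 1.0 / np.sqrt(2000)
        off = fit.coefs[0][~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 3 * se)

    def test_nesting_invariant(self):
        x = _var1(np.array([[0.5, 0.2], [0.0, 0.4]]), 500, seed=2)
        fit = fit_var(x, order=2)
        assert np.all(fit.reduced_var >= fit.full_var[:, None])

    def test_short_series_raises_with_minimum_named(self):
        with pytest.raises(ValueError, match="need more than"):
            fit_var(np.random.default_rng(0).standard_normal((30, 3)), order=1)

    def test_duplicated_region_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((300, 2))
        dup = np.column_stack([x[:, 0], x[:, 0], x[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            fit_var(dup, order=1)


class TestInfluence:
    def test_bivariate_analytic_oracle(self):
        # y(t) = 0.8 x(t-1) + e: F_{x->y} = ln(1 + 0.64), F_{y->x} = 0
        errs, rev = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(2001)
            y = np.empty(2001)
            y[0] = 0
            y[1:] = 0.8 * x[:-1] + rng.standard_normal(2000)
            F = influence_terms(np.column_stack([x, y])[1:], order=1)
            errs.append(abs(F[1, 0] - np.log(1.64)))
            rev.append(F[0, 1])
        assert np.mean(errs) < 0.05
        assert max(rev) < 0.05
        assert np.log(1.64) > 0.3  # forward influence is large

    def test_nonnegative_and_zero_diagonal(self):
        x = _var1(np.eye(3) * 0.4, 400, seed=4)
        F = influence_terms(x, order=1)
        assert np.all(F >= 0)
        assert np.all(np.diag(F) == 0)

    def test_estimator_class_fit_attributes(self, small_cohort):
        ts = preprocess_timeseries(small_cohort.timeseries[0])
        g = GrangerCausality(order=1).fit(ts)
        assert g.influence_.shape == (5, 5)
        np.testing.assert_allclose(g.doi_ + g.doi_.T, 0.0, atol=1e-15)

    def test_white_noise_influences_below_simulated_null(self):
        # analytic small-sample null: simulate independent series
        rng = np.random.default_rng(5)
        null_max = []
        for _ in range(50):
            F = influence_terms(rng.standard_normal((400, 4)), order=1)
            null_max.append(F.max())
        thresh = np.quantile(null_max, 0.99)
        F = influence_terms(np.random.default_rng(123).standard_normal((400, 4)))
        assert F.max() <= thresh * 1.5


class TestDoi:
    def test_symmetric_F_gives_zero(self):
        F = np.array([[0.0, 0.3], [0.3, 0.0]])
        np.testing.assert_array_equal(doi_matrix(F), np.zeros((2, 2)))

    def test_direct_subtraction(self):
        F = np.zeros((2, 2))
        F[1, 0] = 3.0  # x -> y
        F[0, 1] = 1.0  # y -> x
        d = doi_matrix(F)
        assert d[1, 0] == 2.0 and d[0, 1] == -2.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (4, 4),
                      elements=st.floats(0, 5, allow_nan=False)))
    def test_antisymmetry_property(self, F):
        d = doi_matrix(F)
        np.testing.assert_allclose(d + d.T, 0.0, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            doi_matrix(np.array([[0.0, np.nan], [0.0, 0.0]]))


class TestSurrogateNull:
    def test_null_doi_mean_near_zero(self, small_cohort):
        pre = [preprocess_timeseries(ts) for ts in small_cohort.timeseries[:4]]
        null = surrogate_null_granger(pre, n_surrogates=150, seed=0)
        M = pre[0].n_regions
        off = ~np.eye(M, dtype=bool)
        mean = null.values.mean(axis=0)
        se = null.values.std(axis=0) / np.sqrt(null.n_surrogates)
        assert np.all(np.abs(mean[off]) < 4 * se[off])

    def test_bookkeeping_and_determinism(self, small_cohort):
        pre = [preprocess_timeseries(ts) for ts in small_cohort.timeseries[:3]]
        a = surrogate_null_granger(pre, n_surrogates=101, seed=3)
        b = surrogate_null_granger(pre, n_surrogates=101, seed=3)
        assert a.values.shape == (101, 5, 5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_statistic_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="doi"):
            surrogate_null_granger(small_cohort.timeseries[:3], statistic="zzz")


class TestGroupInference:
    def test_identical_groups_no_differences(self, small_cohort):
        pre = [preprocess_timeseries(ts) for ts in small_cohort.timeseries[:5]]
        null = surrogate_null_granger(pre, n_surrogates=120, seed=1)
        dn = difference_null(null, null)
        diff = compare_groups_doi(pre, pre, 1, dn, alpha=0.05)
        assert diff.significant.sum() == 0
        np.testing.assert_array_equal(diff.strength, np.zeros((5, 5)))

    def test_label_swap_flips_difference_signs(self, two_group_cohort):
        adults = [preprocess_timeseries(ts)
                  for ts in two_group_cohort.group_subjects("adult")]
        children = [preprocess_timeseries(ts)
                    for ts in two_group_cohort.group_subjects("child")]
        nA = surrogate_null_granger(adults, n_surrogates=110, seed=2)
        nB = surrogate_null_granger(children, n_surrogates=110, seed=3)
        ab = compare_groups_doi(adults, children, 1,
                                difference_null(nA, nB), alpha=0.05)
        ba = compare_groups_doi(children, adults, 1,
                                difference_null(nB, nA), alpha=0.05)
        np.testing.assert_allclose(ab.strength, -ba.strength, atol=1e-12)

    def test_mismatched_regions_rejected(self, two_group_cohort):
        adults = [preprocess_timeseries(ts)
                  for ts in two_group_cohort.group_subjects("adult")]
        renamed = [ROITimeSeries(ts.values, ("a", "b", "c", "d", "e"),
                                 ts.tr, ts.subject_id) for ts in adults]
        null = surrogate_null_granger(adults, n_surrogates=110, seed=1)
        with pytest.raises(ValueError, match="region set"):
            compare_groups_doi(adults, renamed, 1,
                               difference_null(null, null))

    def test_single_subject_group_warns(self, small_cohort):
        pre = [preprocess_timeseries(small_cohort.timeseries[0])]
        null = surrogate_null_granger(pre, n_surrogates=105, seed=0)
        with pytest.warns(UserWarning, match="unreliable"):
            group_causal_graph(pre, 1, null, alpha=0.05)

    def test_invalid_alpha_rejected(self, small_cohort):
        pre = [preprocess_timeseries(ts) for ts in small_cohort.timeseries[:3]]
        null = surrogate_null_granger(pre, n_surrogates=105, seed=0)
        with pytest.raises(ValueError, match="alpha"):
            group_causal_graph(pre, 1, null, alpha=1.5)


def test_bic_order_selection_prefers_true_order():
    coef = np.array([[0.5, 0.3], [0.0, 0.4]])
    x = _var1(coef, 3000, seed=6)
    assert select_var_order(x, max_order=4) == 1
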