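"""Ground-truth model families: closed forms, sampling, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import l1precision as lp
from l1precision.models import support_from_matrix

from conftest import random_pd_matrix


class TestWeightMatrix:
    def test_shape_and_determinism(self):
        A = lp.generate_weight_matrix(2, 10, seed=3)
        assert A.shape == (10, 2)
        assert np.array_equal(A, lp.generate_weight_matrix(2, 10, seed=3))
        assert not np.array_equal(A, lp.generate_weight_matrix(2, 10, seed=4))

    def test_smallest_case_is_scalar_draw(self):
        assert lp.generate_weight_matrix(1, 1, seed=0).shape == (1, 1)

    def test_standard_normal_moments_over_seeds(self):
        draws = np.concatenate(
            [lp.generate_weight_matrix(2, 10, seed=s).ravel() for s in range(200)])
        assert abs(draws.mean()) < 0.05
        assert abs(draws.var() - 1.0) < 0.05

    @pytest.mark.parametrize("d1,d2", [(0, 5), (5, 0), (-1, 3)])
    def test_rejects_non_positive_dimensions(self, d1, d2):
        with pytest.raises(ValueError):
            lp.generate_weight_matrix(d1, d2, seed=0)


class TestBipartiteModel:
    def test_two_by_two_hand_inverse(self):
        m = lp.build_bipartite_model(np.array([[1.0]]), 1.0, 1.0)
        assert np.allclose(m.C, [[1, 1], [1, 2]])
        assert np.allclose(m.Omega_star, [[2, -1], [-1, 1]])

    def test_zero_weights_give_independence(self):
        m = lp.build_bipartite_model(np.zeros((4, 2)), 1.0, 0.5)
        assert np.allclose(m.C, np.diag(np.concatenate([np.ones(2), 0.5 * np.ones(4)])))
        assert np.count_nonzero(m.Omega_star - np.diag(np.diag(m.Omega_star))) == 0
        assert m.support.n_edges == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_inverse_at_paper_geometry(self, seed):
        A = lp.generate_weight_matrix(2, 10, seed)
        m = lp.build_bipartite_model(A, 1.0, 0.01)
        assert np.abs(m.Omega_star @ m.C - np.eye(m.p)).max() < 1e-8

    def test_closed_form_matches_numeric_inverse_across_noise(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            d1, d2 = rng.integers(1, 5), rng.integers(2, 12)
            sig_eps = 10 ** rng.uniform(-2, 1)
            A = lp.generate_weight_matrix(d1, d2, seed=trial)
            m = lp.build_bipartite_model(A, 1.0, sig_eps ** 2)
            num = np.linalg.inv(m.C)
            rel = np.abs(m.Omega_star - num).max() / np.abs(num).max()
            assert rel < 1e-6

    def test_output_block_is_diagonal(self, small_bipartite_model):
        m = small_bipartite_model
        yy = m.Omega_star[m.d1:, m.d1:]
        assert np.count_nonzero(yy - np.diag(np.diag(yy))) == 0

    def test_support_matches_weight_pattern(self):
        A = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]])
        m = lp.build_bipartite_model(A, 1.0, 0.1)
        # cross edges where A[j, i] != 0 (nodes 0,1 are inputs; 2,3,4 outputs)
        expected = {(0, 2), (1, 3), (0, 4)}
        # rows 0 and 2 of A share input 0 only; no input pair shares an output
        assert m.support.edges == frozenset(expected)

    def test_dense_weights_make_dense_input_block(self, small_bipartite_model):
        m = small_bipartite_model
        cross = m.d1 * m.d2
        xx = m.d1 * (m.d1 - 1) // 2
        assert m.support.n_edges == cross + xx

    def test_rejects_non_positive_variances(self):
        with pytest.raises(ValueError):
            lp.build_bipartite_model(np.ones((2, 2)), -1.0, 0.1)
        with pytest.raises(ValueError):
            lp.build_bipartite_model(np.ones((2, 2)), 1.0, 0.0)


class TestSampling:
    def test_deterministic_per_seed(self, small_bipartite_model):
        a = lp.sample_mvn(small_bipartite_model.C, 50, seed=1)
        b = lp.sample_mvn(small_bipartite_model.C, 50, seed=1)
        assert np.array_equal(a.X, b.X)

    def test_rejects_non_pd_covariance(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            lp.sample_mvn(bad, 10, seed=0)

    def test_empirical_covariance_within_sampling_error(self, small_bipartite_model):
        C = small_bipartite_model.C
        n = 10_000
        S = lp.sample_covariance(lp.sample_mvn(C, n, seed=5))
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C ** 2) / n)
        assert np.all(np.abs(S - C) < 5 * se)


class TestStandardise:
    def test_defining_properties_and_idempotence(self, standardised_sample):
        X = standardised_sample.X
        assert np.abs(X.mean(axis=0)).max() < 1e-10
        assert np.abs(X.std(axis=0) - 1).max() < 1e-10
        again = lp.standardise(standardised_sample)
        assert np.allclose(again.X, X, atol=1e-12)
        assert again.standardized

    def test_two_point_column(self):
        s = lp.DataSample(X=np.array([[0.0], [2.0]]), n=2)
        assert np.allclose(lp.standardise(s).X, [[-1.0], [1.0]])

    def test_rejects_constant_column(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="constant"):
            lp.standardise(lp.DataSample(X=X, n=5))


class TestSampleCovariance:
    def test_unit_diagonal_after_standardising(self, standardised_sample):
        S = lp.sample_covariance(standardised_sample)
        assert np.abs(np.diag(S) - 1).max() < 1e-10

    def test_divisor_n_convention(self):
        s = lp.DataSample(X=np.array([[1.0], [-1.0]]), n=2)
        assert np.isclose(lp.sample_covariance(s)[0, 0], 1.0)
        assert np.isclose(lp.sample_covariance(s, ddof=1)[0, 0], 2.0)

    def test_rank_deficient_when_n_below_p(self):
        data = lp.sample_mvn(np.eye(10), n=4, seed=0)
        S = lp.sample_covariance(data)
        assert np.linalg.matrix_rank(S, tol=1e-10) <= 4

    def test_rejects_single_observation(self):
        with pytest.raises(ValueError):
            lp.sample_covariance(lp.DataSample(X=np.ones((1, 3)), n=1))


class TestThresholdPrecision:
    def test_keeps_only_entries_strictly_above_cutoff(self):
        L0 = np.array([[1.0, 0.1, 0.3], [0.1, 1.0, -0.05], [0.3, -0.05, 1.0]])
        L = lp.threshold_precision(L0, delta=0.1)
        assert L[0, 1] == 0.0  # exactly at the cutoff: removed
        assert L[0, 2] == 0.3
        assert L[1, 2] == 0.0

    def test_limits(self):
        L0 = random_pd_matrix(6, seed=1)
        full = lp.threshold_precision(L0, delta=10.0)
        assert np.count_nonzero(full - np.diag(np.diag(full))) == 0
        noop = lp.threshold_precision(L0, delta=1e-300)
        assert np.array_equal(noop, L0)

    @given(st.floats(min_value=0.01, max_value=2.0), st.floats(min_value=0.01, max_value=2.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_edge_count_monotone_in_delta(self, d_small, d_big):
        lo, hi = sorted([d_small, d_big])
        L0 = random_pd_matrix(8, seed=3)
        n_lo = support_from_matrix(lp.threshold_precision(L0, lo)).n_edges
        n_hi = support_from_matrix(lp.threshold_precision(L0, hi)).n_edges
        assert n_hi <= n_lo


class TestGeneLikeEmulator:
    @pytest.mark.parametrize("d", [10, 40])
    def test_output_is_correlation_pd(self, d):
        C0 = lp.generate_genelike_correlation(d, seed=1)
        assert np.allclose(np.diag(C0), 1.0)
        assert np.allclose(C0, C0.T)
        assert np.linalg.eigvalsh(C0).min() > 0

    def test_noise_dominated_limit_near_identity(self):
        C0 = lp.generate_genelike_correlation(10, n_factors=12, idio_var=500.0, seed=0)
        assert np.abs(C0 - np.eye(10)).max() < 0.25

    def test_strong_collinearity_at_defaults(self):
        for seed in range(5):
            C0 = lp.generate_genelike_correlation(40, seed=seed)
            iu = np.triu_indices(40, 1)
            assert np.abs(C0[iu]).max() > 0.5


class TestThresholdedModel:
    def test_identity_input(self):
        m = lp.build_thresholded_model(np.eye(5), delta=0.1)
        assert np.array_equal(m.Lambda, np.eye(5))
        assert np.array_equal(m.C, np.eye(5))
        assert m.zero_fraction == 1.0
        assert m.support.n_edges == 0

    def test_inverse_pair_and_pd_at_paper_cutoff(self):
        gen = lambda s: lp.generate_genelike_correlation(20, seed=s)
        m = lp.build_thresholded_model(gen, delta=0.1, seed=3)
        assert np.abs(m.C @ m.Lambda - np.eye(20)).max() < 1e-8
        assert np.linalg.eigvalsh(m.Lambda).min() > 0
        off = m.Lambda[~np.eye(20, dtype=bool)]
        surviving = np.abs(off[off != 0])
        assert surviving.min() > 0.1

    def test_fails_with_diagnostic_when_never_pd(self):
        singular = np.ones((3, 3))
        with pytest.raises(ValueError, match="attempt"):
            lp.build_thresholded_model(lambda s: singular, delta=0.1, max_retries=2)
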