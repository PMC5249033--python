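"""Estimator correctness: closed forms, optimality certificates, solver oracles."""

import numpy as np
import pytest
from scipy.optimize import linprog, minimize
from sklearn.covariance import graphical_lasso as sk_graphical_lasso

import l1precision as lp
from l1precision.estimators import SolverSettings, symmetrise_min_magnitude
from l1precision.objective import objective_terms

from conftest import random_pd_matrix

TIGHT = SolverSettings(tol=1e-9, max_iter=2000)


# ---------------------------------------------------------------- oracles

def clime_column_with_duality_certificate(S, lam, i, tol=1e-6):
    """Optimal l1 norm of one CLIME column, certified by an explicit dual LP.

    The dual solution is feasibility-checked with plain numpy, so matching
    primal/dual objectives certify optimality independently of the solver.
    """
    p = S.shape[0]
    A = np.block([[S, -S], [-S, S]])
    e = np.zeros(p)
    e[i] = 1.0
    b = np.concatenate([lam + e, lam - e])
    c = np.ones(2 * p)
    primal = linprog(c, A_ub=A, b_ub=b, bounds=(0, None), method="highs")
    assert primal.success
    dual = linprog(b, A_ub=-A.T, b_ub=c, bounds=(0, None), method="highs")
    assert dual.success
    y = dual.x
    assert y.min() >= -1e-9
    assert np.all(A.T @ y >= -c - 1e-8)  # dual feasibility, checked by hand
    assert abs(primal.fun - (-b @ y)) < tol  # strong duality
    return primal.fun


def scio_column_objective_oracle(S, lam, i):
    """SCIO column optimum via a smooth split-variable QP solved by SLSQP."""
    p = S.shape[0]

    def obj(z):
        b = z[:p] - z[p:]
        return 0.5 * b @ S @ b - b[i] + lam * z.sum()

    def grad(z):
        b = z[:p] - z[p:]
        g = S @ b
        g[i] -= 1.0
        return np.concatenate([g + lam, -g + lam])

    res = minimize(obj, np.zeros(2 * p), jac=grad, method="SLSQP",
                   bounds=[(0, None)] * 2 * p,
                   options={"maxiter": 1000, "ftol": 1e-14})
    assert res.success
    return res.fun


def scio_objective(S, B, lam):
    p = S.shape[0]
    return np.array([0.5 * B[:, i] @ S @ B[:, i] - B[i, i] + lam * np.abs(B[:, i]).sum()
                     for i in range(p)])


# ---------------------------------------------------------------- glasso

class TestGraphicalLasso:
    def test_identity_covariance_closed_form(self):
        est = lp.fit_glasso(np.eye(5), lam=0.5, penalise_diagonal=False)
        assert np.allclose(est.Omega_hat, np.eye(5))
        assert est.converged and est.kkt_residual < 1e-8

    def test_identity_with_penalised_diagonal(self):
        # diagonal entries solve 1/w - 1 - lam = 0
        est = lp.fit_glasso(np.eye(4), lam=0.5, penalise_diagonal=True)
        assert np.allclose(est.Omega_hat, np.eye(4) / 1.5)

    def test_zero_penalty_returns_inverse(self):
        S = random_pd_matrix(6, seed=2)
        est = lp.fit_glasso(S, lam=0.0)
        assert np.allclose(est.Omega_hat, np.linalg.inv(S), atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_sklearn_oracle(self, seed):
        S = random_pd_matrix(5, seed=seed)
        lam = 0.2
        est = lp.fit_glasso(S, lam, settings=TIGHT)
        _, prec_sk = sk_graphical_lasso(S, alpha=lam, tol=1e-10, max_iter=2000)
        ours = objective_terms(est.Omega_hat, S, lam).total
        theirs = objective_terms(prec_sk, S, lam).total
        assert abs(ours - theirs) < 1e-6
        assert est.kkt_residual < 1e-6

    def test_positive_definite_and_symmetric(self, standardised_sample):
        S = lp.sample_covariance(standardised_sample)
        est = lp.fit_glasso(S, lam=0.05, settings=TIGHT)
        assert np.array_equal(est.Omega_hat, est.Omega_hat.T)
        assert np.linalg.eigvalsh(est.Omega_hat).min() > 0


# ---------------------------------------------------------------- CLIME

class TestClime:
    def test_identity_covariance_shrinks_diagonal(self):
        est = lp.fit_clime(np.eye(4), lam=0.5)
        assert np.allclose(est.Omega_hat, 0.5 * np.eye(4), atol=1e-9)

    def test_full_shrinkage_to_zero(self):
        est = lp.fit_clime(np.eye(4), lam=1.0)
        assert np.allclose(est.Omega_hat, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_column_norms_match_lp_duality_oracle(self, seed):
        S = random_pd_matrix(6, seed=seed + 10)
        lam = 0.3
        est = lp.fit_clime(S, lam)
        # feasibility certificate of the assembled columns
        assert est.kkt_residual <= 1e-8
        c = lp.Clime(alpha=lam, covariance="precomputed").fit(S)
        for i in range(6):
            opt = clime_column_with_duality_certificate(S, lam, i)
            assert abs(np.abs(c.columns_[:, i]).sum() - opt) < 1e-6

    def test_symmetry(self):
        S = random_pd_matrix(7, seed=3)
        est = lp.fit_clime(S, lam=0.2)
        assert np.array_equal(est.Omega_hat, est.Omega_hat.T)


# ---------------------------------------------------------------- SCIO

class TestScio:
    def test_identity_covariance_soft_threshold(self):
        est = lp.fit_scio(np.eye(4), lam=0.3)
        assert np.allclose(est.Omega_hat, 0.7 * np.eye(4), atol=1e-9)

    def test_zero_solution_at_large_penalty(self):
        est = lp.fit_scio(np.eye(4), lam=1.0)
        assert np.allclose(est.Omega_hat, 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_columns_match_qp_oracle_and_kkt(self, seed):
        S = random_pd_matrix(6, seed=seed + 20)
        lam = 0.25
        s = lp.Scio(alpha=lam, covariance="precomputed").fit(S)
        ours = scio_objective(S, s.columns_, lam)
        for i in range(6):
            opt = scio_column_objective_oracle(S, lam, i)
            assert ours[i] <= opt + 1e-6
        assert s.kkt_residual_ < 1e-6
        assert s.converged_

    def test_ill_conditioned_input_still_converges(self, small_bipartite_model,
                                                   standardised_sample):
        S = lp.sample_covariance(standardised_sample)
        est = lp.fit_scio(S, lam=0.03)
        assert est.converged
        assert est.kkt_residual < 1e-4


# ---------------------------------------------------------------- shared pieces

class TestSymmetriseMinMagnitude:
    def test_quoted_rule(self):
        M = np.eye(2)
        M[0, 1], M[1, 0] = 0.8, -0.2
        out = symmetrise_min_magnitude(M)
        assert out[0, 1] == out[1, 0] == -0.2

    def test_tie_takes_upper_triangle(self):
        M = np.eye(2)
        M[0, 1], M[1, 0] = 0.5, -0.5
        out = symmetrise_min_magnitude(M)
        assert out[0, 1] == out[1, 0] == 0.5

    def test_symmetric_input_unchanged(self):
        S = random_pd_matrix(5, seed=0)
        assert np.array_equal(symmetrise_min_magnitude(S), S)


class TestNaive:
    def test_zero_target_gives_diagonal(self):
        S = random_pd_matrix(5, seed=1)
        est = lp.naive_estimate(S, target_edges=0)
        assert np.count_nonzero(est.Omega_hat - np.diag(np.diag(est.Omega_hat))) == 0

    def test_full_target_returns_inverse(self):
        S = random_pd_matrix(5, seed=2)
        est = lp.naive_estimate(S, target_edges=10)
        assert np.allclose(est.Omega_hat, np.linalg.inv(S), atol=1e-10)

    def test_exact_covariance_recovers_exact_support(self, small_bipartite_model):
        m = small_bipartite_model
        est = lp.naive_estimate(m.C, target_edges=m.support.n_edges)
        assert lp.support_of(est).edges == m.support.edges

    def test_singular_covariance_rejected(self):
        S = np.ones((4, 4)) + np.eye(4) * 1e-15
        with pytest.raises(ValueError, match="singular"):
            lp.naive_estimate(S, target_edges=2)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lp.naive_estimate(np.eye(4), target_edges=7)
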