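"""l1-penalised precision-matrix estimators with a scikit-learn interface.

``GraphicalLasso`` (penalised Gaussian likelihood, block coordinate
descent), ``Clime`` (constrained l1 minimisation, per-column linear
programs), ``Scio`` (per-column quadratic lasso, coordinate descent) and
``NaiveInverseThreshold`` (invert the sample covariance and keep the
largest off-diagonal entries).  Every estimator accepts either raw data
(``covariance="empirical"``) or a precomputed covariance matrix in
``fit`` and exposes ``precision_``, ``converged_``, ``n_iter_`` and
``kkt_residual_`` after fitting.

The module-level ``fit_glasso`` / ``fit_clime`` / ``fit_scio`` /
``naive_estimate`` functions are thin wrappers returning a
:class:`PrecisionEstimate` record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from . import _solvers
from .models import DataSample, sample_covariance, standardise

__all__ = [
    "SolverSettings",
    "PrecisionEstimate",
    "GraphicalLasso",
    "Clime",
    "Scio",
    "NaiveInverseThreshold",
    "fit_glasso",
    "fit_clime",
    "fit_scio",
    "naive_estimate",
    "symmetrise_min_magnitude",
    "METHOD_NAMES",
]

METHOD_NAMES = ("glasso", "clime", "scio", "naive", "fmpl")


@dataclass(frozen=True)
class SolverSettings:
    """Shared numerical knobs for the iterative solvers."""

    tol: float = 1e-6
    max_iter: int = 500
    zero_tol: float = 1e-8

    def __post_init__(self):
        if self.tol <= 0 or self.max_iter <= 0 or self.zero_tol <= 0:
            raise ValueError("all solver settings must be positive")


@dataclass(frozen=True)
class PrecisionEstimate:
    """A fitted precision matrix with its optimisation metadata."""

    Omega_hat: np.ndarray
    method: str
    lam: Optional[float]
    converged: bool
    n_iter: int
    kkt_residual: float
    penalise_diagonal: Optional[bool] = None

    @property
    def p(self) -> int:
        return self.Omega_hat.shape[0]


def _as_covariance(est, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if est.covariance == "precomputed":
        S = 0.5 * (X + X.T)
    else:
        sample = DataSample(X=X, n=X.shape[0])
        if est.standardize:
            sample = standardise(sample)
        S = sample_covariance(sample)
    if S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrix must be square")
    return S


def symmetrise_min_magnitude(M: np.ndarray) -> np.ndarray:
    """Symmetrise a column-wise estimate by keeping the smaller-magnitude entry.

    For each unordered pair, whichever of M[i, j], M[j, i] has the smaller
    absolute value is written to both positions; exact-magnitude ties take
    the upper-triangle entry M[i, j] (i < j).
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("square input required")
    U = np.triu(M, k=1)
    L = np.tril(M, k=-1).T
    keep_upper = np.abs(U) <= np.abs(L)  # tie -> upper triangle
    W = np.where(keep_upper, U, L)
    out = np.diag(np.diag(M)) + np.triu(W, 1) + np.triu(W, 1).T
    return out


class GraphicalLasso(BaseEstimator):
    """l1-penalised Gaussian maximum likelihood (graphical lasso).

    Maximises ``log det(Omega) - trace(Omega S) - alpha * |Omega|_1`` over
    positive-definite matrices by block coordinate descent, with the
    diagonal excluded from the penalty by default (``penalize_diagonal``
    restores the all-elements variant).

    Parameters
    ----------
    alpha : float
        Regularisation strength, >= 0.  ``alpha = 0`` requires an
        invertible covariance and returns the unpenalised MLE S^-1.
    penalize_diagonal : bool
        Include the diagonal in the l1 penalty.
    covariance : {"empirical", "precomputed"}
        Whether ``fit`` receives raw data or a covariance matrix.
    standardize : bool
        Centre/scale columns before the empirical covariance.
    tol : float
        KKT tolerance deciding the ``converged_`` flag.
    max_iter : int
        Cap on outer sweeps.
    """

    def __init__(self, alpha=0.1, penalize_diagonal=False, covariance="empirical",
                 standardize=False, tol=1e-6, max_iter=500, zero_tol=1e-8):
        self.alpha = alpha
        self.penalize_diagonal = penalize_diagonal
        self.covariance = covariance
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.zero_tol = zero_tol

    def fit(self, X, y=None):
        S = _as_covariance(self, X)
        lam = float(self.alpha)
        if lam < 0:
            raise ValueError("alpha must be non-negative")
        if lam == 0.0:
            Om = np.linalg.inv(S)
            Om = 0.5 * (Om + Om.T)
            self.precision_, self.covariance_ = Om, S.copy()
            self.n_iter_, self.converged_ = 0, True
            self.kkt_residual_ = 0.0
            return self
        # inner lasso tolerance well below the W-change tolerance
        w_tol = self.tol * max(1.0, np.abs(S).max()) * 1e-2
        Om, W, B, n_sweeps, conv = _solvers.glasso_bcd(
            np.ascontiguousarray(S, dtype=float), lam, bool(self.penalize_diagonal),
            w_tol, int(self.max_iter), w_tol * 1e-2, 200,
        )
        self.precision_, self.covariance_ = Om, W
        self.n_iter_ = int(n_sweeps)
        self.kkt_residual_ = self._kkt_residual(S, Om, W, lam)
        self.converged_ = bool(conv)
        return self

    def _kkt_residual(self, S, Om, W, lam):
        """Max violation of the stationarity conditions of the penalised likelihood."""
        G = S - W  # = S - Omega^-1 at convergence
        p = S.shape[0]
        active = np.abs(Om) > self.zero_tol
        pen = ~np.eye(p, dtype=bool) | bool(self.penalize_diagonal)
        res_active = np.abs(G + lam * np.sign(Om))
        res_inactive = np.maximum(0.0, np.abs(G) - lam)
        res = np.where(active, res_active, res_inactive)
        res_unpen = np.abs(G)
        return float(np.where(pen, res, res_unpen).max())

    def objective(self, S: np.ndarray) -> float:
        """Penalised log-likelihood of the fitted precision at covariance S."""
        from .objective import objective_terms

        return objective_terms(self.precision_, S, self.alpha, self.penalize_diagonal).total


class Clime(BaseEstimator):
    """Constrained l1-minimisation precision estimator.

    Each column solves ``min |b|_1  s.t.  |S b - e_i|_inf <= alpha`` as a
    linear program over split positive/negative parts; the assembled matrix
    is symmetrised by the min-magnitude rule.
    """

    def __init__(self, alpha=0.1, covariance="empirical", standardize=False,
                 zero_tol=1e-8, feas_tol=1e-8):
        self.alpha = alpha
        self.covariance = covariance
        self.standardize = standardize
        self.zero_tol = zero_tol
        self.feas_tol = feas_tol

    def fit(self, X, y=None):
        S = _as_covariance(self, X)
        lam = float(self.alpha)
        if lam < 0:
            raise ValueError("alpha must be non-negative")
        p = S.shape[0]
        A_ub = np.block([[S, -S], [-S, S]])
        c = np.ones(2 * p)
        B = np.empty((p, p))
        n_iter = 0
        for i in range(p):
            e = np.zeros(p)
            e[i] = 1.0
            b_ub = np.concatenate([lam + e, lam - e])
            res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
            if not res.success:
                raise ValueError(
                    f"CLIME column {i} infeasible or unsolved at lam={lam}: {res.message}"
                )
            B[:, i] = res.x[:p] - res.x[p:]
            n_iter = max(n_iter, int(res.nit or 0))
        self.columns_ = B
        # feasibility certificate on the raw columns, before symmetrisation
        self.kkt_residual_ = float(max(0.0, np.abs(S @ B - np.eye(p)).max() - lam))
        self.precision_ = symmetrise_min_magnitude(B)
        self.n_iter_ = n_iter
        self.converged_ = self.kkt_residual_ <= self.feas_tol
        return self


class Scio(BaseEstimator):
    """Sparse column-wise inverse operator.

    Column i minimises ``0.5 b' S b - e_i' b + alpha |b|_1`` by cyclic
    coordinate descent with soft-thresholding; a single shared alpha is
    used for all columns and the result is min-magnitude symmetrised.
    """

    def __init__(self, alpha=0.1, covariance="empirical", standardize=False,
                 tol=1e-8, max_iter=100_000, zero_tol=1e-8):
        self.alpha = alpha
        self.covariance = covariance
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.zero_tol = zero_tol

    def fit(self, X, y=None):
        S = np.ascontiguousarray(_as_covariance(self, X), dtype=float)
        lam = float(self.alpha)
        if lam < 0:
            raise ValueError("alpha must be non-negative")
        p = S.shape[0]
        B = np.zeros((p, p))
        n_iter = 0
        conv_all = True
        for i in range(p):
            beta = B[:, i].copy()
            n_it, conv = _solvers.scio_column(S, i, lam, beta, self.tol, int(self.max_iter))
            B[:, i] = beta
            n_iter = max(n_iter, n_it)
            conv_all = conv_all and conv
        self.columns_ = B
        self.kkt_residual_ = self._kkt_residual(S, B, lam)
        self.precision_ = symmetrise_min_magnitude(B)
        self.n_iter_ = n_iter
        self.converged_ = bool(conv_all)
        return self

    def _kkt_residual(self, S, B, lam):
        """Per-column KKT: |S b - e_i| <= lam off-support, equality with sign on it."""
        p = S.shape[0]
        G = S @ B - np.eye(p)  # gradient of the smooth part, per column
        active = np.abs(B) > self.zero_tol
        res_active = np.abs(G + lam * np.sign(B))
        res_inactive = np.maximum(0.0, np.abs(G) - lam)
        return float(np.where(active, res_active, res_inactive).max())


class NaiveInverseThreshold(BaseEstimator):
    """Invert the covariance and keep the largest off-diagonal entries.

    Keeps the ``target_edges`` unordered pairs of largest magnitude in
    S^-1 (both symmetric positions), zeroes the rest, keeps the diagonal.
    Requires the ground-truth edge count, so it is an oracle baseline,
    not a practical estimator.
    """

    def __init__(self, target_edges=0, covariance="empirical", standardize=False,
                 cond_max=1e12):
        self.target_edges = target_edges
        self.covariance = covariance
        self.standardize = standardize
        self.cond_max = cond_max

    def fit(self, X, y=None):
        S = _as_covariance(self, X)
        p = S.shape[0]
        m_max = p * (p - 1) // 2
        if not (0 <= self.target_edges <= m_max):
            raise ValueError(f"target_edges must lie in [0, {m_max}]")
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > self.cond_max:
            raise ValueError(
                f"sample covariance is singular or near-singular (cond={cond:.3e}); "
                "add an explicit ridge before calling if this is intended"
            )
        Om = np.linalg.inv(S)
        Om = 0.5 * (Om + Om.T)
        iu, ju = np.triu_indices(p, k=1)
        vals = np.abs(Om[iu, ju])
        keep = np.zeros(len(vals), dtype=bool)
        if self.target_edges > 0:
            order = np.lexsort((ju, iu, -vals))  # deterministic tie-break by (i, j)
            keep[order[: self.target_edges]] = True
        out = np.diag(np.diag(Om))
        out[iu[keep], ju[keep]] = Om[iu[keep], ju[keep]]
        out[ju[keep], iu[keep]] = Om[ju[keep], iu[keep]]
        self.precision_ = out
        self.n_iter_ = 0
        self.converged_ = True
        self.kkt_residual_ = 0.0
        return self


def _wrap(est, method, lam, pen_diag=None) -> PrecisionEstimate:
    return PrecisionEstimate(
        Omega_hat=est.precision_, method=method, lam=lam,
        converged=est.converged_, n_iter=est.n_iter_,
        kkt_residual=est.kkt_residual_, penalise_diagonal=pen_diag,
    )


def fit_glasso(S, lam, penalise_diagonal=False, settings=SolverSettings()) -> PrecisionEstimate:
    est = GraphicalLasso(alpha=lam, penalize_diagonal=penalise_diagonal,
                         covariance="precomputed", tol=settings.tol,
                         max_iter=settings.max_iter, zero_tol=settings.zero_tol).fit(S)
    return _wrap(est, "glasso", lam, penalise_diagonal)


def fit_clime(S, lam, settings=SolverSettings()) -> PrecisionEstimate:
    est = Clime(alpha=lam, covariance="precomputed",
                zero_tol=settings.zero_tol).fit(S)
    return _wrap(est, "clime", lam)


def fit_scio(S, lam, settings=SolverSettings()) -> PrecisionEstimate:
    est = Scio(alpha=lam, covariance="precomputed", tol=min(settings.tol, 1e-8),
               max_iter=max(settings.max_iter, 100_000), zero_tol=settings.zero_tol).fit(S)
    return _wrap(est, "scio", lam)


def naive_estimate(S, target_edges: int) -> PrecisionEstimate:
    est = NaiveInverseThreshold(target_edges=target_edges, covariance="precomputed").fit(S)
    return _wrap(est, "naive", None)
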