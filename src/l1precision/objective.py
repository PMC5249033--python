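"""Decomposition of the penalised-likelihood objective and its analytic values.

The graphical-lasso objective at a candidate precision matrix Omega is

    log det(Omega) - trace(Omega S) - lam * |Omega|_1,

and at the bipartite ground truth every term has a closed form or bound:
log det(C^-1) = -(d1 + d2) log sigma_x2 - d2 log sigma_eps2,
-trace(C C^-1) = -(d1 + d2), and the penalty magnitude is bounded below by
lam * sigma_x2^-1 * sigma_eps2^-1 * (d2 + 2 |A|_1) — the term that blows
up as the noise vanishes and makes the truth a terrible optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import BipartiteModel

__all__ = [
    "ObjectiveBreakdown",
    "CheckResult",
    "objective_terms",
    "analytic_truth_terms",
    "verify_blockdet_identity",
    "verify_trace_l1_bound",
    "PreconditionError",
]


class PreconditionError(ValueError):
    """An input violated a stated precondition (as opposed to a failed bound)."""


@dataclass(frozen=True)
class ObjectiveBreakdown:
    logdet_term: float
    trace_term: float  # -trace(Omega S)
    penalty_term: float  # -lam * |Omega|_1 under the diagonal convention used
    lam: float
    penalise_diagonal: bool

    @property
    def loglik(self) -> float:
        return self.logdet_term + self.trace_term

    @property
    def total(self) -> float:
        return self.loglik + self.penalty_term


@dataclass(frozen=True)
class CheckResult:
    passed: bool
    lhs: float
    rhs: float

    @property
    def gap(self) -> float:
        return self.rhs - self.lhs


def _l1(Omega: np.ndarray, penalise_diagonal: bool) -> float:
    a = np.abs(Omega).sum()
    if not penalise_diagonal:
        a -= np.abs(np.diag(Omega)).sum()
    return float(a)


def objective_terms(Omega, S, lam: float, penalise_diagonal: bool = False) -> ObjectiveBreakdown:
    """Exact terms of the penalised objective at Omega given covariance S."""
    Omega = np.asarray(Omega, dtype=float)
    S = np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(Omega)
    if sign <= 0:
        raise ValueError("Omega must be positive definite (log det undefined)")
    return ObjectiveBreakdown(
        logdet_term=float(logdet),
        trace_term=float(-np.trace(Omega @ S)),
        penalty_term=-lam * _l1(Omega, penalise_diagonal),
        lam=float(lam),
        penalise_diagonal=bool(penalise_diagonal),
    )


def analytic_truth_terms(model: BipartiteModel, lam: float):
    """Closed-form objective terms at the bipartite ground truth.

    Returns (logdet, trace, penalty_bound):
    ``logdet`` and ``trace`` are exact; ``penalty_bound`` is the strict
    upper bound on the penalty term, -lam/(sigma_x2*sigma_eps2) * (d2 + 2|A|_1),
    obtained by dropping the top-left block from |C^-1|_1.
    """
    d1, d2 = model.d1, model.d2
    logdet = -(d1 + d2) * np.log(model.sigma_x2) - d2 * np.log(model.sigma_eps2)
    trace = -(d1 + d2)
    a1 = np.abs(model.A).sum()
    bound = -lam / (model.sigma_x2 * model.sigma_eps2) * (d2 + 2.0 * a1)
    return float(logdet), float(trace), float(bound)


def verify_blockdet_identity(model: BipartiteModel, rtol: float = 1e-6) -> CheckResult:
    """Dense log-determinant of Omega* against its block-determinant closed form."""
    sign, numeric = np.linalg.slogdet(model.Omega_star)
    if sign <= 0:
        raise ValueError("model precision matrix is not positive definite")
    closed, _, _ = analytic_truth_terms(model, lam=0.0)
    scale = max(1.0, abs(closed))
    return CheckResult(passed=abs(numeric - closed) <= rtol * scale,
                       lhs=float(numeric), rhs=float(closed))


def verify_trace_l1_bound(C, Omega, slack: float = 1e-12) -> CheckResult:
    """trace(C Omega) <= |Omega|_1 whenever every |C_ij| <= 1.

    This is the mechanism by which a bounded-objective estimate can always
    be constructed for normalised covariances, regardless of the truth.
    """
    C = np.asarray(C, dtype=float)
    Omega = np.asarray(Omega, dtype=float)
    if np.abs(C).max() > 1 + 1e-12:
        raise PreconditionError(
            f"|C|_inf = {np.abs(C).max():.6g} > 1; normalise the covariance first"
        )
    lhs = float(np.trace(C @ Omega))
    rhs = float(np.abs(Omega).sum())
    return CheckResult(passed=lhs <= rhs + slack, lhs=lhs, rhs=rhs)
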