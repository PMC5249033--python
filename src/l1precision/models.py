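"""Ground-truth model families with exact covariance/precision pairs.

Two families are provided:

* a bipartite latent-linear model ``y = A x + eps`` whose covariance and
  precision matrices are available in closed form, and whose precision
  matrix becomes arbitrarily large (entrywise) as the noise variance
  shrinks while its sparsity pattern stays fixed — the adversarial case
  for l1-penalised structure learning;
* a "gene-like" family built by inverting a dense, strongly collinear
  correlation matrix and hard-thresholding the resulting precision
  matrix, which mimics sparse models derived from gene expression data.

Both produce exact (covariance, precision, support) triples suitable for
oracle-calibrated support-recovery experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "EdgeSet",
    "DataSample",
    "BipartiteModel",
    "ThresholdedGeneModel",
    "generate_weight_matrix",
    "build_bipartite_model",
    "sample_mvn",
    "standardise",
    "sample_covariance",
    "threshold_precision",
    "generate_genelike_correlation",
    "build_thresholded_model",
    "support_from_matrix",
    "correlation_from_covariance",
]


@dataclass(frozen=True)
class EdgeSet:
    """An undirected graph support: unordered node pairs {i, j}, i < j, 0-based."""

    p: int
    edges: frozenset

    def __post_init__(self):
        for (i, j) in self.edges:
            if not (0 <= i < j < self.p):
                raise ValueError(f"invalid edge ({i}, {j}) for p={self.p}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def symmetric_difference(self, other: "EdgeSet") -> int:
        if self.p != other.p:
            raise ValueError(f"node-count mismatch: {self.p} != {other.p}")
        return len(self.edges ^ other.edges)

    def to_array(self) -> np.ndarray:
        """Edges as a sorted (n_edges, 2) int array."""
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.edges), dtype=int)

    @classmethod
    def from_pairs(cls, p: int, pairs) -> "EdgeSet":
        norm = frozenset((min(i, j), max(i, j)) for i, j in pairs if i != j)
        return cls(p=p, edges=norm)


def support_from_matrix(M: np.ndarray, zero_tol: float = 0.0) -> EdgeSet:
    """Edge set of the off-diagonal entries of ``M`` with |entry| > zero_tol."""
    M = np.asarray(M)
    p = M.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    mag = np.maximum(np.abs(M[iu, ju]), np.abs(M[ju, iu]))
    keep = mag > zero_tol
    return EdgeSet.from_pairs(p, zip(iu[keep].tolist(), ju[keep].tolist()))


@dataclass(frozen=True)
class DataSample:
    """An (n, p) data matrix of i.i.d. multivariate-normal rows."""

    X: np.ndarray
    n: int
    standardized: bool = False

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class BipartiteModel:
    """Latent-linear model x ~ N(0, sigma_x2 I), y = A x + eps.

    The covariance of the stacked vector (x, y) is

        C = sigma_x2 * [[I,  A^T],
                        [A,  A A^T + sigma_eps2 I]]

    with the closed-form inverse

        Omega* = sigma_x2^-1 * [[I + sigma_eps2^-1 A^T A,  -sigma_eps2^-1 A^T],
                                [-sigma_eps2^-1 A,          sigma_eps2^-1 I ]].

    The lower-right block of Omega* is diagonal: the outputs y are
    conditionally independent given the inputs x.  Off-diagonal entries
    scale with 1/sigma_eps2, so the precision matrix blows up entrywise
    as the noise vanishes although its support never changes.
    """

    A: np.ndarray
    sigma_x2: float
    sigma_eps2: float
    C: np.ndarray
    Omega_star: np.ndarray
    support: EdgeSet
    seed: Optional[int] = None
    gamma: Optional[float] = None  # recorded by scale_weights_to_gamma

    @property
    def d1(self) -> int:
        return self.A.shape[1]

    @property
    def d2(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.d1 + self.d2

    def with_weights(self, A_new: np.ndarray, gamma: Optional[float] = None) -> "BipartiteModel":
        m = build_bipartite_model(A_new, self.sigma_x2, self.sigma_eps2, seed=self.seed)
        return dataclasses.replace(m, gamma=gamma)


@dataclass(frozen=True)
class ThresholdedGeneModel:
    """Sparse ground truth from hard-thresholding a dense inverse correlation.

    Lambda keeps entries of Lambda0 = C0^-1 with |entry| > delta and zeroes
    the rest; the testing covariance is C = Lambda^-1.
    """

    C0: np.ndarray
    delta: float
    Lambda: np.ndarray
    C: np.ndarray
    support: EdgeSet
    zero_fraction: float
    seed: Optional[int] = None
    n_retries: int = 0


def generate_weight_matrix(d1: int, d2: int, seed: int) -> np.ndarray:
    """Draw a (d2, d1) weight matrix of i.i.d. standard-normal entries."""
    if d1 < 1 or d2 < 1:
        raise ValueError(f"dimensions must be positive, got d1={d1}, d2={d2}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((d2, d1))


def build_bipartite_model(
    A: np.ndarray, sigma_x2: float = 1.0, sigma_eps2: float = 0.01, seed: Optional[int] = None
) -> BipartiteModel:
    """Assemble the exact covariance/precision pair of the latent-linear model.

    Both matrices are built from their closed forms; no numerical inversion
    is involved, so the support of ``Omega_star`` is known symbolically:
    x_i — y_j edges wherever A[j, i] != 0 and x_i — x_k edges wherever the
    structural pattern of A^T A is non-zero (a shared output).  y — y pairs
    never carry an edge.
    """
    if sigma_x2 <= 0 or sigma_eps2 <= 0:
        raise ValueError("sigma_x2 and sigma_eps2 must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    d2, d1 = A.shape
    p = d1 + d2

    C = np.empty((p, p))
    C[:d1, :d1] = np.eye(d1)
    C[:d1, d1:] = A.T
    C[d1:, :d1] = A
    C[d1:, d1:] = A @ A.T + sigma_eps2 * np.eye(d2)
    C *= sigma_x2

    ie2 = 1.0 / sigma_eps2
    Om = np.empty((p, p))
    Om[:d1, :d1] = np.eye(d1) + ie2 * (A.T @ A)
    Om[:d1, d1:] = -ie2 * A.T
    Om[d1:, :d1] = -ie2 * A
    Om[d1:, d1:] = ie2 * np.eye(d2)
    Om /= sigma_x2

    # structural (symbolic) support: pattern of A and of |A|^T |A|
    pattern = A != 0
    edges = []
    for i in range(d1):
        for j in range(d2):
            if pattern[j, i]:
                edges.append((i, d1 + j))
    shared = (np.abs(A).T @ np.abs(A)) > 0
    for i in range(d1):
        for k in range(i + 1, d1):
            if shared[i, k]:
                edges.append((i, k))
    support = EdgeSet.from_pairs(p, edges)
    return BipartiteModel(
        A=A, sigma_x2=float(sigma_x2), sigma_eps2=float(sigma_eps2),
        C=C, Omega_star=Om, support=support, seed=seed,
    )


def sample_mvn(C: np.ndarray, n: int, seed: int) -> DataSample:
    """Draw n i.i.d. rows from N(0, C) via a Cholesky factor of C."""
    C = np.asarray(C, dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "covariance matrix is not positive definite "
            f"(Cholesky failed: {e}); smallest eigenvalue "
            f"{np.linalg.eigvalsh(C).min():.3e}"
        ) from None
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, C.shape[0]))
    return DataSample(X=Z @ L.T, n=n, standardized=False)


def standardise(sample: DataSample) -> DataSample:
    """Centre columns and scale them to unit standard deviation (divisor n)."""
    X = sample.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) {bad.tolist()} cannot be standardised")
    return DataSample(X=(X - mu) / sd, n=sample.n, standardized=True)


def sample_covariance(sample: DataSample, ddof: int = 0) -> np.ndarray:
    """Sample covariance after centring; maximum-likelihood divisor n by default."""
    if sample.n < 2:
        raise ValueError("at least two observations are required")
    Xc = sample.X - sample.X.mean(axis=0)
    S = (Xc.T @ Xc) / (sample.n - ddof)
    return 0.5 * (S + S.T)


def threshold_precision(Lambda0: np.ndarray, delta: float) -> np.ndarray:
    """Zero every entry with |entry| <= delta; keep the rest unchanged."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    Lambda0 = np.asarray(Lambda0, dtype=float)
    if not np.allclose(Lambda0, Lambda0.T, atol=1e-10):
        raise ValueError("input precision matrix must be symmetric")
    out = np.where(np.abs(Lambda0) > delta, Lambda0, 0.0)
    return 0.5 * (out + out.T)


def generate_genelike_correlation(
    d: int,
    n_factors: Optional[int] = None,
    idio_var: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Dense, strongly collinear correlation matrix from a latent-factor draw.

    Emulates the empirical correlation matrices of co-regulated gene panels:
    W (d, n_factors) with standard-normal entries, M = W W^T + idio_var * I,
    rescaled to unit diagonal.  Few factors relative to d give the
    near-linear dependencies that make the inverse ill-behaved; the default
    idiosyncratic variance is calibrated so that thresholding the inverse at
    0.1 zeroes roughly half to 60 % of the off-diagonals while the
    irrepresentability norm still exceeds 1 for panels of 20+ genes.
    """
    if d < 2:
        raise ValueError("d must be at least 2")
    if n_factors is None:
        n_factors = max(2, round(d / 6))
    if n_factors < 1:
        raise ValueError("n_factors must be at least 1")
    if idio_var <= 0:
        raise ValueError("idio_var must be positive")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((d, n_factors))
    M = W @ W.T + idio_var * np.eye(d)
    s = np.sqrt(np.diag(M))
    C0 = M / np.outer(s, s)
    np.fill_diagonal(C0, 1.0)
    return 0.5 * (C0 + C0.T)


def build_thresholded_model(
    C0,
    delta: float = 0.1,
    max_retries: int = 10,
    seed: int = 0,
    zero_tol: float = 0.0,
) -> ThresholdedGeneModel:
    """Invert C0, threshold the precision at delta, verify positive definiteness.

    ``C0`` may be a fixed correlation matrix (single attempt) or a callable
    ``C0(seed) -> matrix`` which is re-drawn with derived seeds up to
    ``max_retries`` times if thresholding destroys positive definiteness.
    """
    generator: Optional[Callable[[int], np.ndarray]]
    if callable(C0):
        generator = C0
        attempts = max_retries + 1
    else:
        generator = None
        attempts = 1

    last_min_eig = np.nan
    for attempt in range(attempts):
        mat = generator(seed + attempt) if generator is not None else np.asarray(C0, dtype=float)
        eig0 = np.linalg.eigvalsh(mat)
        if eig0.min() <= 0:
            last_min_eig = eig0.min()
            continue
        Lambda0 = np.linalg.inv(mat)
        Lambda0 = 0.5 * (Lambda0 + Lambda0.T)
        Lambda = threshold_precision(Lambda0, delta)
        eigs = np.linalg.eigvalsh(Lambda)
        last_min_eig = eigs.min()
        if last_min_eig > 0:
            C = np.linalg.inv(Lambda)
            C = 0.5 * (C + C.T)
            d = Lambda.shape[0]
            off = d * (d - 1)
            n_zero = int((Lambda == 0).sum())  # zeros live off the diagonal only
            support = support_from_matrix(Lambda, zero_tol=zero_tol)
            return ThresholdedGeneModel(
                C0=mat, delta=float(delta), Lambda=Lambda, C=C,
                support=support, zero_fraction=n_zero / off if off else 0.0,
                seed=seed, n_retries=attempt,
            )
    raise ValueError(
        f"thresholded precision not positive definite after {attempts} attempt(s); "
        f"last smallest eigenvalue {last_min_eig:.3e} (delta={delta})"
    )


def correlation_from_covariance(C: np.ndarray) -> np.ndarray:
    """Rescale a covariance matrix to unit diagonal."""
    s = np.sqrt(np.diag(C))
    R = C / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)
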