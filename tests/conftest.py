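import numpy as np
import pytest

import l1precision as lp


def random_pd_matrix(p: int, seed: int, unit_diagonal: bool = True) -> np.ndarray:
    """Well-conditioned random PD matrix (correlation matrix by default)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((4 * p, p))
    S = X.T @ X / (4 * p)
    if unit_diagonal:
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        np.fill_diagonal(S, 1.0)
    return 0.5 * (S + S.T)


@pytest.fixture(scope="session")
def small_bipartite_model():
    """The study's default geometry: d1=2, d2=10, sigma_eps = 0.1."""
    A = lp.generate_weight_matrix(2, 10, seed=42)
    return lp.build_bipartite_model(A, sigma_x2=1.0, sigma_eps2=0.01, seed=42)


@pytest.fixture(scope="session")
def standardised_sample(small_bipartite_model):
    data = lp.sample_mvn(small_bipartite_model.C, n=1000, seed=7)
    return lp.standardise(data)
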