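import numpy as np
import pytest

from fccomm.synthetic import (
    make_planted_partition,
    planted_network,
    sample_fc_matrix,
)
from fccomm.types import BlockParams, FCMatrix, Partition


def random_fc(n: int, rng: np.random.Generator) -> FCMatrix:
    """Unstructured symmetric matrix with unit diagonal (noise network)."""
    w = rng.uniform(-0.5, 0.5, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return FCMatrix(w)


def random_partition(n: int, K: int, rng: np.random.Generator) -> Partition:
    """Random partition guaranteed to use all K labels."""
    labels = np.concatenate([np.arange(1, K + 1), rng.integers(1, K + 1, size=n - K)])
    return Partition(rng.permutation(labels), K)


@pytest.fixture(scope="session")
def default_network():
    """One planted 100-ROI, 5-community network at the default signal."""
    return planted_network(seed=3)


@pytest.fixture(scope="session")
def strong_network():
    """Well-separated network: within-mean 0.6, between 0.0, sd 0.05."""
    sizes = (30, 15, 25, 20, 10)
    part = make_planted_partition(sizes)
    K = len(sizes)
    mu = np.full((K, K), 0.0)
    np.fill_diagonal(mu, 0.6)
    params = BlockParams(mu=mu, sigma2=np.full((K, K), 0.05**2))
    A = sample_fc_matrix(part, params, seed=7)
    return A, part, params
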