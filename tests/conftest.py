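import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from clusterlab.datasets import Dataset, standardize
from clusterlab.synthetic import MixtureSpec, make_mixture


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def triples_1d():
    """Nine 1-D points in three obvious triples; optimal K=3 SSE is 6.0."""
    return np.array([0, 1, 2, 10, 11, 12, 20, 21, 22], dtype=float).reshape(-1, 1)


@pytest.fixture
def blobs3():
    """Three well-separated 2-D blobs with ground-truth labels."""
    return make_mixture(MixtureSpec(n=90, d=2, K=3, separation=12.0, seed=7))


@pytest.fixture
def iris_std():
    from sklearn.datasets import load_iris
    b = load_iris()
    return standardize(Dataset("iris", b.data.astype(float), b.target.astype(int)))


@pytest.fixture
def wine_std():
    from sklearn.datasets import load_wine
    b = load_wine()
    return standardize(Dataset("wine", b.data.astype(float), b.target.astype(int)))


def random_partition_pair(rng, n_max=60):
    n = int(rng.integers(4, n_max + 1))
    ku = int(rng.integers(1, 6))
    kv = int(rng.integers(1, 6))
    u = rng.integers(0, ku, size=n)
    v = rng.integers(0, kv, size=n)
    return u, v
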