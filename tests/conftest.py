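import numpy as np
import pytest

from circa.datatypes import Partition, SimilarityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_partition():
    # {a,b | c,d | e,f,g,h,i,j}: 10 items, 3 clusters
    return Partition(np.array([0, 0, 1, 1, 2, 2, 2, 2, 2, 2]), 3)


def random_soft_matrix(n, rng):
    """Symmetric random soft similarity matrix (fully observed)."""
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return SimilarityMatrix.dense(v)


@pytest.fixture
def soft6(rng):
    return random_soft_matrix(6, rng)
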