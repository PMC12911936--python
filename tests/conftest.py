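import numpy as np
import pytest

from gpmaps import SequenceSpace
from gpmaps.simulate import canonical_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fixtures():
    return canonical_fixtures()


@pytest.fixture
def dna2():
    return SequenceSpace("ACGT", 2)


@pytest.fixture
def binary3():
    return SequenceSpace("01", 3)


@pytest.fixture
def trinuc3():
    return SequenceSpace("ACG", 3)


def dense_laplacian(space):
    n = space.n_genotypes
    a = np.zeros((n, n))
    for i in range(n):
        a[i, space.hamming_neighbors(i)] = 1.0
    return np.diag(a.sum(1)) - a


def dense_subset_projection(space, sites):
    """P_U from its entrywise formula: alpha^-l * prod_{p in U}
    [(alpha-1) if matching else -1]."""
    n, alpha = space.n_genotypes, space.alpha
    seqs = space.all_sequences()
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            v = 1.0
            for p in sites:
                v *= (alpha - 1.0) if seqs[i][p] == seqs[j][p] else -1.0
            out[i, j] = v
    return out / n


def pairwise_distances(space, genotypes=None):
    idx = np.arange(space.n_genotypes) if genotypes is None else genotypes
    codes = (idx[:, None] // space.powers[None, :]) % space.alpha
    return (codes[:, None, :] != codes[None, :, :]).sum(-1)
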