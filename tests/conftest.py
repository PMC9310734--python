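import numpy as np
import pytest

from landpop.gl import GenotypeLikelihoodSet


def certain_gl(genotypes: np.ndarray) -> GenotypeLikelihoodSet:
    """GL set with probability-1 likelihoods at the given (n_sites, n_ind) dosages."""
    genotypes = np.asarray(genotypes)
    n_sites, n_ind = genotypes.shape
    gls = np.zeros((n_sites, n_ind, 3))
    for g in range(3):
        gls[..., g] = genotypes == g
    return GenotypeLikelihoodSet(
        [f"ind{i}" for i in range(n_ind)],
        [f"site{s}" for s in range(n_sites)],
        gls,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_certain_gl(rng):
    genotypes = rng.integers(0, 3, size=(50, 5))
    return certain_gl(genotypes), genotypes
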