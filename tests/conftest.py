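import numpy as np
import pytest

from lrmne.models import StimulusResponseSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_quadratic_data(rng):
    """D=8 dataset from a rank-1 quadratic (suppressive-free) neuron."""
    D, N = 8, 500
    S = rng.standard_normal((N, D))
    w = rng.standard_normal(D)
    w /= np.linalg.norm(w)
    z = 0.6 * (S @ w) ** 2 - 1.8
    y = (rng.uniform(size=N) < 1.0 / (1.0 + np.exp(-z))).astype(float)
    return StimulusResponseSet(S, y), w


def random_factors(rng, D, r, scale=0.4):
    from lrmne.models import LowRankFactors

    signs = rng.choice((-1.0, 1.0), size=r)
    U = scale * rng.standard_normal((D, r))
    V = scale * rng.standard_normal((D, r))
    return LowRankFactors(U, V, signs, rng.uniform(0, 1, size=r))
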