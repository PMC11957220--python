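import numpy as np
import pytest

from chaostopo import OscillatorSpec, PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_cloud(rng):
    return PointCloud(coords=rng.uniform(-2.0, 2.0, size=(10, 3)))


@pytest.fixture
def lorenz_spec():
    return OscillatorSpec()


def random_zero_row_sum(rng, n):
    """Random symmetric zero-row-sum coupling matrix."""
    M = rng.normal(size=(n, n))
    G = 0.5 * (M + M.T)
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))
    return G
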