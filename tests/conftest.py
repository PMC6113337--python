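import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(rng, n, scale=1.0):
    M = rng.normal(0, scale, (n, n))
    return (M + M.T) / 2.0


@pytest.fixture
def block_matrix():
    """Exact two-block all-ones similarity on 6 nodes (4 + 2)."""
    M = np.zeros((6, 6))
    M[:4, :4] = 1.0
    M[4:, 4:] = 1.0
    return M
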