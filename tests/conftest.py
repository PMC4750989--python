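import numpy as np
import pytest

from glvtypes import (MetacommunityConfig, generate_metacommunity,
                      sample_local_communities)

# the worked four-species assembly example: components and assembled matrix
TOY_N = np.array([
    [0.0, 0.2, 0.4, -0.1],
    [0.7, 0.0, 0.3, 0.4],
    [-0.1, 0.7, 0.0, 0.1],
    [-0.3, -0.2, 0.4, 0.0],
])
TOY_H = np.diag([1.0, 0.2, 0.2, 0.4])
TOY_G = np.array([
    [0, 1, 1, 1],
    [1, 0, 1, 0],
    [1, 0, 0, 0],
    [0, 0, 1, 0],
], dtype=float)
TOY_A = np.array([
    [-1.0, 0.04, 0.08, -0.04],
    [0.7, -1.0, 0.06, 0.0],
    [-0.1, 0.0, -1.0, 0.0],
    [0.0, 0.0, 0.08, -1.0],
])


@pytest.fixture(scope="session")
def toy_components():
    return TOY_N, TOY_H, TOY_G, TOY_A


@pytest.fixture(scope="session")
def small_meta():
    """A 20-species heterogeneous metacommunity used across unit tests."""
    return generate_metacommunity(MetacommunityConfig(n=20, alpha=2.0, seed=7))


@pytest.fixture(scope="session")
def small_lcs(small_meta):
    return sample_local_communities(small_meta, q=12, p=15, seed=7)
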