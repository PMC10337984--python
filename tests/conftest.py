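import numpy as np
import pytest

from memodyn import GamePayoffs


@pytest.fixture(scope="session")
def game():
    """The reference donation game: b = 1, c = 0.1."""
    return GamePayoffs.donation(1.0, 0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def interior_points(n, dims, seed=0, lo=0.05, hi=0.95):
    """Seeded strategy sample bounded away from the boundary."""
    return np.random.default_rng(seed).uniform(lo, hi, (n, dims))
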