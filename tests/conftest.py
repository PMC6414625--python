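import numpy as np
import pytest

from laminachrom import ContactMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def random_symmetric(n, rng, low=0.0, high=10.0):
    m = rng.uniform(low, high, size=(n, n))
    m = 0.5 * (m + m.T)
    return m


@pytest.fixture
def small_map(rng):
    """6-bin corrected map with generic positive entries."""
    return ContactMap(random_symmetric(6, rng, 1.0, 5.0), corrected=True)
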