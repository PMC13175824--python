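import numpy as np
import pytest

from ospreyfuse import ScoreTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tensor(rng, k=3, n=20, c=4):
    """Random valid score tensor: Dirichlet rows per (model, sample)."""
    vals = rng.dirichlet(np.ones(c), size=(k, n))
    return ScoreTensor(values=vals)


@pytest.fixture
def small_tensor(rng):
    return random_tensor(rng)
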