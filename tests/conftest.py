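import numpy as np
import pytest

from roarbout import gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact default-condition corpus shared across tests."""
    return gen_dataset(3, 4, seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
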