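import numpy as np
import pytest
from hypothesis import settings

import optbias as ob

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_linear_dataset():
    """n=300, d=4 linear data with moderate noise; shared across tests."""
    return ob.gen_linear(300, 4, [1.5, -2.0, 1.0, 0.5], 1.0, 0.5, seed=11)


@pytest.fixture
def univariate_dataset():
    return ob.gen_linear(1000, 1, [2.0], 1.0, 0.5, seed=7)
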