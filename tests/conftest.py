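import numpy as np
import pytest

from mhng.intergm import Hyperparameters
from mhng.stimuli import builtin_specs, generate_dataset


@pytest.fixture(scope="session")
def hyper():
    """Study-default hyperparameters (K = L = 5)."""
    return Hyperparameters()


@pytest.fixture(scope="session")
def easy_stimuli():
    return generate_dataset(builtin_specs()[1], n_items=15, seed=101)


@pytest.fixture(scope="session")
def hard_stimuli():
    return generate_dataset(builtin_specs()[0], n_items=15, seed=101)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
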