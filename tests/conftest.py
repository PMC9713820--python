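import numpy as np
import pytest

from pmms.model import ModelConfig, init_parameters
from pmms.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Reduced network used by unit tests (full-width tests live in acceptance)."""
    return ModelConfig(k=3, d_b=8, d_k=4, d_v=4, h=2, epochs=2, batch_size=8, seed=7)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_parameters(tiny_config)


@pytest.fixture(scope="session")
def small_dataset():
    """10+10 strongly separable synthetic hairpins."""
    return generate_dataset(SynthConfig.with_effect("strong", n_pos=10, n_neg=10, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
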