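import numpy as np
import pytest
from hypothesis import settings

from barofold.synthetic import ScenarioConfig

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def noiseless_config() -> ScenarioConfig:
    return ScenarioConfig(noise=0.0)


@pytest.fixture
def default_config() -> ScenarioConfig:
    return ScenarioConfig(seed=7)


@pytest.fixture
def eq_pressures() -> np.ndarray:
    """The standard pressure ladder: 0.1 MPa then 30 MPa steps up to 600."""
    return np.concatenate([[0.1], np.arange(30.0, 601.0, 30.0)])
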