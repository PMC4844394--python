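import numpy as np
import pytest

from elicitca import ModelParameters, StimulusProtocol, SyntheticConfig


@pytest.fixture
def params() -> ModelParameters:
    """Default plant-adapted parameter set."""
    return ModelParameters()


@pytest.fixture
def unit_pulse() -> StimulusProtocol:
    """Unit-amplitude seven-minute stimulus after 60 s of baseline."""
    return StimulusProtocol.single(1.0, 60.0, 420.0)


@pytest.fixture
def config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
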