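import numpy as np
import pytest

from boundedmi import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def complete_dataset_500(default_config):
    """One complete default-size dataset, shared read-only across tests."""
    return generate_dataset(default_config, np.random.default_rng(42))
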