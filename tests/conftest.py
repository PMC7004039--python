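import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from firesucc import PlantTypeSet, SeedBankRules

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> PlantTypeSet:
    """Standard calibrated parameter set."""
    return PlantTypeSet()


@pytest.fixture(scope="session")
def rules() -> SeedBankRules:
    return SeedBankRules()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
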