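import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pedcds import knowledge, reference_data

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def rulebase():
    return knowledge.packaged_rulebase()


@pytest.fixture(scope="session")
def library():
    return reference_data.default_reference_library(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210914)
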