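import numpy as np
import pytest

from vectortrace.scenario import build_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default study scenario: chr13 locus, one clonal chr3 integration."""
    return build_scenario(1)


@pytest.fixture(scope="session")
def scenario_two_random():
    """Three chromosomes, targeted + two random integrations."""
    return build_scenario(1, n_random_integrations=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
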