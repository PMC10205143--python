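import pytest
from hypothesis import HealthCheck, settings

import ippid as ip

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def avg_tf():
    return ip.average_tf()


@pytest.fixture(scope="session")
def avg_patient():
    """Single patient collapsed onto the population-average dynamics."""
    return ip.make_population(1, seed=0,
                              config=ip.PopulationConfig(dispersion=0.0))[0]


@pytest.fixture(scope="session")
def cohort():
    return ip.make_population(100, seed=42)
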