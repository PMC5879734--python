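import pytest
from hypothesis import HealthCheck, settings

from livermotion import SimulationParams, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """A 20-patient synthetic cohort at the default study conditions."""
    return generate_cohort(default_params, 20, seed=1234)
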