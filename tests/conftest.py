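import pytest
from hypothesis import HealthCheck, settings

from achastroke import CohortConfig, build_atlas, generate_cohort

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def atlas():
    return build_atlas()


@pytest.fixture(scope="session")
def config():
    return CohortConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free study conditions: deterministic CBV fields."""
    return CohortConfig(noise_sd=0.0, baseline_cbv_sd=0.0)


@pytest.fixture(scope="session")
def cohort(config):
    return generate_cohort(config, seed=1)
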