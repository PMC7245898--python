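import pytest
from hypothesis import HealthCheck, settings

import levocea as lv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_records():
    """The reconstructed 54-patient study cohort."""
    return list(lv.study_cohort().records)


@pytest.fixture(scope="session")
def config():
    """The packaged calibrated base-case configuration."""
    return lv.default_config()


@pytest.fixture(scope="session")
def base_case_result(config):
    return lv.base_case(config)


@pytest.fixture(scope="session")
def psa_draws(config):
    """One shared 10,000-draw PSA run at a fixed seed."""
    return lv.run_psa(config, lv.PSAConfig(n_draws=10_000, seed=2026))
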