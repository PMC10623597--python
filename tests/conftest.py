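import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_world():
    """Five heterogeneous countries, equal populations."""
    from twinworld import calibrated_world

    return calibrated_world(n_countries=5, between_share=0.19)


@pytest.fixture
def flat_world():
    """Five identical countries: no between-country variance."""
    from twinworld import homogeneous_world

    return homogeneous_world(5, 5.0, 2.0)
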