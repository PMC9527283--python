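import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from ngra import SyntheticScenario, generate_scenario  # noqa: E402


@pytest.fixture(scope="session")
def small_scenario():
    """A compact scenario shared by read-only tests: 50 subjects, 14 substances."""
    return generate_scenario(SyntheticScenario(n_subjects=50, seed=11))


@pytest.fixture(scope="session")
def default_scenario():
    """The default study conditions: 200 subjects x 2 days, 30% non-detects."""
    return generate_scenario(SyntheticScenario(seed=7))
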