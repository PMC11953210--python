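import pytest

from osteofrailia import default_registry, hk_fixture_cohorts


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def us_male_pop(registry):
    return registry.population("us_older_m")


@pytest.fixture(scope="session")
def us_female_pop(registry):
    return registry.population("us_older_f")


@pytest.fixture(scope="session")
def hk_cohorts():
    """Marginal-constrained Hong Kong cohort fixtures (built once)."""
    return hk_fixture_cohorts()
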