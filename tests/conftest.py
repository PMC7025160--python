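import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sets():
    from griefcriteria import default_criteria

    return default_criteria()


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated default cohort (n=1732), shared across tests."""
    from griefcriteria import default_config, generate_cohort

    return generate_cohort(default_config())
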