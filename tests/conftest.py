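import pytest

from dlwtee import cohort as ch


@pytest.fixture(scope="session")
def default_config():
    """Default study emulation config with a fixed seed."""
    return ch.CohortConfig.study_defaults(seed=11)


@pytest.fixture(scope="session")
def default_study(default_config):
    """One generated study (cohort, doses, enrichments) shared across tests."""
    return ch.generate_study(default_config)
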