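import pytest

from titedose import TrialConfig, scenario_table


@pytest.fixture(scope="session")
def config() -> TrialConfig:
    """The default study configuration: six oral dose levels, target 1/3,
    six-month window, offset 0.05, 24 patients, 2 arrivals/month."""
    return TrialConfig()


@pytest.fixture(scope="session")
def scenarios():
    return scenario_table()
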