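import pytest
from hypothesis import HealthCheck, settings

import heatcount as hc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    """The packaged 4-company x 11-year disclosure panel."""
    return hc.load_bundled_panel()


@pytest.fixture(scope="session")
def config():
    """The packaged default assumptions."""
    return hc.default_assumptions()


@pytest.fixture(scope="session")
def prepared_panel(panel, config):
    """Panel after imputation and double-counting reconciliation."""
    return hc.prepare_panel(panel, config)


@pytest.fixture(scope="session")
def survey_records():
    """The packaged 35-country survey table."""
    return hc.load_bundled_survey()
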