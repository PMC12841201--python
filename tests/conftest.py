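import pytest
from hypothesis import HealthCheck, settings

import cholscreen as cs

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """The bundled transcriptions of the published strain-panel tables."""
    return cs.load_study_tables()


@pytest.fixture(scope="session")
def proteome_panel():
    """Strains with liver proteome data (the fourth lacks it entirely)."""
    return ["B6", "BXD51", "BXD73"]
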