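import pytest
from hypothesis import HealthCheck, settings

from taadvc.examples import example_cohort, example_depths, example_plp_variants
from taadvc.model import PanelConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def panel_config() -> PanelConfig:
    return PanelConfig()


@pytest.fixture
def plp_variants():
    """The six-variant worked example (one P/LP variant per patient)."""
    return example_plp_variants()


@pytest.fixture
def plp_depths():
    return example_depths()


@pytest.fixture
def cohort_101():
    """Deterministic 101-patient phenotype fixture around the six carriers."""
    return example_cohort()
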