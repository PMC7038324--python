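import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import palmripe as pr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort() -> pr.Cohort:
    """One default 52-fruit cohort (21 ripe / 15 under-ripe / 16 unripe)."""
    return pr.generate_cohort(pr.CohortSpec(seed=0))


@pytest.fixture(scope="session")
def chart_layout() -> pr.ChartLayout:
    return pr.default_chart_layout()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
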