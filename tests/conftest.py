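import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from iptwkit import (default_config, expand_two_by_two, generate_cohort,
                     study_two_by_two)


@pytest.fixture(scope="session")
def study_table():
    return study_two_by_two()


@pytest.fixture(scope="session")
def expanded_study(study_table):
    return expand_two_by_two(study_table)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-like synthetic cohort: n=1003, ~2.3% exposed, seed 42."""
    return generate_cohort(default_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)
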