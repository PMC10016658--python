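import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caninet import GeneratorConfig, canine_atlas, generate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas():
    return canine_atlas()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (25 controls / 13 patients, seed 1)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def null_config():
    """Generator settings with no implanted group difference."""
    return GeneratorConfig(seed=11, effect_edges=(), behavior_links=())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
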