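import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsmga import (
    FactorSpace,
    fit_quadratic,
    load_study_fixture,
    published_surface,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """The shipped 33-run fermentation fixture: (space, design table)."""
    return load_study_fixture()


@pytest.fixture(scope="session")
def space(study):
    return study[0]


@pytest.fixture(scope="session")
def design(study):
    return study[1]


@pytest.fixture(scope="session")
def study_fit(design):
    return fit_quadratic(design)


@pytest.fixture(scope="session")
def surface():
    """The published second-order lipase model in coded units."""
    return published_surface()


@pytest.fixture
def space2():
    return FactorSpace.from_bounds([("a", 0.0, 1.0), ("b", -2.0, 2.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
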