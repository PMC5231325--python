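import numpy as np
import pytest

from overmix.growth_mcmc import GrowthModelSpec
from overmix.scenarios import make_scenario, simulate_growth, simulate_univariate


@pytest.fixture(scope="session")
def a2_data():
    """One well-separated three-class univariate sample (n=500)."""
    return simulate_univariate(make_scenario("A2"), seed=42)


@pytest.fixture(scope="session")
def a1_data():
    """One homogeneous univariate sample (n=500)."""
    return simulate_univariate(make_scenario("A1"), seed=42)


@pytest.fixture(scope="session")
def b2_data():
    """One three-class random-intercept longitudinal sample."""
    return simulate_growth(make_scenario("B2"), seed=42)


@pytest.fixture(scope="session")
def b2_model():
    return GrowthModelSpec(
        class_specific_terms=("intercept",),
        common_terms=("time",),
        random_terms=("intercept",),
    )


@pytest.fixture(scope="session")
def b3_model():
    return GrowthModelSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(2027)
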