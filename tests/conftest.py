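import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_model():
    from wristsim import build_default_model

    return build_default_model()


@pytest.fixture(scope="session")
def fixture_problem():
    from wristsim import make_fixture

    _model, problem = make_fixture()
    return problem


@pytest.fixture(scope="session")
def fe_simulation(default_model):
    """A coarse FE motion simulation under the 100 N metacarpal load."""
    from wristsim import make_motion_cycle, simulate_motion

    cycle = make_motion_cycle("FE", 21)
    return simulate_motion(default_model, cycle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
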