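import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# reproducible property tests: one fixed derandomised profile
settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from sproutsim import make_parameters
from sproutsim.solver import SolverControls


@pytest.fixture(scope="session")
def params():
    """Default (isolated-sprout) parameter set."""
    return make_parameters()


@pytest.fixture(scope="session")
def tissue_params():
    """Tissue-case (bounded domain) parameter set."""
    return make_parameters(case="tissue")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def quick_controls():
    """Controls suitable for small unit-test problems."""
    return SolverControls(dt_init=0.1, dt_max=600.0, max_iters=20000)
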