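import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from renalkin.kinetic_model import RateConstants
from renalkin.synthetic_data import (
    CohortSpec,
    InputFunctionSpec,
    default_schedule,
    make_input_function,
    simulate_cohort,
    simulate_kidney,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: Control-group mean rate constants (convolution fit).
CONTROL_RC = RateConstants(0.985, 0.246, 0.212, 0.013)


@pytest.fixture(scope="session")
def control_rc():
    return CONTROL_RC


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def input_fn():
    grid = np.arange(0.0, 90.0 + 0.005, 0.01)
    return make_input_function(InputFunctionSpec(), grid)


@pytest.fixture(scope="session")
def noiseless_tac(control_rc, input_fn, schedule):
    return simulate_kidney(control_rc, 0.15, input_fn, schedule, noise_level=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """12 kidneys spanning the study's group means with zero noise."""
    return simulate_cohort(CohortSpec(seed=11, noise_level=0.0))


@pytest.fixture(scope="session")
def noisy_cohort():
    """12 kidneys at the generator's default noise level."""
    return simulate_cohort(CohortSpec(seed=5))
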