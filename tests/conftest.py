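import numpy as np
import pytest

from simdcis import AgeSchedule, ScenarioConfig, ScreeningPolicy
from simdcis.synthetic_params import SyntheticSpec, constant_hazard_parameters, generate_parameter_set


@pytest.fixture(scope="session")
def stylized_params():
    """Default stylized parameter set used across tests."""
    return generate_parameter_set(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def base_policy():
    return ScreeningPolicy(start_age=50, stop_age=74, interval=2, compliance=0.76)


@pytest.fixture
def small_scenario(base_policy):
    """Fast scenario for unit tests (not the reporting scale)."""
    return ScenarioConfig(
        policy=base_policy, cohort_size=10_000, n_cohorts=3, master_seed=11
    )


@pytest.fixture(scope="session")
def onset50_fixture():
    """Canonical oracle fixture: certain grade-3 onset at 50, no death."""
    return constant_hazard_parameters(
        onset_age=50, onset_prob=1.0, grade=3,
        progression=0.1, clinical=0.05, regression=0.05, death=0.0,
    )


@pytest.fixture(scope="session")
def single_screen_50():
    return ScreeningPolicy(start_age=50, stop_age=50, compliance=1.0, single_round=True)


def stepped_death(params, start_age, value):
    """Replace death with 0 below start_age and `value` at/after it."""
    death = np.zeros(params.max_age + 1)
    death[start_age:] = value
    return params.with_(death=AgeSchedule(0, death))
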