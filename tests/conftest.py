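import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capscreen import (
    CalibrationTargets,
    CEAConfig,
    LifeTable,
    NaturalHistoryModel,
    generate_default_params,
    load_default_costs_utilities,
    load_default_profiles,
    simulate_cohort,
)

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def life_table():
    return LifeTable.gompertz_makeham()


@pytest.fixture(scope="session")
def default_params():
    return generate_default_params(1)


@pytest.fixture(scope="session")
def calibration(life_table):
    return NaturalHistoryModel(
        targets=CalibrationTargets(), life_table=life_table
    ).fit(sim_size=60_000, seed=3)


@pytest.fixture(scope="session")
def calibrated_params(calibration):
    return calibration.params


@pytest.fixture(scope="session")
def cohort(calibrated_params, life_table):
    """Mid-sized cohort shared by the engine and economics tests."""
    return simulate_cohort(calibrated_params, life_table, 60_000, seed=5)


@pytest.fixture(scope="session")
def profiles():
    return load_default_profiles()


@pytest.fixture(scope="session")
def costs_utilities():
    return load_default_costs_utilities()


@pytest.fixture(scope="session")
def cea_config():
    return CEAConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
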