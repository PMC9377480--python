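import pytest

from hautil import (
    AssessmentMethod,
    TitrationConfig,
    default_calibration,
    load_bundled_life_table,
    results_wide,
    simulate_study,
)


@pytest.fixture(scope="session")
def life_table():
    return load_bundled_life_table()


@pytest.fixture(scope="session")
def config():
    return TitrationConfig()


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def sim_long():
    """One full noise-free simulated study (all methods), seed 7."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def sim_wide(sim_long):
    return results_wide(sim_long)


@pytest.fixture(scope="session")
def sim_sg_long():
    """SG-only simulated study used by elicitation-fidelity checks."""
    return simulate_study(seed=11, methods=[AssessmentMethod.SG])
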