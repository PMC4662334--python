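import numpy as np
import pytest

import ctsecr as ct


@pytest.fixture(scope="session")
def study_traps():
    """The 5 x 4 study array at 100 m spacing."""
    return ct.build_grid_array(5, 4, 100.0)


@pytest.fixture(scope="session")
def study_design(study_traps):
    return ct.SurveyDesign(study_traps, duration_T=5.0, num_occasions_L=5)


@pytest.fixture(scope="session")
def study_params():
    return ct.DetectionParams(g0=0.2, sigma=100.0)


@pytest.fixture(scope="session")
def integration_mask(study_traps):
    """4-sigma buffered integration mask at sigma/4 spacing."""
    return ct.build_mask(study_traps, 400.0, 25.0, "full_integration")


@pytest.fixture(scope="session")
def full_report_mask(study_traps):
    return ct.build_mask(study_traps, 200.0, 25.0, "full_report")


@pytest.fixture(scope="session")
def reduced_report_mask(study_traps):
    return ct.build_mask(study_traps, 0.0, 25.0, "reduced_report")


@pytest.fixture(scope="session")
def exp1_survey(study_design, study_params):
    """One simulated scenario-1 survey (population + timed captures)."""
    geom_model = ct.get_scenario("exp1").density_model()
    mask = ct.build_mask(study_design.traps, 400.0, 25.0, "full_integration")
    rng = np.random.default_rng(1234)
    pop = ct.simulate_population(geom_model, mask, rng)
    data = ct.simulate_survey(pop, study_design, study_params, rng)
    return pop, data


@pytest.fixture(scope="session")
def lone_trap_design():
    traps = ct.build_grid_array(1, 1, 100.0)
    return ct.SurveyDesign(traps, duration_T=5.0, num_occasions_L=5)
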