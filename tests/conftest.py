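import pytest
from hypothesis import settings

import leafcal as lc

settings.register_profile("leafcal", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("leafcal")

SWEEP_POSITIONS = tuple(float(p) for p in range(-10, 20, 2))


@pytest.fixture(scope="session")
def elekta():
    return lc.load_preset("elekta80")


@pytest.fixture(scope="session")
def model(elekta):
    return elekta[0]


@pytest.fixture(scope="session")
def setup(elekta):
    return elekta[1]


@pytest.fixture(scope="session")
def zero_table():
    return lc.RLOTable.zero(SWEEP_POSITIONS)


@pytest.fixture(scope="session")
def zero_fit(model, setup, zero_table):
    """Calibration fitted from a zero-table sweep (the consistency-check arm)."""
    return lc.RLOCalibration(model, setup, zero_table).fit()


@pytest.fixture(scope="session")
def derived_table(zero_fit):
    return zero_fit.table


@pytest.fixture(scope="session")
def beam1_profile(model, setup, zero_table):
    """Normalized profile of the first sweep beam (Y2=18, Y1=-10) through
    leaf pair 19."""
    beam = lc.BeamDefinition.uniform(model.layout, y2=18.0, y1=-10.0)
    dose = lc.compute_planar_dose(model, beam, zero_table, setup)
    profile = lc.extract_line_profile(dose, model.layout.leaf_center(19))
    return lc.normalize_profile(profile, 14.0)
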