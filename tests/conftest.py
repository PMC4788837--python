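import numpy as np
import pytest
from hypothesis import settings

from qaleplan import fixtures_io as fx
from qaleplan.config import Calibration, TreatmentDecision

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib() -> Calibration:
    return Calibration()


@pytest.fixture(scope="session")
def life_table():
    return fx.make_life_table()


@pytest.fixture(scope="session")
def patients():
    high, intermediate = fx.reference_patients()
    return {"high": high, "intermediate": intermediate}


@pytest.fixture(scope="session")
def plan_library(calib):
    return fx.make_dvh_library(10, seed=7, calib=calib)


@pytest.fixture(scope="session")
def mid_plan(plan_library):
    return plan_library[5]


@pytest.fixture(scope="session")
def default_decision():
    return TreatmentDecision()


@pytest.fixture(scope="session")
def small_phantom():
    cfg = fx.PhantomConfig(nx=14, ny=14, spacing_mm=7.0,
                           ptv_radius_mm=14.0, rectum_offset_mm=28.0,
                           bladder_offset_mm=30.0, oar_semi_axes_mm=(18.0, 10.0),
                           n_beams=3, beamlets_per_beam=5, beamlet_spacing_mm=9.0)
    return fx.make_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
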