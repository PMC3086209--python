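import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tmrquant import (DensityProfile, FilmModel, LesionTruth, PhantomSpec,
                      SpatialCalibration, generate_tooth_pair)
from tmrquant.profiles import UNITS_PERCENT


@pytest.fixture
def noiseless_film() -> FilmModel:
    # integer-valued responses for attenuations that are multiples of 0.05,
    # so rounding to the pixel grid is exact
    return FilmModel(intercept=400.0, slope=2000.0, noise_sd=0.0)


@pytest.fixture
def erosion_spec() -> PhantomSpec:
    return PhantomSpec(lesion=LesionTruth(erosion_um=11.3))


def make_ramp_profile(surface_um: float, width_um: float, pitch_um: float,
                      n: int, shift_um: float = 0.0) -> DensityProfile:
    """Normalized ramp: 0 % outside, rising linearly to 100 % over width_um."""
    x = np.arange(n) * pitch_um
    v = np.clip((x - surface_um - shift_um) / width_um, 0.0, 1.0) * 100.0
    return DensityProfile(values=v, origin_index=0,
                          calibration=SpatialCalibration(pitch_um),
                          units=UNITS_PERCENT)


@pytest.fixture
def ramp_factory():
    return make_ramp_profile
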