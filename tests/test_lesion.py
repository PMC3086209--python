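import json

import numpy as np
import pytest

from tmrquant import (AlignedPair, DensityProfile, FilmModel,
                      InsufficientDataError, LesionTruth, NoCrossingError,
                      PhantomSpec, RegistrationFaultError, SpatialCalibration,
                      classify, fit_surface_gradient, generate_tooth_pair,
                      measure_demineralization, measure_erosion,
                      measure_phantom_pair, threshold_crossing,
                      validate_report)
from tmrquant.lesion import (CLASS_DEMIN, CLASS_EROSION, CLASS_MIXED,
                             CLASS_NONE)
from tmrquant.profiles import UNITS_PERCENT

from conftest import make_ramp_profile


def _percent_profile(values, pitch=1.0, origin=0):
    return DensityProfile(values=np.asarray(values, dtype=float),
                          origin_index=origin,
                          calibration=SpatialCalibration(pitch),
                          units=UNITS_PERCENT)


class TestFitSurfaceGradient:
    def test_exact_ramp_slope(self):
        # 0 -> 100 % over 20 um: slope 5 %/um, zero residual
        prof = make_ramp_profile(10.0, 20.0, 1.0, 60)
        fit = fit_surface_gradient(prof)
        assert fit.slope == pytest.approx(5.0, abs=1e-9)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)
        assert fit.n_points >= 3

    def test_band_choice_does_not_change_exact_line(self):
        prof = make_ramp_profile(10.0, 20.0, 1.0, 60)
        a = fit_surface_gradient(prof, 25.0, 75.0)
        b = fit_surface_gradient(prof, 15.0, 85.0)
        assert a.slope == pytest.approx(b.slope, abs=1e-9)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-9)

    def test_too_steep_edge_is_insufficient(self):
        prof = make_ramp_profile(10.0, 1.0, 1.0, 40)  # 1 sample on the edge
        with pytest.raises(InsufficientDataError):
            fit_surface_gradient(prof)

    def test_phantom_edge_slope_matches_truth(self):
        # linear-regime phantom (background attenuation inside the linear
        # band) so the normalized scale is exactly proportional to density
        w = 8.0
        spec = PhantomSpec(image_shape=(16, 1600),
                           film=FilmModel(noise_sd=0.0),
                           background_attenuation=0.15,
                           lesion=LesionTruth(edge_width_um=w))
        b, a, _ = generate_tooth_pair(spec, 0)
        out = measure_phantom_pair(b, a, spec)
        assert out.fit.slope == pytest.approx(100.0 / w, rel=0.02)


class TestThresholdCrossing:
    def test_linear_interpolation(self):
        prof = _percent_profile([0.0, 100.0])
        assert threshold_crossing(prof, 20.0) == pytest.approx(0.2)

    def test_level_zero_at_first_sample(self):
        prof = _percent_profile([0.0, 50.0, 100.0])
        assert threshold_crossing(prof, 0.0) == 0.0

    def test_matches_analytic_ramp(self):
        s, w = 12.0, 17.0
        prof = make_ramp_profile(s, w, 0.305, 400)
        for level in (5.0, 20.0, 50.0, 95.0):
            assert threshold_crossing(prof, level) == pytest.approx(
                s + level / 100.0 * w, abs=1e-9)

    def test_never_crossed(self):
        prof = _percent_profile([0.0, 10.0, 15.0])
        with pytest.raises(NoCrossingError):
            threshold_crossing(prof, 50.0)


def _ramp_pair(shift_um, s=30.0, w=10.0, pitch=0.305, n=500):
    before = make_ramp_profile(s, w, pitch, n)
    after = make_ramp_profile(s, w, pitch, n, shift_um=shift_um)
    return AlignedPair(before=before, after=after, applied_offset_px=0)


class TestMeasureErosion:
    def test_pure_translation_recovered(self):
        pair = _ramp_pair(7.3)
        fit = fit_surface_gradient(pair.before)
        res = measure_erosion(pair, fit)
        assert res.erosion_um == pytest.approx(7.3, abs=0.305)
        assert not res.zero_called

    def test_identity_is_zero(self):
        pair = _ramp_pair(0.0)
        fit = fit_surface_gradient(pair.before)
        res = measure_erosion(pair, fit)
        assert res.erosion_um == 0.0
        assert res.zero_called

    def test_surface_gain_is_a_fault(self):
        pair = _ramp_pair(-5.0)
        fit = fit_surface_gradient(pair.before)
        with pytest.raises(RegistrationFaultError):
            measure_erosion(pair, fit)

    def test_translation_equivariance(self):
        # shifting both profiles by the same integer offset changes nothing
        pair = _ramp_pair(7.3)
        shifted = AlignedPair(
            before=DensityProfile(pair.before.values, origin_index=100,
                                  calibration=pair.before.calibration,
                                  units=UNITS_PERCENT),
            after=DensityProfile(pair.after.values, origin_index=100,
                                 calibration=pair.after.calibration,
                                 units=UNITS_PERCENT),
            applied_offset_px=0)
        r1 = measure_erosion(pair, fit_surface_gradient(pair.before))
        r2 = measure_erosion(shifted, fit_surface_gradient(shifted.before))
        assert r2.erosion_um == pytest.approx(r1.erosion_um, abs=1e-9)

    def test_monotone_in_true_erosion(self):
        raws = []
        for e in (2.0, 5.0, 10.0, 20.0, 40.0):
            spec = PhantomSpec(image_shape=(8, 1600),
                               film=FilmModel(noise_sd=0.0),
                               lesion=LesionTruth(erosion_um=e))
            b, a, _ = generate_tooth_pair(spec, 0)
            raws.append(measure_phantom_pair(b, a, spec).erosion.raw_um)
        assert np.all(np.diff(raws) > 0)


class TestMeasureDemineralization:
    def test_pure_erosion_gives_zero_depth(self):
        spec = PhantomSpec(image_shape=(96, 1600),
                           lesion=LesionTruth(erosion_um=20.0))
        b, a, _ = generate_tooth_pair(spec, 5)
        out = measure_phantom_pair(b, a, spec)
        assert out.measurement.demin_depth_um < 2 * 0.305

    def test_identical_images_give_zero_zero(self):
        spec = PhantomSpec(image_shape=(96, 1600),
                           film=FilmModel(noise_sd=0.0))
        b, a, _ = generate_tooth_pair(spec, 0)
        out = measure_phantom_pair(b, a, spec)
        assert out.measurement.erosion_um == 0.0
        assert out.measurement.demin_depth_um == 0.0
        assert out.measurement.classification == CLASS_NONE

    def test_subsurface_lesion_depth_recovered(self):
        # 10 um lesion at half severity, medium magnification
        spec = PhantomSpec(image_shape=(96, 512), pixel_pitch_um=1.11,
                           lesion=LesionTruth(demin_depth_um=10.0,
                                              demin_severity=0.5))
        b, a, _ = generate_tooth_pair(spec, 8)
        out = measure_phantom_pair(b, a, spec)
        assert out.measurement.demin_depth_um == pytest.approx(10.0, abs=2 * 1.11)
        assert out.measurement.erosion_um == 0.0
        assert out.measurement.classification == CLASS_DEMIN

    def test_report_depth_at_percentage(self):
        from tmrquant import MeasurementSettings
        spec = PhantomSpec(image_shape=(96, 512), pixel_pitch_um=1.11,
                           lesion=LesionTruth(demin_depth_um=15.0,
                                              demin_severity=0.6))
        b, a, _ = generate_tooth_pair(spec, 8)
        out = measure_phantom_pair(b, a, spec,
                                   settings=MeasurementSettings(
                                       report_depth_pct=50.0))
        # innermost depth where after density is still below 50 %
        assert out.demin.report_depth_um is not None
        assert out.demin.report_depth_um > spec.lesion.surface_position_um


class TestClassify:
    @pytest.mark.parametrize("erosion,demin,expected", [
        (11.3, 0.0, CLASS_EROSION),   # erosive challenge outcome
        (0.0, 10.0, CLASS_DEMIN),     # cariogenic cycling outcome
        (0.0, 0.0, CLASS_NONE),
        (5.0, 5.0, CLASS_MIXED),
        (0.4, 0.4, CLASS_NONE),       # below the 1 um distance tolerance
    ])
    def test_table(self, erosion, demin, expected):
        assert classify(erosion, demin, eps_distance_um=1.0) == expected


class TestMeasurementReport:
    @pytest.fixture(scope="class")
    @staticmethod
    def outcome():
        spec = PhantomSpec(image_shape=(32, 1600),
                           lesion=LesionTruth(erosion_um=11.3))
        b, a, _ = generate_tooth_pair(spec, 5)
        return measure_phantom_pair(b, a, spec)

    def test_json_round_trip_validates(self, outcome):
        blob = json.dumps(outcome.report)
        back = json.loads(blob)
        validate_report(back)
        assert back["classification"] == CLASS_EROSION

    def test_pixel_and_um_distances_consistent(self, outcome):
        ero = outcome.report["erosion"]
        pitch = outcome.report["calibration"]["um_per_pixel"]
        assert ero["px"] * pitch == pytest.approx(ero["um"], abs=1e-9)

    def test_thresholds_echoed(self, outcome):
        thr = outcome.report["thresholds"]
        assert thr["erosion_threshold_pct"] == 20.0
        assert thr["demin_ceiling_pct"] == 80.0
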