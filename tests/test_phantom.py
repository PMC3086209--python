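import numpy as np
import pytest
from hypothesis import given, strategies as st

from tmrquant import (FilmModel, LesionTruth, PhantomSpec, ROI,
                      ValidationError, analysis_layout, film_response,
                      generate_step_wedge_image, generate_tooth_pair,
                      mineral_density_after, mineral_density_before)


class TestDensityModels:
    truth = LesionTruth(surface_position_um=100.0, edge_width_um=4.0)

    def test_before_ramp_landmarks(self):
        t = self.truth
        assert mineral_density_before(100.0, t) == 0.0
        assert mineral_density_before(104.0, t) == 1.0
        assert mineral_density_before(102.0, t) == pytest.approx(0.5)

    def test_pure_erosion_is_translation(self):
        t = LesionTruth(surface_position_um=100.0, edge_width_um=4.0,
                        erosion_um=10.0)
        x = np.linspace(80, 140, 241)
        np.testing.assert_allclose(mineral_density_after(x, t),
                                   mineral_density_before(x - 10.0, t))

    def test_no_lesion_is_identity(self):
        t = LesionTruth(surface_position_um=100.0, edge_width_um=4.0)
        x = np.linspace(80, 140, 241)
        np.testing.assert_allclose(mineral_density_after(x, t),
                                   mineral_density_before(x, t))

    def test_demin_value_at_edge_top(self):
        # e=0, delta=0.5, w=2, L=10, x=s+w: 1 * (1 - 0.5*(1 - 2/10)) = 0.6
        t = LesionTruth(surface_position_um=100.0, edge_width_um=2.0,
                        demin_depth_um=10.0, demin_severity=0.5)
        assert mineral_density_after(102.0, t) == pytest.approx(0.6)

    def test_demin_recovers_to_sound_at_L(self):
        t = LesionTruth(surface_position_um=100.0, edge_width_um=2.0,
                        demin_depth_um=10.0, demin_severity=0.5)
        assert mineral_density_after(110.0, t) == pytest.approx(1.0)

    def test_severity_cap(self):
        with pytest.raises(ValidationError):
            LesionTruth(demin_severity=0.9)


class TestFilmResponse:
    film = FilmModel(intercept=400.0, slope=2000.0, noise_sd=0.0)

    def test_linear_region_exact(self):
        a = np.linspace(0.10, 0.90, 33)
        np.testing.assert_allclose(film_response(a, self.film), 400.0 + 2000.0 * a,
                                   rtol=0, atol=1e-12)

    def test_far_beyond_scale_bounded(self):
        g_hi = film_response(0.90, self.film)
        g_metal = film_response(10.0, self.film)
        assert np.isfinite(g_metal)
        assert g_hi <= g_metal <= g_hi + 2000.0 * self.film.clip_softness + 1e-9

    def test_monotone_over_grid(self):
        a = np.linspace(-0.5, 11.0, 1000)
        g = film_response(a, self.film)
        assert np.all(np.diff(g) >= 0)

    @given(st.floats(-1, 12), st.floats(-1, 12))
    def test_monotone_pairs(self, a1, a2):
        lo, hi = sorted((a1, a2))
        assert film_response(lo, self.film) <= film_response(hi, self.film) + 1e-9

    def test_hard_clip_limit(self):
        film = FilmModel(intercept=0.0, slope=1000.0, clip_softness=0.0,
                         noise_sd=0.0)
        assert film_response(5.0, film) == pytest.approx(900.0)
        assert film_response(-1.0, film) == pytest.approx(100.0)


class TestToothPair:
    def test_determinism(self):
        spec = PhantomSpec(image_shape=(16, 1200), jitter_frac=0.05,
                           lesion=LesionTruth(erosion_um=5.0))
        b1, a1, _ = generate_tooth_pair(spec, 42)
        b2, a2, _ = generate_tooth_pair(spec, 42)
        np.testing.assert_array_equal(b1.pixels, b2.pixels)
        np.testing.assert_array_equal(a1.pixels, a2.pixels)

    def test_identity_case(self, noiseless_film):
        spec = PhantomSpec(image_shape=(8, 1200), film=noiseless_film)
        before, after, _ = generate_tooth_pair(spec, 0)
        np.testing.assert_array_equal(before.pixels, after.pixels)

    def test_grid_spacing_at_max_magnification(self, noiseless_film):
        # 127 um pitch at 0.305 um/px -> bar maxima 416-417 px apart
        spec = PhantomSpec(image_shape=(4, 1600), film=noiseless_film)
        before, _, _ = generate_tooth_pair(spec, 0)
        row = before.pixels[0].astype(int)
        peak_cols = np.flatnonzero(row == row.max())
        groups = np.split(peak_cols, np.flatnonzero(np.diff(peak_cols) > 1) + 1)
        # bars truncated by the image border have biased centers
        groups = [g for g in groups if g[0] > 0 and g[-1] < row.size - 1]
        centers = np.array([g.mean() for g in groups])
        assert len(centers) >= 3
        spacings = np.diff(centers)
        assert np.all((spacings >= 416) & (spacings <= 417))

    def test_polarity_and_grid_maxima(self, noiseless_film):
        spec = PhantomSpec(image_shape=(8, 1600), film=noiseless_film)
        before, _, _ = generate_tooth_pair(spec, 0)
        lay = analysis_layout(spec)
        bg = before.pixels[:, slice(*lay.background_window)].mean()
        snd = before.pixels[:, slice(*lay.sound_window)].mean()
        assert snd > bg
        assert before.pixels.max() > snd  # grid bars are the raster maxima

    def test_geometry_must_fit(self):
        with pytest.raises(ValidationError, match="fit"):
            PhantomSpec(image_shape=(8, 400), pixel_pitch_um=0.305,
                        lesion=LesionTruth(erosion_um=50.0))

    def test_phantom_image_is_12bit_bounded(self):
        spec = PhantomSpec(image_shape=(8, 1600))
        before, after, _ = generate_tooth_pair(spec, 3)
        assert before.bit_depth == 12
        assert int(before.pixels.max()) <= 4095
        assert int(after.pixels.max()) <= 4095


class TestStepWedge:
    def test_minimum_steps(self, noiseless_film):
        with pytest.raises(ValidationError):
            generate_step_wedge_image(2, [0.2, 0.6], noiseless_film, (40, 20), 0)

    def test_non_increasing_attenuations(self, noiseless_film):
        with pytest.raises(ValidationError):
            generate_step_wedge_image(3, [0.2, 0.2, 0.6], noiseless_film,
                                      (60, 20), 0)

    def test_noise_free_band_means_exact(self, noiseless_film):
        # attenuations multiples of 0.05 with slope 2000 -> integer grayscale
        attens = np.array([0.15, 0.30, 0.45, 0.60, 0.75])
        img, rois, truth = generate_step_wedge_image(5, attens, noiseless_film,
                                                     (5 * 12, 16), 0)
        expected = film_response(attens, noiseless_film)
        for roi, g in zip(rois, expected):
            assert img.pixels[roi.slices].mean() == pytest.approx(g, abs=1e-12)

    def test_noisy_band_means_monotone(self):
        film = FilmModel(noise_sd=20.0)
        attens = np.linspace(0.05, 0.95, 6)
        img, rois, _ = generate_step_wedge_image(6, attens, film, (6 * 40, 60), 1)
        means = [img.pixels[r.slices].mean() for r in rois]
        assert np.all(np.diff(means) > 0)


class TestAnalysisLayout:
    def test_windows_avoid_grid_bars(self):
        spec = PhantomSpec(image_shape=(8, 1600))
        lay = analysis_layout(spec)
        before, _, _ = generate_tooth_pair(
            PhantomSpec(image_shape=(8, 1600),
                        film=FilmModel(noise_sd=0.0)), 0)
        row = before.pixels[0].astype(int)
        grid_val = row.max()
        for win in (lay.background_window, lay.sound_window,
                    lay.surface_segment):
            assert grid_val not in row[slice(*win)]
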