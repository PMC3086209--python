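"""End-to-end measurement chain: images in, lesion measurement out.

Glue between the stage modules: extract -> detect peaks -> align ->
normalize -> gradient fit -> erosion -> demineralization -> report.
Both the command-line ``measure`` subcommand and the synthetic recovery
experiments run through :func:`measure_pair`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lesion as ls
from . import profiles as pf
from .calibration import SpatialCalibration
from .errors import ValidationError
from .phantom import PhantomSpec, analysis_layout
from .raster_io import ROI, RadiographImage

__all__ = ["MeasurementSettings", "MeasurementOutcome", "measure_pair",
           "measure_phantom_pair"]


@dataclass(frozen=True)
class MeasurementSettings:
    """Thresholds and tolerances of the measurement chain (percent scale
    unless noted)."""

    erosion_threshold_pct: float = 20.0
    demin_ceiling_pct: float = 80.0
    band_lo_pct: float = 25.0
    band_hi_pct: float = 75.0
    noise_tolerance_pct: float | None = None  # None: 3 x sound-window noise, floor 2
    noise_tolerance_floor_pct: float = 2.0
    foot_level_pct: float = 5.0
    foot_tol_px: float = 2.5
    eps_distance_um: float = 1.0
    report_depth_pct: float | None = None
    grid_pitch_um: float = 127.0
    align: bool = True


@dataclass
class MeasurementOutcome:
    measurement: ls.LesionMeasurement
    erosion: ls.ErosionResult
    demin: ls.DeminResult
    fit: ls.GradientFit
    pair: pf.AlignedPair              # normalized, full common axis
    segment_pair: pf.AlignedPair      # normalized, surface segment only
    noise_tolerance_pct: float
    report: dict


def _normalized_pair(pair: pf.AlignedPair, background_window, sound_window
                     ) -> pf.AlignedPair:
    nb = pf.normalize_profile(pair.before, background_window, sound_window)
    na = pf.normalize_profile(pair.after, background_window, sound_window)
    return pf.AlignedPair(before=nb, after=na,
                          applied_offset_px=pair.applied_offset_px)


def measure_pair(before: RadiographImage, after: RadiographImage, roi: ROI,
                 background_window: tuple[int, int],
                 sound_window: tuple[int, int],
                 surface_segment: tuple[int, int],
                 calibration: SpatialCalibration | None = None,
                 settings: MeasurementSettings = MeasurementSettings(),
                 ) -> MeasurementOutcome:
    """Run the full chain on a before/after image pair.

    Windows and the surface segment are absolute column-index ranges in
    the *before* image frame; after alignment the after profile lives on
    the same axis.  ``calibration`` overrides any pixel pitch carried in
    the image metadata.
    """
    prof_b = pf.extract_profile(before, roi, axis="columns")
    prof_a = pf.extract_profile(after, roi, axis="columns")
    if calibration is not None:
        prof_b.calibration = calibration
        prof_a.calibration = calibration
    if prof_b.calibration is None:
        raise ValidationError("no spatial calibration: supply one or embed a "
                              "pixel pitch in the image metadata")

    if settings.align:
        peaks_b = pf.detect_grid_peaks(prof_b, grid_pitch_um=settings.grid_pitch_um)
        peaks_a = pf.detect_grid_peaks(prof_a, grid_pitch_um=settings.grid_pitch_um)
        pair = pf.align_profiles(prof_b, prof_a, peaks_b, peaks_a)
    else:
        start = max(prof_b.origin_index, prof_a.origin_index)
        end = min(prof_b.origin_index + len(prof_b),
                  prof_a.origin_index + len(prof_a))
        pair = pf.AlignedPair(before=prof_b.slice_abs(start, end),
                              after=prof_a.slice_abs(start, end),
                              applied_offset_px=0)

    npair = _normalized_pair(pair, background_window, sound_window)

    eps = settings.noise_tolerance_pct
    if eps is None:
        noise = pf.estimate_noise(npair.before, sound_window)
        eps = max(3.0 * noise, settings.noise_tolerance_floor_pct)

    seg = surface_segment
    seg_pair = pf.AlignedPair(
        before=npair.before.slice_abs(seg[0], seg[1]),
        after=npair.after.slice_abs(seg[0], seg[1]),
        applied_offset_px=npair.applied_offset_px)

    fit = ls.fit_surface_gradient(seg_pair.before, settings.band_lo_pct,
                                  settings.band_hi_pct)
    ero = ls.measure_erosion(seg_pair, fit,
                             erosion_threshold_pct=settings.erosion_threshold_pct,
                             noise_tolerance_pct=eps,
                             foot_level_pct=settings.foot_level_pct,
                             foot_tol_px=settings.foot_tol_px)
    dem = ls.measure_demineralization(seg_pair, fit, ero,
                                      demin_ceiling_pct=settings.demin_ceiling_pct,
                                      noise_tolerance_pct=eps,
                                      report_depth_pct=settings.report_depth_pct)
    cls = ls.classify(ero.erosion_um, dem.depth_um, settings.eps_distance_um)
    meas = ls.LesionMeasurement(
        erosion_um=ero.erosion_um, demin_depth_um=dem.depth_um,
        erosion_raw_um=ero.raw_um, classification=cls,
        erosion_threshold_pct=settings.erosion_threshold_pct,
        demin_ceiling_pct=settings.demin_ceiling_pct,
        noise_tolerance_pct=eps, eps_distance_um=settings.eps_distance_um,
        report_depth_pct=settings.report_depth_pct,
        report_depth_um=dem.report_depth_um)
    report = ls.measurement_report(npair, fit, ero, dem, meas,
                                   calibration=calibration)
    return MeasurementOutcome(measurement=meas, erosion=ero, demin=dem, fit=fit,
                              pair=npair, segment_pair=seg_pair,
                              noise_tolerance_pct=eps, report=report)


def measure_phantom_pair(before: RadiographImage, after: RadiographImage,
                         spec: PhantomSpec,
                         settings: MeasurementSettings = MeasurementSettings(),
                         ) -> MeasurementOutcome:
    """Measure a generated phantom pair using windows derived from its
    known geometry (full-height ROI, bar-free normalization windows)."""
    layout = analysis_layout(spec)
    rows, cols = spec.image_shape
    roi = ROI(0, rows, 0, cols)
    calib = SpatialCalibration(spec.pixel_pitch_um, source="phantom spec")
    return measure_pair(before, after, roi,
                        background_window=layout.background_window,
                        sound_window=layout.sound_window,
                        surface_segment=layout.surface_segment,
                        calibration=calib, settings=settings)
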