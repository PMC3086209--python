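"""Geometric erosion and demineralization measurement.

Definitions, on an aligned and normalized before/after profile pair
(percent mineral density versus depth, exterior -> interior):

* **Erosion** — bulk surface loss.  A least-squares line is fitted to the
  before profile's surface gradient; erosion is the depth-axis distance
  between that line and the parallel line of the same slope through the
  after profile's crossing of the erosion threshold (default 20 %
  mineral density).  Reported in micrometers of lost surface.

* **Demineralization** — partial subsurface mineral loss that keeps at
  least ``100 - demin_ceiling_pct`` (default 20 %) of sound density.  Its
  depth runs from the (eroded) surface to the lesion front: the innermost
  depth at which the after profile still falls short of the
  erosion-compensated before profile by more than the noise tolerance.

Zero-calls are explicit.  Erosion is called zero when the two profiles'
surface feet coincide within a pixel-scale tolerance — the profiles rise
from the background at the same place, so any apparent offset between the
threshold crossings is edge-shape distortion by the lesion, not surface
loss.  Negative apparent erosion within tolerance also clamps to zero;
beyond tolerance it raises (apparent surface *gain* means a registration
or polarity fault, and remineralization is out of scope).

Sub-pixel positions come from linear interpolation of threshold
crossings; registration itself stays integer-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    NoCrossingError,
    PolarityError,
    RegistrationFaultError,
    ValidationError,
)
from .profiles import AlignedPair, DensityProfile, UNITS_PERCENT

__all__ = [
    "GradientFit", "ErosionResult", "DeminResult", "LesionMeasurement",
    "fit_surface_gradient", "threshold_crossing", "measure_erosion",
    "measure_demineralization", "classify", "measurement_report",
    "validate_report", "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

CLASS_NONE = "none"
CLASS_EROSION = "erosion-only"
CLASS_DEMIN = "demineralization-only"
CLASS_MIXED = "mixed"


@dataclass(frozen=True)
class GradientFit:
    """Least-squares line through the before profile's surface gradient."""

    slope: float          # percent mineral density per um, > 0
    intercept: float      # percent at position 0 um
    band_lo_pct: float
    band_hi_pct: float
    n_points: int
    residual_rms: float   # percent

    def position_at(self, level_pct: float) -> float:
        """Depth (um) at which the fitted line attains ``level_pct``."""
        return (level_pct - self.intercept) / self.slope


@dataclass(frozen=True)
class ErosionResult:
    erosion_um: float        # reported value (zero-calls applied)
    raw_um: float            # x_after(threshold) - x_line(threshold), unclamped
    zero_called: bool
    threshold_pct: float
    x_before_um: float       # before-gradient line at the threshold
    x_after_um: float        # after-profile crossing of the threshold
    foot_distance_um: float  # after foot minus before foot


@dataclass(frozen=True)
class DeminResult:
    depth_um: float
    front_um: float | None          # lesion front; None when no deficit found
    surface_ref_um: float
    report_depth_pct: float | None
    report_depth_um: float | None
    max_deficit_pct: float
    erosion_zone_fraction: float    # lesion samples below the demin floor


@dataclass(frozen=True)
class LesionMeasurement:
    erosion_um: float
    demin_depth_um: float
    erosion_raw_um: float
    classification: str
    erosion_threshold_pct: float
    demin_ceiling_pct: float
    noise_tolerance_pct: float
    eps_distance_um: float
    report_depth_pct: float | None = None
    report_depth_um: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.erosion_um) and self.erosion_um >= 0):
            raise ValidationError("erosion_um must be finite and >= 0")
        if not (np.isfinite(self.demin_depth_um) and self.demin_depth_um >= 0):
            raise ValidationError("demin_depth_um must be finite and >= 0")
        expected = classify(self.erosion_um, self.demin_depth_um, self.eps_distance_um)
        if expected != self.classification:
            raise ValidationError(
                f"classification {self.classification!r} inconsistent with "
                f"distances (expected {expected!r})")


def _require_percent(profile: DensityProfile) -> None:
    if profile.units != UNITS_PERCENT:
        raise ValidationError("profile must be normalized to percent mineral density")


def fit_surface_gradient(profile: DensityProfile, band_lo_pct: float = 25.0,
                         band_hi_pct: float = 75.0) -> GradientFit:
    """Fit the outermost rising edge of a normalized profile.

    Selects the first (most exterior) contiguous run of samples whose
    values lie within ``[band_lo_pct, band_hi_pct]`` and fits percent
    density against depth in micrometers.  The default 25-75 % band keeps
    a margin inside the film's trusted 10-90 % linear range.
    """
    _require_percent(profile)
    v = profile.values
    x = profile.positions_um
    start = None
    for i in range(v.size):
        if v[i] >= band_lo_pct:
            start = i
            break
    if start is None:
        raise InsufficientDataError(
            f"profile never reaches {band_lo_pct}%; no rising edge in view")
    end = start
    while end < v.size and band_lo_pct <= v[end] <= band_hi_pct:
        end += 1
    n = end - start
    if n < 3:
        raise InsufficientDataError(
            f"only {n} samples inside the {band_lo_pct}-{band_hi_pct}% band; "
            "need >= 3 (edge too steep for this pixel pitch?)")
    fit = stats.linregress(x[start:end], v[start:end])
    if fit.slope <= 0:
        raise PolarityError("fitted surface gradient is non-positive")
    resid = v[start:end] - (fit.intercept + fit.slope * x[start:end])
    return GradientFit(slope=float(fit.slope), intercept=float(fit.intercept),
                       band_lo_pct=band_lo_pct, band_hi_pct=band_hi_pct,
                       n_points=n, residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def threshold_crossing(profile: DensityProfile, level_pct: float) -> float:
    """First exterior->interior crossing of ``level_pct``, in micrometers.

    Linearly interpolated between the bracketing samples.  If the profile
    already starts at or above the level, the first sample's position is
    returned.
    """
    _require_percent(profile)
    v = profile.values
    x = profile.positions_um
    if v[0] >= level_pct:
        return float(x[0])
    for i in range(1, v.size):
        if v[i] >= level_pct:
            frac = (level_pct - v[i - 1]) / (v[i] - v[i - 1])
            return float(x[i - 1] + frac * (x[i] - x[i - 1]))
    raise NoCrossingError(
        f"profile never rises to {level_pct}% (max {v.max():.1f}%)")


def measure_erosion(pair: AlignedPair, fit: GradientFit,
                    erosion_threshold_pct: float = 20.0,
                    noise_tolerance_pct: float = 2.0,
                    foot_level_pct: float = 5.0,
                    foot_tol_px: float = 2.5) -> ErosionResult:
    """Erosion: depth-axis distance between the before-gradient line and
    the same-slope line through the after profile's threshold crossing.

    ``x_line = (threshold - intercept) / slope`` from the fitted line
    (closed form); ``x_after`` from :func:`threshold_crossing`.  The raw
    distance ``x_after - x_line`` is zero-called when the two profiles'
    surface feet (first crossings of ``foot_level_pct``) coincide within
    ``foot_tol_px`` pixels.  Raw values more negative than the noise
    tolerance raise :class:`RegistrationFaultError`.
    """
    _require_percent(pair.before)
    _require_percent(pair.after)
    pitch = pair.before.um_per_pixel
    x_line = fit.position_at(erosion_threshold_pct)
    x_after = threshold_crossing(pair.after, erosion_threshold_pct)
    raw = x_after - x_line

    foot_b = threshold_crossing(pair.before, foot_level_pct)
    foot_a = threshold_crossing(pair.after, foot_level_pct)
    foot_dist = foot_a - foot_b

    neg_tol = max(noise_tolerance_pct / fit.slope, pitch)
    if raw < -neg_tol:
        raise RegistrationFaultError(
            f"after surface sits {-raw:.2f} um exterior of the before surface "
            f"(tolerance {neg_tol:.2f} um): registration or polarity fault")
    zero_called = abs(foot_dist) <= foot_tol_px * pitch
    erosion = 0.0 if (zero_called or raw <= 0.0) else raw
    return ErosionResult(erosion_um=erosion, raw_um=raw,
                         zero_called=zero_called or raw <= 0.0,
                         threshold_pct=erosion_threshold_pct,
                         x_before_um=x_line, x_after_um=x_after,
                         foot_distance_um=foot_dist)


def _smooth(v: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return v
    kernel = np.ones(k) / k
    return np.convolve(v, kernel, mode="same")


def measure_demineralization(pair: AlignedPair, fit: GradientFit,
                             erosion: ErosionResult,
                             demin_ceiling_pct: float = 80.0,
                             noise_tolerance_pct: float = 2.0,
                             report_depth_pct: float | None = None,
                             smooth_px: int = 1,
                             slope_fit_samples: int = 4) -> DeminResult:
    """Demineralization depth: lesion front minus eroded-surface reference.

    The before profile is translated inward by the *reported* erosion so
    that a purely eroded edge cancels; the residual deficit
    ``before(x - e) - after(x)`` is scanned from the
    interior outward for its first excursion above the noise tolerance.
    The tolerance crossing is interpolated sub-pixel and then extrapolated
    to the zero-deficit depth using the local deficit slope, since the
    raw tolerance crossing systematically undershoots the true front by
    ``tolerance / slope``.  The surface reference is the before-gradient
    line's zero-density position advanced by the reported erosion.
    """
    _require_percent(pair.before)
    _require_percent(pair.after)
    if smooth_px < 1 or smooth_px % 2 == 0:
        raise ValidationError("smooth_px must be a positive odd integer")
    x = pair.before.positions_um
    pitch = pair.before.um_per_pixel
    vb, va = pair.before.values, pair.after.values
    eps = noise_tolerance_pct

    shift = erosion.erosion_um
    vb_shifted = np.interp(x - shift, x, vb)
    deficit = _smooth(vb_shifted - va, smooth_px)

    # innermost index where the deficit still exceeds tolerance
    above = deficit > eps
    front: float | None = None
    j = None
    for i in range(x.size - 1, -1, -1):
        if above[i]:
            j = i
            break
    if j is not None:
        if j == x.size - 1:
            raise ValidationError(
                "deficit exceeds tolerance at the interior end of the analysis "
                "segment; segment too short or inputs misordered")
        # sub-pixel tolerance crossing between j (above) and j+1 (below)
        frac = (deficit[j] - eps) / (deficit[j] - deficit[j + 1])
        x_c = float(x[j] + frac * (x[j + 1] - x[j]))
        # local deficit slope from the exterior side of the crossing
        lo = max(j - slope_fit_samples + 1, 0)
        seg_x, seg_d = x[lo:j + 2], deficit[lo:j + 2]
        slope = float(stats.linregress(seg_x, seg_d).slope) if seg_x.size >= 2 else 0.0
        if slope < -1e-9:
            extension = min(eps / -slope, max(5.0 * pitch, 5.0))
        else:
            extension = 0.0
        front = x_c + extension

    surface_ref = fit.position_at(0.0) + erosion.erosion_um
    depth = max(front - surface_ref, 0.0) if front is not None else 0.0

    max_deficit = float(deficit.max()) if x.size else 0.0
    erosion_zone_fraction = 0.0
    if front is not None:
        lesion_mask = (x >= surface_ref) & (x <= front) & (vb_shifted - va > eps)
        if lesion_mask.any():
            floor = 100.0 - demin_ceiling_pct
            erosion_zone_fraction = float(np.mean(va[lesion_mask] < floor))

    rep_um: float | None = None
    if report_depth_pct is not None:
        below = va < report_depth_pct
        for i in range(x.size - 1, 0, -1):
            if below[i]:
                frac = (report_depth_pct - va[i]) / (va[i - 1] - va[i]) \
                    if va[i - 1] != va[i] else 0.0
                rep_um = float(x[i] + frac * (x[i - 1] - x[i]))
                break

    return DeminResult(depth_um=depth, front_um=front, surface_ref_um=surface_ref,
                       report_depth_pct=report_depth_pct, report_depth_um=rep_um,
                       max_deficit_pct=max_deficit,
                       erosion_zone_fraction=erosion_zone_fraction)


def classify(erosion_um: float, demin_depth_um: float,
             eps_distance_um: float = 1.0) -> str:
    """Classify a measurement by which distances exceed ``eps_distance_um``."""
    if erosion_um < 0 or demin_depth_um < 0:
        raise ValidationError("distances must be >= 0")
    has_e = erosion_um >= eps_distance_um
    has_d = demin_depth_um >= eps_distance_um
    if has_e and has_d:
        return CLASS_MIXED
    if has_e:
        return CLASS_EROSION
    if has_d:
        return CLASS_DEMIN
    return CLASS_NONE


def measurement_report(pair: AlignedPair, fit: GradientFit,
                       erosion: ErosionResult, demin: DeminResult,
                       measurement: LesionMeasurement,
                       calibration=None) -> dict:
    """Assemble a JSON-serializable measurement report.

    Distances appear both in micrometers and in pixels; the normalized
    profile pair is embedded for plotting (positions plus both value
    arrays on the common axis).
    """
    pitch = pair.before.um_per_pixel if pair.before.calibration else None
    if calibration is not None:
        pitch = calibration.um_per_pixel

    def px(um: float | None) -> float | None:
        return None if (um is None or pitch is None) else um / pitch

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "calibration": {
            "um_per_pixel": pitch,
            "source": getattr(calibration or pair.before.calibration, "source", ""),
        },
        "alignment": {"applied_offset_px": pair.applied_offset_px},
        "gradient_fit": {
            "slope_pct_per_um": fit.slope,
            "intercept_pct": fit.intercept,
            "band_lo_pct": fit.band_lo_pct,
            "band_hi_pct": fit.band_hi_pct,
            "n_points": fit.n_points,
            "residual_rms_pct": fit.residual_rms,
        },
        "erosion": {
            "um": measurement.erosion_um,
            "px": px(measurement.erosion_um),
            "raw_um": erosion.raw_um,
            "zero_called": erosion.zero_called,
            "threshold_pct": erosion.threshold_pct,
            "x_before_um": erosion.x_before_um,
            "x_after_um": erosion.x_after_um,
            "foot_distance_um": erosion.foot_distance_um,
        },
        "demineralization": {
            "depth_um": measurement.demin_depth_um,
            "depth_px": px(measurement.demin_depth_um),
            "front_um": demin.front_um,
            "surface_ref_um": demin.surface_ref_um,
            "max_deficit_pct": demin.max_deficit_pct,
            "erosion_zone_fraction": demin.erosion_zone_fraction,
            "report_depth_pct": demin.report_depth_pct,
            "report_depth_um": demin.report_depth_um,
        },
        "thresholds": {
            "erosion_threshold_pct": measurement.erosion_threshold_pct,
            "demin_ceiling_pct": measurement.demin_ceiling_pct,
            "noise_tolerance_pct": measurement.noise_tolerance_pct,
            "eps_distance_um": measurement.eps_distance_um,
        },
        "classification": measurement.classification,
        "profiles": {
            "position_px": [int(p) for p in pair.before.positions_px],
            "position_um": ([float(p) for p in pair.before.positions_um]
                            if pair.before.calibration else None),
            "before_pct": [float(v) for v in pair.before.values],
            "after_pct": [float(v) for v in pair.after.values],
        },
    }


_REQUIRED_REPORT_KEYS = {
    "schema_version", "calibration", "alignment", "gradient_fit", "erosion",
    "demineralization", "thresholds", "classification", "profiles",
}


def validate_report(report: dict) -> None:
    """Check a report dict against the (flat) schema; raise on problems."""
    missing = sorted(_REQUIRED_REPORT_KEYS - set(report))
    if missing:
        raise ValidationError(f"report missing keys: {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported report schema version {report['schema_version']}")
    for key in ("um", "raw_um"):
        if key not in report["erosion"]:
            raise ValidationError(f"report erosion block missing {key!r}")
    if "depth_um" not in report["demineralization"]:
        raise ValidationError("report demineralization block missing depth_um")
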