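"""Width-averaged density profiles, grid-peak registration, normalization.

The measurement chain works on 1-D profiles: a rectangular ROI is averaged
across its width to give grayscale versus depth position (exterior ->
interior).  The near-opaque bars of the TEM-grid fiducial produce grayscale
maxima at a known pitch; matching those peaks between the before and after
profiles yields the integer-pixel offset that registers the two exposures.
Finally a two-point normalization maps the black background to 0 % and
unaffected (sound) mineral to 100 % mineral density; grid-peak samples may
legitimately exceed 100 % since metal out-attenuates enamel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .calibration import SpatialCalibration
from .errors import (
    AlignmentError,
    DegenerateNormalizationError,
    PolarityError,
    ValidationError,
)
from .raster_io import ROI, RadiographImage

__all__ = [
    "DensityProfile", "GridPeaks", "AlignedPair",
    "extract_profile", "detect_grid_peaks", "align_profiles",
    "normalize_profile", "estimate_noise",
]

UNITS_GRAYSCALE = "grayscale"
UNITS_PERCENT = "percent_mineral_density"


@dataclass
class DensityProfile:
    """1-D profile: one value per pixel position along the chosen axis.

    Positions are implicit: sample ``i`` sits at absolute pixel index
    ``origin_index + i`` in the source image frame, and at
    ``(origin_index + i) * um_per_pixel`` micrometers when calibrated.
    Direction is exterior -> interior.
    """

    values: np.ndarray
    origin_index: int = 0
    axis: str = "columns"
    calibration: SpatialCalibration | None = None
    units: str = UNITS_GRAYSCALE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("a profile needs at least 2 samples")
        if self.axis not in ("rows", "columns"):
            raise ValidationError(f"axis must be 'rows' or 'columns', got {self.axis!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def positions_px(self) -> np.ndarray:
        return self.origin_index + np.arange(self.values.size)

    @property
    def positions_um(self) -> np.ndarray:
        if self.calibration is None:
            raise ValidationError("profile has no spatial calibration")
        return self.positions_px * self.calibration.um_per_pixel

    @property
    def um_per_pixel(self) -> float:
        if self.calibration is None:
            raise ValidationError("profile has no spatial calibration")
        return self.calibration.um_per_pixel

    def slice_abs(self, start: int, end: int) -> "DensityProfile":
        """Sub-profile over absolute pixel indices [start, end)."""
        i0 = start - self.origin_index
        i1 = end - self.origin_index
        if i0 < 0 or i1 > self.values.size or i1 - i0 < 2:
            raise ValidationError(
                f"slice [{start}, {end}) outside profile "
                f"[{self.origin_index}, {self.origin_index + self.values.size})")
        return replace(self, values=self.values[i0:i1], origin_index=start)

    def window_mean(self, window: tuple[int, int]) -> float:
        """Mean value over absolute pixel indices [window[0], window[1])."""
        sub = self.slice_abs(window[0], window[1])
        return float(sub.values.mean())


@dataclass(frozen=True)
class GridPeaks:
    """Detected fiducial peaks: absolute (sub-sample) pixel positions."""

    positions: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValidationError("peak positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "prominences",
                           np.asarray(self.prominences, dtype=float))

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class AlignedPair:
    """Before/after profiles registered onto a common position axis."""

    before: DensityProfile
    after: DensityProfile
    applied_offset_px: int

    def __post_init__(self) -> None:
        if self.before.origin_index != self.after.origin_index \
                or len(self.before) != len(self.after):
            raise ValidationError("aligned profiles must share origin and length")


def extract_profile(image: RadiographImage, roi: ROI,
                    axis: str = "columns") -> DensityProfile:
    """Average an ROI across its width into a 1-D grayscale profile.

    ``axis='columns'`` yields one value per column (mean over the ROI's
    rows), i.e. a profile running along the image width; ``axis='rows'``
    the transpose.  This mirrors the familiar plot-profile behaviour of
    averaging pixels perpendicular to the selection direction.
    """
    roi.validate_within(image.pixels.shape)
    block = image.pixels[roi.slices].astype(float)
    if axis == "columns":
        values = block.mean(axis=0)
        origin = roi.col_start
    elif axis == "rows":
        values = block.mean(axis=1)
        origin = roi.row_start
    else:
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if values.size < 2:
        raise ValidationError("profile axis must span at least 2 pixels")
    calibration = None
    if image.pixel_pitch_um is not None:
        calibration = SpatialCalibration(image.pixel_pitch_um, source="image metadata")
    return DensityProfile(values=values, origin_index=origin, axis=axis,
                          calibration=calibration)


def detect_grid_peaks(profile: DensityProfile,
                      min_separation_px: float | None = None,
                      min_prominence: float | None = None,
                      grid_pitch_um: float = 127.0) -> GridPeaks:
    """Locate the grayscale maxima produced by the metal grid bars.

    Local maxima with at least ``min_prominence`` prominence and pairwise
    separation >= ``min_separation_px`` (default: half the grid pitch in
    pixels when the profile is calibrated).  The prominence default is
    8 % of the profile range: bars standing on the bright enamel plateau
    are far less prominent than bars over background, yet still dominate
    grain noise by orders of magnitude.  Each peak position is refined
    to the intensity-weighted centroid of the contiguous run of samples
    above ``peak - prominence/2``, so the wide, flat-topped bars get stable
    sub-sample positions.  Finding no peaks is not an error.
    """
    v = profile.values
    if min_separation_px is None:
        if profile.calibration is None:
            raise ValidationError(
                "min_separation_px required for an uncalibrated profile")
        min_separation_px = 0.5 * grid_pitch_um / profile.um_per_pixel
    if min_prominence is None:
        min_prominence = 0.08 * (float(v.max()) - float(v.min()))
    if min_prominence <= 0:  # flat profile
        return GridPeaks(np.empty(0), np.empty(0))

    idx, props = signal.find_peaks(v, prominence=min_prominence,
                                   distance=max(int(min_separation_px), 1))
    positions = []
    proms = []
    for i, p in zip(idx, props["prominences"]):
        thr = v[i] - 0.5 * p
        a = i
        while a > 0 and v[a - 1] >= thr:
            a -= 1
        b = i
        while b < v.size - 1 and v[b + 1] >= thr:
            b += 1
        w = v[a:b + 1] - thr
        centroid = float(np.sum(np.arange(a, b + 1) * w) / np.sum(w))
        positions.append(profile.origin_index + centroid)
        proms.append(float(p))
    return GridPeaks(np.asarray(positions), np.asarray(proms))


def _match_score(b: np.ndarray, a: np.ndarray, offset: int, tol: float
                 ) -> tuple[int, float]:
    shifted = a + offset
    j = np.searchsorted(b, shifted)
    n, cost = 0, 0.0
    for k, x in enumerate(shifted):
        cands = []
        if j[k] < b.size:
            cands.append(b[j[k]])
        if j[k] > 0:
            cands.append(b[j[k] - 1])
        if not cands:
            continue
        d = min(abs(x - c) for c in cands)
        if d <= tol:
            n += 1
            cost += d * d
    return n, cost


def align_profiles(before: DensityProfile, after: DensityProfile,
                   peaks_before: GridPeaks, peaks_after: GridPeaks,
                   match_tol_px: float | None = None) -> AlignedPair:
    """Register the after profile onto the before profile via grid peaks.

    Chooses the integer offset minimizing the summed squared distance
    between greedily matched peaks, preferring more matches, then lower
    cost, then the smallest ``|offset|``.  The offset is applied to the
    after profile's origin and both profiles are cropped to their common
    axis.  Registration is integer-pixel by design; sub-pixel precision
    enters later through interpolated threshold crossings.
    """
    if len(peaks_before) < 1 or len(peaks_after) < 1:
        raise AlignmentError(
            f"need at least one grid peak on each side "
            f"(before: {len(peaks_before)}, after: {len(peaks_after)})")
    b = np.sort(peaks_before.positions)
    a = np.sort(peaks_after.positions)
    if match_tol_px is None:
        spacings = np.diff(b)
        match_tol_px = float(0.25 * np.median(spacings)) if spacings.size else 10.0

    cands = sorted({int(round(pb - pa)) for pb in b for pa in a})
    best: tuple[int, float, int] | None = None  # (-n, cost, |off|) minimized
    best_off = None
    for off in cands:
        n, cost = _match_score(b, a, off, match_tol_px)
        if n == 0:
            continue
        key = (-n, cost, abs(off))
        if best is None or key < best:
            best = key
            best_off = off
    if best_off is None:
        raise AlignmentError(
            f"no peak matching within {match_tol_px:.1f} px for any candidate "
            f"offset; before peaks at {b}, after peaks at {a}")

    n_matched, cost = _match_score(b, a, best_off, match_tol_px)
    rms = float(np.sqrt(cost / n_matched))
    if rms > 1.0:
        raise AlignmentError(
            f"best offset {best_off} px leaves matched-peak rms residual "
            f"{rms:.2f} px (> 1 px); {n_matched} peaks matched")

    shifted_after = replace(after, origin_index=after.origin_index + best_off)
    start = max(before.origin_index, shifted_after.origin_index)
    end = min(before.origin_index + len(before),
              shifted_after.origin_index + len(shifted_after))
    if end - start < 2:
        raise AlignmentError("aligned profiles have no overlap")
    return AlignedPair(before=before.slice_abs(start, end),
                       after=shifted_after.slice_abs(start, end),
                       applied_offset_px=best_off)


def normalize_profile(profile: DensityProfile,
                      background_window: tuple[int, int],
                      sound_window: tuple[int, int]) -> DensityProfile:
    """Two-point normalization to percent mineral density.

    The mean over ``background_window`` maps to 0 % and the mean over
    ``sound_window`` to 100 %; the same affine map is applied to every
    sample.  Windows are absolute pixel-index ranges.  Idempotent when
    re-applied with the same windows, and exactly invariant under positive
    affine transforms of the raw grayscale.
    """
    m_bg = profile.window_mean(background_window)
    m_snd = profile.window_mean(sound_window)
    if m_bg == m_snd:
        raise DegenerateNormalizationError(
            "background and sound windows have equal means")
    if m_bg > m_snd:
        raise PolarityError(
            f"background mean ({m_bg:.1f}) exceeds sound mean ({m_snd:.1f}); "
            "check film orientation / window placement")
    values = 100.0 * (profile.values - m_bg) / (m_snd - m_bg)
    return replace(profile, values=values, units=UNITS_PERCENT)


def estimate_noise(profile: DensityProfile, window: tuple[int, int]) -> float:
    """Sample standard deviation over a user-designated flat window."""
    sub = profile.slice_abs(window[0], window[1])
    if len(sub) < 8:
        raise ValidationError(f"noise window must span >= 8 samples, got {len(sub)}")
    return float(np.std(sub.values, ddof=1))
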