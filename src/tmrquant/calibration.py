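"""Spatial calibration and step-wedge film-linearity assessment.

Contact microradiography encodes mineral density as film grayscale.  Two
calibrations make the grayscale quantitative:

* **Spatial** — micrometers per pixel, measured by counting pixels across a
  known stage-micrometer distance.
* **Densitometric** — an aluminum step wedge radiographed beside every
  sample verifies that grayscale responds *linearly* to x-ray attenuation
  over the working range.  Brightness and contrast differ between
  radiographs (developer freshness, digitization lamp intensity, ...) but
  act as affine modifiers of grayscale, so a two-point normalization at two
  anchor steps removes them exactly.  The pooled, normalized wedge response
  is then fitted against step index and its r-squared reported.

Standard-deviation conventions: pixel ROIs use the population sd (the ROI
is the whole region of interest, not a sample); across-wedge spread uses
the sample sd (it estimates process variability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateNormalizationError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "SpatialCalibration",
    "WedgeMeasurement",
    "LinearityReport",
    "spatial_calibration",
    "wedge_step_means",
    "normalize_wedge",
    "choose_anchor_steps",
    "pooled_linearity",
]


@dataclass(frozen=True)
class SpatialCalibration:
    """Micrometers per pixel plus a free-text provenance note."""

    um_per_pixel: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.um_per_pixel) and self.um_per_pixel > 0):
            raise ValidationError(
                f"um_per_pixel must be a positive finite real, got {self.um_per_pixel!r}"
            )


@dataclass
class WedgeMeasurement:
    """Per-step mean/sd grayscale of one radiograph of one step wedge.

    Step index 0 is the thinnest (least attenuating) step.
    """

    wedge_id: str
    radiograph_id: str
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.ndim != 1 or self.means.size < 3:
            raise ValidationError("a wedge needs at least 3 steps")
        if self.sds.shape != self.means.shape:
            raise ValidationError("means and sds must have the same length")

    @property
    def n_steps(self) -> int:
        return int(self.means.size)


@dataclass
class LinearityReport:
    """Least-squares assessment of the pooled normalized wedge response."""

    slope: float
    intercept: float
    r_squared: float
    range_lo_pct: float
    range_hi_pct: float
    anchor_low_step: int
    anchor_high_step: int
    target_low_pct: float
    target_high_pct: float
    step_means: np.ndarray  # per-wedge-averaged normalized means, step-wise mean across wedges
    step_sds: np.ndarray    # sample sd across wedges, NaN where < 2 wedges
    n_points: int
    n_wedges: int
    r2_threshold: float
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError(f"r_squared outside [0, 1]: {self.r_squared}")
        self.passed = bool(self.r_squared >= self.r2_threshold)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "range_lo_pct": self.range_lo_pct,
            "range_hi_pct": self.range_hi_pct,
            "anchor_low_step": self.anchor_low_step,
            "anchor_high_step": self.anchor_high_step,
            "target_low_pct": self.target_low_pct,
            "target_high_pct": self.target_high_pct,
            "step_means": list(map(float, self.step_means)),
            "step_sds": [None if not np.isfinite(s) else float(s) for s in self.step_sds],
            "n_points": self.n_points,
            "n_wedges": self.n_wedges,
            "r2_threshold": self.r2_threshold,
            "passed": self.passed,
        }


def spatial_calibration(pixel_count: int, known_distance_um: float,
                        source: str = "stage micrometer") -> SpatialCalibration:
    """Derive micrometers-per-pixel from a stage-micrometer measurement.

    Parameters
    ----------
    pixel_count : number of pixels spanning the known distance (> 0).
    known_distance_um : the marked distance on the stage micrometer (> 0).
    """
    if pixel_count <= 0:
        raise ValidationError(f"pixel_count must be > 0, got {pixel_count}")
    if not known_distance_um > 0:
        raise ValidationError(f"known_distance_um must be > 0, got {known_distance_um}")
    return SpatialCalibration(um_per_pixel=known_distance_um / float(pixel_count),
                              source=source)


def wedge_step_means(image, step_rois: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population sd of pixel grayscale per step ROI.

    ``step_rois`` is ordered thinnest step first.  ROIs must be pairwise
    disjoint and lie within the raster.
    """
    from .raster_io import RadiographImage, ROI  # noqa: F401  (type reference)

    rois = list(step_rois)
    if len(rois) < 3:
        raise ValidationError("need at least 3 step ROIs")
    shape = image.pixels.shape
    for r in rois:
        r.validate_within(shape)
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            if rois[i].overlaps(rois[j]):
                raise ValidationError(f"step ROIs {i} and {j} overlap")
    means = np.empty(len(rois))
    sds = np.empty(len(rois))
    for k, r in enumerate(rois):
        block = image.pixels[r.slices].astype(float)
        means[k] = block.mean()
        sds[k] = block.std(ddof=0)  # population sd: fixed region, not a sample
    return means, sds


def normalize_wedge(means: np.ndarray, anchor_low_step: int, anchor_high_step: int,
                    target_low_pct: float = 20.0,
                    target_high_pct: float = 80.0) -> np.ndarray:
    """Two-point affine normalization of step means to a percent scale.

    Maps the low-anchor mean to ``target_low_pct`` and the high-anchor mean
    to ``target_high_pct``; other steps may legitimately fall outside
    [0, 100].  Invariant under any positive affine transform of the raw
    grayscale, which is exactly why inter-radiograph brightness/contrast
    differences drop out.
    """
    means = np.asarray(means, dtype=float)
    n = means.size
    for a in (anchor_low_step, anchor_high_step):
        if not (0 <= a < n):
            raise ValidationError(f"anchor step {a} outside [0, {n})")
    m_lo = means[anchor_low_step]
    m_hi = means[anchor_high_step]
    if m_lo == m_hi:
        raise DegenerateNormalizationError(
            "anchor steps have equal mean grayscale; cannot normalize")
    if m_lo > m_hi:
        raise ValidationError(
            "low anchor mean exceeds high anchor mean; check step ordering/polarity")
    scale = (target_high_pct - target_low_pct) / (m_hi - m_lo)
    return target_low_pct + (means - m_lo) * scale


def choose_anchor_steps(means: np.ndarray, target_low_pct: float = 20.0,
                        target_high_pct: float = 80.0) -> tuple[int, int]:
    """Propose the anchor steps whose means sit nearest the target fractions
    of the observed grayscale range.  A convenience only — anchors remain an
    explicit, user-visible choice."""
    means = np.asarray(means, dtype=float)
    lo, hi = means.min(), means.max()
    if hi == lo:
        raise DegenerateNormalizationError("all step means equal")
    frac = 100.0 * (means - lo) / (hi - lo)
    low = int(np.argmin(np.abs(frac - target_low_pct)))
    high = int(np.argmin(np.abs(frac - target_high_pct)))
    if low == high:
        raise ValidationError("anchor selection collapsed onto a single step")
    return (low, high) if low < high else (high, low)


def pooled_linearity(measurements: Sequence[WedgeMeasurement],
                     anchor_low_step: int, anchor_high_step: int,
                     target_low_pct: float = 20.0, target_high_pct: float = 80.0,
                     range_lo_pct: float = 10.0, range_hi_pct: float = 90.0,
                     r2_threshold: float = 0.9959) -> LinearityReport:
    """Pooled linearity of a multi-wedge, multi-radiograph series.

    Each radiograph is normalized independently (two-point anchor rule),
    repeats of the same wedge are averaged per step, and a least-squares
    line of averaged normalized value versus step index is fitted over the
    steps whose averaged value lies within ``[range_lo_pct, range_hi_pct]``
    — the band where the film is trusted to be linear.  ``r_squared`` is
    the squared Pearson correlation of those pooled points.
    """
    ms = list(measurements)
    if len(ms) < 1:
        raise ValidationError("no wedge measurements supplied")
    n_steps = ms[0].n_steps
    if any(m.n_steps != n_steps for m in ms):
        raise ValidationError("all radiographs in a series must share the step count")

    by_wedge: dict[str, list[np.ndarray]] = {}
    for m in ms:
        norm = normalize_wedge(m.means, anchor_low_step, anchor_high_step,
                               target_low_pct, target_high_pct)
        by_wedge.setdefault(m.wedge_id, []).append(norm)

    wedge_avg = {w: np.mean(np.vstack(v), axis=0) for w, v in by_wedge.items()}
    stack = np.vstack(list(wedge_avg.values()))  # (n_wedges, n_steps)
    step_means = stack.mean(axis=0)
    if stack.shape[0] >= 2:
        step_sds = stack.std(axis=0, ddof=1)  # sample sd: across-wedge variability
    else:
        step_sds = np.full(n_steps, np.nan)

    xs, ys = [], []
    for row in stack:
        for step, v in enumerate(row):
            if range_lo_pct <= v <= range_hi_pct:
                xs.append(step)
                ys.append(v)
    xs_a = np.asarray(xs, dtype=float)
    ys_a = np.asarray(ys, dtype=float)
    if np.unique(xs_a).size < 3:
        raise InsufficientDataError(
            f"only {np.unique(xs_a).size} steps fall inside "
            f"[{range_lo_pct}, {range_hi_pct}]%; need at least 3")

    fit = stats.linregress(xs_a, ys_a)
    r2 = float(min(fit.rvalue ** 2, 1.0))
    return LinearityReport(
        slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2,
        range_lo_pct=range_lo_pct, range_hi_pct=range_hi_pct,
        anchor_low_step=anchor_low_step, anchor_high_step=anchor_high_step,
        target_low_pct=target_low_pct, target_high_pct=target_high_pct,
        step_means=step_means, step_sds=step_sds,
        n_points=int(xs_a.size), n_wedges=int(stack.shape[0]),
        r2_threshold=r2_threshold,
    )
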