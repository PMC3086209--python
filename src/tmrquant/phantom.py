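"""Synthetic negative-film radiograph phantoms with known ground truth.

The physical films behind the method are not available, so this module
emulates them: a 100 um tooth slab imaged edge-on, a metal TEM-grid
fiducial (127 um pitch, 24 um bars) glued to the surface, an aluminum step
wedge, per-radiograph brightness/contrast variation, reciprocity-failure
style nonlinearity at the scale extremes, and additive grain noise.

Geometry is deliberately 1-D: mineral density varies only along the depth
axis (image columns), is constant along rows, and the depth position of
column ``c`` is ``c * pixel_pitch_um``.  Column-averaged profiles therefore
recover the ground-truth curves exactly up to noise and quantization.

Polarity is that of a digitized negative: more attenuating material reads
*brighter*, so the near-opaque grid bars are the raster maxima and the
unattenuated background is darkest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .raster_io import ROI, RadiographImage

__all__ = [
    "FilmModel", "LesionTruth", "PhantomSpec", "AnalysisLayout",
    "mineral_density_before", "mineral_density_after", "film_response",
    "generate_tooth_pair", "generate_step_wedge_image", "analysis_layout",
]


@dataclass(frozen=True)
class FilmModel:
    """Film + digitization response: grayscale vs. x-ray attenuation.

    The response is exactly affine (``intercept + slope * a``) for
    attenuation fractions inside ``[linear_lo, linear_hi]`` and rolls off
    smoothly, monotonically and boundedly outside — a stand-in for
    reciprocity failure at the lightest and darkest film regions; no
    quantitative characteristic curve is available for the real film.

    ``clip_softness`` (attenuation units) sets the roll-off scale; 0 gives
    a hard clip.  ``noise_sd`` is additive Gaussian grain noise in
    grayscale units, applied by the generators (never by
    :func:`film_response` itself).
    """

    intercept: float = 400.0
    slope: float = 3400.0
    linear_lo: float = 0.10
    linear_hi: float = 0.90
    clip_softness: float = 0.05
    noise_sd: float = 41.0  # ~1 % of 12-bit full scale

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValidationError("slope must be > 0 (negative-film polarity)")
        if not (0.0 <= self.linear_lo < self.linear_hi <= 1.0):
            raise ValidationError("need 0 <= linear_lo < linear_hi <= 1")
        if self.clip_softness < 0:
            raise ValidationError("clip_softness must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LesionTruth:
    """Ground-truth lesion parameters for a before/after pair.

    ``surface_position_um`` (s): depth of the before-image surface;
    ``edge_width_um`` (w): width of the linear surface density ramp;
    ``erosion_um`` (e): bulk surface loss; ``demin_depth_um`` (L): depth of
    the demineralized zone; ``demin_severity`` (delta): maximum fractional
    mineral loss, capped at 0.8 so lesion density keeps at least 20 % of
    sound — deeper loss counts as erosion, not demineralization.
    """

    surface_position_um: float = 150.0
    edge_width_um: float = 8.0
    erosion_um: float = 0.0
    demin_depth_um: float = 0.0
    demin_severity: float = 0.0

    def __post_init__(self) -> None:
        if not self.edge_width_um > 0:
            raise ValidationError("edge_width_um must be > 0")
        if self.erosion_um < 0 or self.demin_depth_um < 0:
            raise ValidationError("erosion_um and demin_depth_um must be >= 0")
        if not (0.0 <= self.demin_severity <= 0.8):
            raise ValidationError("demin_severity must lie in [0, 0.8]")


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render a deterministic before/after pair."""

    image_shape: tuple[int, int] = (96, 1600)
    pixel_pitch_um: float = 0.305
    film: FilmModel = field(default_factory=FilmModel)
    lesion: LesionTruth = field(default_factory=LesionTruth)
    grid_pitch_um: float = 127.0
    grid_bar_um: float = 24.0
    grid_present: bool = True
    grid_phase_um: float | None = None  # center of one bar; default surface - 40 um
    background_attenuation: float = 0.0
    sound_attenuation: float = 0.8
    bit_depth: int = 12
    jitter_frac: float = 0.0       # per-radiograph uniform brightness/contrast jitter
    after_shift_px: int = 0        # whole-scene shift of the after exposure (film repositioning)

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 2 or cols < 2:
            raise ValidationError("image_shape must be at least 2x2")
        if not self.pixel_pitch_um > 0:
            raise ValidationError("pixel_pitch_um must be > 0")
        if self.grid_present and not self.grid_bar_um < self.grid_pitch_um:
            raise ValidationError("grid bars must be narrower than the grid pitch")
        if not (self.film.linear_lo < self.sound_attenuation <= self.film.linear_hi):
            raise ValidationError(
                "sound_attenuation must lie in (linear_lo, linear_hi]")
        if not (0.0 <= self.background_attenuation < self.sound_attenuation):
            raise ValidationError(
                "background_attenuation must lie in [0, sound_attenuation)")
        if self.jitter_frac < 0 or self.jitter_frac >= 1:
            raise ValidationError("jitter_frac must lie in [0, 1)")
        t = self.lesion
        width_um = cols * self.pixel_pitch_um
        deepest = (t.surface_position_um + t.erosion_um
                   + max(t.edge_width_um, t.demin_depth_um))
        if t.surface_position_um <= 0 or deepest >= width_um:
            raise ValidationError(
                f"lesion geometry (deepest feature at {deepest:.1f} um) does not "
                f"fit inside the {width_um:.1f} um wide image")

    @property
    def grid_phase(self) -> float:
        if self.grid_phase_um is not None:
            return self.grid_phase_um
        return self.lesion.surface_position_um - 40.0


GRID_ATTENUATION = 10.0  # metal: effectively opaque, far beyond film scale


def mineral_density_before(x, truth: LesionTruth):
    """Sound-tissue density fraction: a linear ramp 0 -> 1 across the edge.

    ``d_b(x) = clamp((x - s) / w, 0, 1)`` with s the surface position and w
    the edge width; x in micrometers, exterior -> interior.
    """
    x = np.asarray(x, dtype=float)
    return np.clip((x - truth.surface_position_um) / truth.edge_width_um, 0.0, 1.0)


def mineral_density_after(x, truth: LesionTruth):
    """Post-challenge density: eroded ramp times a demineralization deficit.

    ``d_a(x) = clamp((x-s-e)/w, 0, 1) * (1 - delta * clamp(1-(x-s-e)/L, 0, 1))``,
    the deficit factor being 1 when L = 0.  Pure erosion (delta = 0) is a
    rigid shift of the before curve; pure demineralization (e = 0)
    depresses density, recovering to sound at depth s + L.
    """
    x = np.asarray(x, dtype=float)
    t = truth
    u = np.clip((x - t.surface_position_um - t.erosion_um) / t.edge_width_um, 0.0, 1.0)
    if t.demin_depth_um == 0.0:
        return u
    deficit = np.clip(1.0 - (x - t.surface_position_um - t.erosion_um)
                      / t.demin_depth_um, 0.0, 1.0)
    return u * (1.0 - t.demin_severity * deficit)


def film_response(attenuation, film: FilmModel):
    """Expected (noise-free) grayscale for a given attenuation fraction.

    ``G(a) = intercept + slope * r(a)`` where r is the identity on
    ``[linear_lo, linear_hi]`` and saturates as ``bound -/+ c*tanh(|gap|/c)``
    outside, matching the linear part in value and first derivative at both
    boundaries.  Monotone non-decreasing and bounded everywhere.
    """
    a = np.asarray(attenuation, dtype=float)
    lo, hi, c = film.linear_lo, film.linear_hi, film.clip_softness
    if c == 0.0:
        r = np.clip(a, lo, hi)
    else:
        r = np.where(
            a < lo, lo - c * np.tanh((lo - a) / c),
            np.where(a > hi, hi + c * np.tanh((a - hi) / c), a),
        )
    return film.intercept + film.slope * r


def _grid_bar_mask(x_um: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    half = 0.5 * spec.grid_bar_um
    dist = np.abs(((x_um - spec.grid_phase + 0.5 * spec.grid_pitch_um)
                   % spec.grid_pitch_um) - 0.5 * spec.grid_pitch_um)
    return dist <= half


def _render(spec: PhantomSpec, density_fn, shift_px: int, film: FilmModel,
            rng: np.random.Generator) -> RadiographImage:
    rows, cols = spec.image_shape
    # scene coordinates shifted by whole pixels *before* scaling to um, so a
    # shifted exposure is bit-identical to the unshifted one translated by
    # shift_px columns (no float boundary ties)
    x = (np.arange(cols, dtype=float) - shift_px) * spec.pixel_pitch_um
    d = density_fn(x)
    atten = spec.background_attenuation + (
        spec.sound_attenuation - spec.background_attenuation) * d
    if spec.grid_present:
        atten = np.where(_grid_bar_mask(x, spec), GRID_ATTENUATION, atten)
    expected = film_response(atten, film)
    img = np.broadcast_to(expected, (rows, cols)).astype(float)
    if film.noise_sd > 0:
        img = img + rng.normal(0.0, film.noise_sd, size=(rows, cols))
    else:
        img = img.copy()
    max_val = (1 << spec.bit_depth) - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(img), 0, max_val).astype(dtype)
    return RadiographImage(pixels=pixels, bit_depth=spec.bit_depth,
                           pixel_pitch_um=spec.pixel_pitch_um)


def _jittered(film: FilmModel, frac: float, rng: np.random.Generator) -> FilmModel:
    if frac == 0.0:
        return film
    b = 1.0 + rng.uniform(-frac, frac)
    c = 1.0 + rng.uniform(-frac, frac)
    return replace(film, intercept=film.intercept * b, slope=film.slope * c)


def generate_tooth_pair(spec: PhantomSpec, seed: int
                        ) -> tuple[RadiographImage, RadiographImage, LesionTruth]:
    """Render a deterministic before/after radiograph pair.

    The before image carries the sound ramp; the after image carries the
    lesion plus an optional whole-scene integer shift
    (``spec.after_shift_px``, emulating film repositioning between
    exposures).  Brightness/contrast jitter, when enabled, is drawn
    independently per radiograph.  All randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    film_b = _jittered(spec.film, spec.jitter_frac, rng)
    film_a = _jittered(spec.film, spec.jitter_frac, rng)
    before = _render(spec, lambda x: mineral_density_before(x, spec.lesion),
                     0, film_b, rng)
    after = _render(spec, lambda x: mineral_density_after(x, spec.lesion),
                    spec.after_shift_px, film_a, rng)
    return before, after, spec.lesion


def generate_step_wedge_image(n_steps: int, step_attenuations, film: FilmModel,
                              shape: tuple[int, int], seed: int,
                              bit_depth: int = 12, roi_margin_px: int = 1
                              ) -> tuple[RadiographImage, list[ROI], np.ndarray]:
    """Render a step wedge as horizontal bands of increasing attenuation.

    Returns the image, one ROI per band (inset by ``roi_margin_px`` rows so
    neighbouring bands never touch), and the truth attenuations.
    """
    atten = np.asarray(step_attenuations, dtype=float)
    if n_steps < 3:
        raise ValidationError(f"a step wedge needs at least 3 steps, got {n_steps}")
    if atten.size != n_steps:
        raise ValidationError("step_attenuations length must equal n_steps")
    if not np.all(np.diff(atten) > 0):
        raise ValidationError("step attenuations must be strictly increasing")
    rows, cols = shape
    band = rows // n_steps
    if band < 2 * roi_margin_px + 1 or cols < 2:
        raise ValidationError(f"shape {shape} too small for {n_steps} bands")

    rng = np.random.default_rng(seed)
    expected = film_response(atten, film)
    img = np.empty((rows, cols), dtype=float)
    rois: list[ROI] = []
    for k in range(n_steps):
        r0, r1 = k * band, (k + 1) * band if k < n_steps - 1 else rows
        img[r0:r1, :] = expected[k]
        rois.append(ROI(r0 + roi_margin_px, r1 - roi_margin_px, 0, cols))
    if film.noise_sd > 0:
        img += rng.normal(0.0, film.noise_sd, size=img.shape)
    max_val = (1 << bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    pixels = np.clip(np.rint(img), 0, max_val).astype(dtype)
    return RadiographImage(pixels, bit_depth), rois, atten


# ---------------------------------------------------------------------------
# Analysis layout: where the measurement windows can safely sit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisLayout:
    """Pixel-index windows (half-open, before-image frame) for a phantom.

    ``background_window`` and ``sound_window`` anchor the 0 %/100 %
    normalization; ``surface_segment`` is the grid hole containing the
    surface edge and lesion, where crossings and fits are evaluated.  All
    three avoid the grid bars.
    """

    background_window: tuple[int, int]
    sound_window: tuple[int, int]
    surface_segment: tuple[int, int]


def _bar_intervals(spec: PhantomSpec, width_um: float) -> list[tuple[float, float]]:
    if not spec.grid_present:
        return []
    half = 0.5 * spec.grid_bar_um
    pitch = spec.grid_pitch_um
    k0 = int(np.floor((-half - spec.grid_phase) / pitch))
    out = []
    for k in range(k0, int(np.ceil(width_um / pitch)) + 1):
        c = spec.grid_phase + k * pitch
        if c + half > 0 and c - half < width_um:
            out.append((max(c - half, 0.0), min(c + half, width_um)))
    return out


def analysis_layout(spec: PhantomSpec, margin_um: float = 5.0,
                    max_window_um: float = 80.0) -> AnalysisLayout:
    """Derive safe normalization windows and the surface segment.

    Uses the known phantom geometry: the background window sits exterior of
    the first grid bar, the sound window in the first bar-free hole that is
    fully interior of every lesion feature, and the surface segment is the
    hole containing the surface edge.
    """
    t = spec.lesion
    pitch_px = spec.pixel_pitch_um
    width_um = spec.image_shape[1] * pitch_px
    bars = _bar_intervals(spec, width_um)

    holes: list[tuple[float, float]] = []
    prev = 0.0
    for b0, b1 in bars:
        if b0 - prev > 2 * margin_um:
            holes.append((prev, b0))
        prev = b1
    if width_um - prev > 2 * margin_um:
        holes.append((prev, width_um))

    surf_lo = t.surface_position_um
    deepest = (t.surface_position_um + t.erosion_um
               + max(t.edge_width_um, t.demin_depth_um))

    def to_px(lo: float, hi: float) -> tuple[int, int]:
        a = int(np.ceil(lo / pitch_px))
        b = int(np.floor(hi / pitch_px))
        if b - a < 4:
            raise ValidationError("analysis window narrower than 4 px")
        return a, b

    bg = next((h for h in holes if h[1] <= surf_lo - margin_um), None)
    if bg is None:
        raise ValidationError("no bar-free background region exterior of the surface")
    bg_hi = min(bg[1] - margin_um, surf_lo - margin_um)
    bg_lo = max(bg[0] + margin_um, bg_hi - max_window_um)

    seg = next((h for h in holes if h[0] <= surf_lo <= h[1]), None)
    if seg is None or seg[1] < deepest + margin_um:
        raise ValidationError(
            "surface edge and lesion do not fit inside a single grid hole; "
            "adjust grid_phase_um or the lesion geometry")
    seg_lo, seg_hi = seg[0] + 2.0, seg[1] - 2.0

    snd = next((h for h in holes if h[0] >= deepest + margin_um
                and h[1] - h[0] > 2 * margin_um + 10.0), None)
    if snd is None:
        raise ValidationError("no bar-free sound-enamel region interior of the lesion")
    snd_lo = snd[0] + 2 * margin_um
    snd_hi = min(snd[1] - 2 * margin_um, snd_lo + max_window_um)

    return AnalysisLayout(
        background_window=to_px(bg_lo, bg_hi),
        sound_window=to_px(snd_lo, snd_hi),
        surface_segment=to_px(seg_lo, seg_hi),
    )
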