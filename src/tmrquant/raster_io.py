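"""Reading and writing the image and tabular formats the pipeline touches.

Digitized microradiographs are single-channel grayscale TIFFs.  The capture
chain described in the method delivers 12-bit samples stored in a 16-bit
container, so the reader accepts an explicit bit-depth override and also
honours a small JSON block this package writes into the TIFF
ImageDescription tag (``{"bit_depth": ..., "pixel_pitch_um": ...}``).

Writes are always uncompressed, single-strip, little-endian baseline
grayscale; the reader additionally tolerates tiled or big-endian input.
Profile interchange uses a fixed CSV dialect: comma separator, ``.``
decimal, UTF-8, mandatory header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError, UnsupportedFormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = ["RadiographImage", "ROI", "read_image", "write_image",
           "export_profile_csv", "read_profile_csv"]

_ALLOWED_BIT_DEPTHS = (8, 12, 16)


@dataclass
class RadiographImage:
    """A digitized film: 2-D non-negative integer raster plus metadata.

    Attributes
    ----------
    pixels : 2-D integer array, rows x columns.
    bit_depth : one of 8, 12, 16.  12-bit data lives in a uint16 container
        with values 0..4095 (no scaling is ever applied).
    pixel_pitch_um : micrometers per pixel; ``None`` until spatially
        calibrated.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_pitch_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"raster must be 2-D, got {px.ndim}-D")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(f"raster must be at least 2x2, got {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError(f"raster must be integer-typed, got {px.dtype}")
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ValidationError(
                f"bit_depth must be one of {_ALLOWED_BIT_DEPTHS}, got {self.bit_depth}")
        if px.size and int(px.min()) < 0:
            raise ValidationError("raster contains negative pixel values")
        if px.size and int(px.max()) > self.max_value:
            raise ValidationError(
                f"pixel value {int(px.max())} exceeds 2^{self.bit_depth}-1")
        if self.pixel_pitch_um is not None and not self.pixel_pitch_um > 0:
            raise ValidationError("pixel_pitch_um must be positive when present")
        self.pixels = px

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROI:
    """Rectangular region, 0-based half-open [start, end) on both axes."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValidationError(f"ROI must satisfy start < end on both axes: {self}")
        if min(self.row_start, self.col_start) < 0:
            raise ValidationError(f"ROI indices must be non-negative: {self}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_end), slice(self.col_start, self.col_end)

    @property
    def n_pixels(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.row_end > shape[0] or self.col_end > shape[1]:
            raise ValidationError(f"ROI {self} exceeds raster shape {shape}")

    def overlaps(self, other: "ROI") -> bool:
        rows = self.row_start < other.row_end and other.row_start < self.row_end
        cols = self.col_start < other.col_end and other.col_start < self.col_end
        return rows and cols


def _container_dtype(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8) if bit_depth == 8 else np.dtype(np.uint16)


def write_image(image: RadiographImage, path) -> None:
    """Write an uncompressed single-strip baseline grayscale TIFF.

    Bit depth and pixel pitch are recorded as JSON in the ImageDescription
    tag so that a later :func:`read_image` round-trips the metadata.
    """
    if not isinstance(image, RadiographImage):
        image = RadiographImage(**image) if isinstance(image, dict) else image
    # __post_init__ re-validates in case pixels were mutated after construction
    RadiographImage(image.pixels, image.bit_depth, image.pixel_pitch_um)
    meta = {"bit_depth": image.bit_depth}
    if image.pixel_pitch_um is not None:
        meta["pixel_pitch_um"] = image.pixel_pitch_um
    data = image.pixels.astype(_container_dtype(image.bit_depth))
    tifffile.imwrite(
        path, data,
        photometric="minisblack",
        compression=None,
        rowsperstrip=data.shape[0],  # single strip
        byteorder="<",
        description=json.dumps(meta),
    )


def read_image(path, bit_depth: int | None = None) -> RadiographImage:
    """Read a single-channel grayscale TIFF.

    ``bit_depth`` overrides autodetection.  Without an override, a JSON
    ImageDescription written by :func:`write_image` is honoured; otherwise
    the sample dtype decides (uint8 -> 8, uint16 -> 16).  The 12-in-16-bit
    case is only declared when the metadata/override says 12 *and* the data
    actually fit in 12 bits.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise UnsupportedFormatError(
                f"expected single-channel grayscale, got samplesperpixel="
                f"{page.samplesperpixel}")
        data = page.asarray()
        if data.ndim != 2:
            raise UnsupportedFormatError(
                f"expected a 2-D grayscale raster, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise UnsupportedFormatError(
                f"expected integer samples, got float sample type {data.dtype}")
        meta: dict = {}
        desc = page.description
        if desc:
            try:
                parsed = json.loads(desc)
                if isinstance(parsed, dict):
                    meta = parsed
            except (json.JSONDecodeError, TypeError):
                pass

    bd = bit_depth if bit_depth is not None else meta.get("bit_depth")
    if bd is None:
        bd = 8 if data.dtype.itemsize == 1 else 16
    bd = int(bd)
    if bd == 12 and data.size and int(data.max()) > 4095:
        raise UnsupportedFormatError(
            f"declared 12-bit but max pixel value {int(data.max())} exceeds 4095")
    pitch = meta.get("pixel_pitch_um")
    return RadiographImage(pixels=data, bit_depth=bd,
                           pixel_pitch_um=float(pitch) if pitch else None)


def export_profile_csv(profile, path) -> None:
    """Write a density profile as CSV: position_px, [position_um,] value.

    ``position_um`` is emitted only when the profile carries a spatial
    calibration.
    """
    if len(profile.values) == 0:
        raise ValidationError("cannot export an empty profile")
    cols: dict[str, np.ndarray] = {"position_px": profile.positions_px}
    if profile.calibration is not None:
        cols["position_um"] = profile.positions_um
    cols["value"] = np.asarray(profile.values, dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False, encoding="utf-8")


def read_profile_csv(path):
    """Read a profile CSV written by :func:`export_profile_csv`.

    Unknown extra columns are ignored with a logged warning.  Missing
    required columns raise :class:`SchemaError` listing their names.
    """
    from .profiles import DensityProfile
    from .calibration import SpatialCalibration

    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty or headerless CSV: {path}") from exc
    required = {"position_px", "value"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"profile CSV missing required columns: {missing}")
    known = {"position_px", "position_um", "value"}
    extra = sorted(set(df.columns) - known)
    if extra:
        log.warning("profile CSV %s has unknown columns %s; ignoring", path, extra)
    if len(df) == 0:
        raise SchemaError(f"profile CSV has no data rows: {path}")

    pos = df["position_px"].to_numpy(dtype=float)
    origin = int(round(pos[0]))
    calibration = None
    if "position_um" in df.columns and len(df) >= 2 and pos[1] != pos[0]:
        um = df["position_um"].to_numpy(dtype=float)
        pitch = (um[1] - um[0]) / (pos[1] - pos[0])
        if pitch > 0:
            calibration = SpatialCalibration(um_per_pixel=pitch, source=f"csv:{path}")
    return DensityProfile(values=df["value"].to_numpy(dtype=float),
                          origin_index=origin, calibration=calibration)
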