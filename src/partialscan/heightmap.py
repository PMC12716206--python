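"""Single-channel height-map container and plain-raster I/O.

SICM topography frames are 2D grids of surface heights acquired line by
line: row index is the slow-scan (Y) axis, 0-based with the first scanned
line on top; column index is the fast (X) axis.  Heights are physical
(default micrometres) until :func:`normalize` rescales them to [0, 1] for
model consumption, recording the (min, max) span so :func:`denormalize`
can restore physical units.

Supported exchange formats are deliberately plain: 32/64-bit float
single-channel TIFF (archival), CSV matrices, and 16-bit grayscale PNG
(visualization-grade, quantized).  Binary line masks travel as 8-bit PNG
(255 = scanned, 0 = skipped) or CSV of 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ChannelError, FormatError, StateError, ValidationError

__all__ = [
    "HeightMap",
    "MaskRaster",
    "read_heightmap",
    "write_heightmap",
    "read_mask_raster",
    "write_mask_raster",
    "normalize",
    "denormalize",
]

RAW = "raw"
UNIT_NORMALIZED = "unit_normalized"


def _validate_grid(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValidationError(f"height map must be 2D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError(f"degenerate image shape {arr.shape}")
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = np.argwhere(bad)[:10]
        raise ValidationError(
            f"non-finite pixels at indices {[tuple(i) for i in idx]}"
            + ("..." if bad.sum() > 10 else "")
        )
    return arr.astype(np.float64, copy=True)


@dataclass
class HeightMap:
    """2D topography grid plus normalization metadata.

    Parameters
    ----------
    values:
        Rectangular, finite 2D array; row 0 = first scanned line.
    pixel_size:
        Physical length per pixel (µm), metadata only.
    norm_state:
        ``"raw"`` (physical units) or ``"unit_normalized"`` ([0, 1]).
    norm_params:
        (min_height, max_height) recorded when the map was normalized.
    """

    values: np.ndarray
    pixel_size: float | None = None
    unit: str = "um"
    norm_state: str = RAW
    norm_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = _validate_grid(self.values)
        if self.norm_state not in (RAW, UNIT_NORMALIZED):
            raise ValidationError(f"unknown norm_state {self.norm_state!r}")
        if self.norm_state == UNIT_NORMALIZED:
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValidationError("normalized map has values outside [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def max_i(self) -> float:
        """Maximum possible pixel value (1 when unit-normalized)."""
        return 1.0 if self.norm_state == UNIT_NORMALIZED else float(self.values.max())

    def copy(self) -> "HeightMap":
        return replace(self, values=self.values.copy())


@dataclass
class MaskRaster:
    """2D binary raster companion of a HeightMap (1 = scanned, 0 = skipped)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValidationError(f"mask raster must be 2D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask raster must be binary, found values {uniq[:5]}")
        self.values = arr.astype(np.float64, copy=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


_EXT_FORMAT = {".tif": "tiff", ".tiff": "tiff", ".csv": "csv", ".png": "png16"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tiff", "csv", "png16"):
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise FormatError(f"cannot infer format from extension {path.suffix!r}") from None


def read_heightmap(path: str | Path, format: str | None = None) -> HeightMap:
    """Load a single-channel raster as a raw-state HeightMap.

    Raises :class:`FormatError` for undecodable files, :class:`ChannelError`
    for multi-channel input and :class:`ValidationError` for non-finite pixels.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if fmt == "tiff":
            arr = tifffile.imread(path)
        elif fmt == "csv":
            arr = np.loadtxt(path, delimiter=",", ndmin=2)
        else:  # png16
            arr = np.asarray(iio.imread(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"could not decode {path} as {fmt}: {exc}") from exc
    if arr.ndim == 3:
        raise ChannelError(
            f"{path} has {arr.shape[-1]} channels; single-channel raster required"
        )
    if fmt == "png16":
        arr = arr.astype(np.float64) / 65535.0
    return HeightMap(values=arr)


def write_heightmap(h: HeightMap, path: str | Path, format: str | None = None) -> Path:
    """Write a HeightMap; tiff/csv round-trip exactly, png16 quantizes to 16 bits.

    png16 export requires a unit-normalized map (values scaled by 65535).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "tiff":
            tifffile.imwrite(path, h.values)
        elif fmt == "csv":
            np.savetxt(path, h.values, delimiter=",", fmt="%.17g")
        else:
            if h.norm_state != UNIT_NORMALIZED:
                raise StateError("png16 export requires a unit-normalized map")
            q = np.rint(np.clip(h.values, 0, 1) * 65535.0).astype(np.uint16)
            iio.imwrite(path, q)
    except OSError as exc:
        raise FormatError(f"could not write {path}: {exc}") from exc
    return path


def read_mask_raster(path: str | Path) -> MaskRaster:
    """Load a binary mask (8-bit PNG with 255 = scanned, or CSV of 0/1)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise ChannelError(f"{path}: mask must be single-channel")
        arr = (arr > 127).astype(np.float64)
    return MaskRaster(values=arr)


def write_mask_raster(m: MaskRaster, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, m.values.astype(int), delimiter=",", fmt="%d")
    else:
        iio.imwrite(path, (m.values * 255).astype(np.uint8))
    return path


def normalize(h: HeightMap) -> HeightMap:
    """Min-max rescale a raw map to [0, 1], recording (min, max).

    A constant image maps to all-zeros with a recorded unit span
    (min, min + 1) so that denormalization stays well defined.
    """
    if h.norm_state != RAW:
        raise StateError("map is already normalized")
    lo = float(h.values.min())
    hi = float(h.values.max())
    if hi > lo:
        scaled = (h.values - lo) / (hi - lo)
        params = (lo, hi)
    else:
        scaled = np.zeros_like(h.values)
        params = (lo, lo + 1.0)
    return HeightMap(
        values=scaled,
        pixel_size=h.pixel_size,
        unit=h.unit,
        norm_state=UNIT_NORMALIZED,
        norm_params=params,
    )


def denormalize(h: HeightMap) -> HeightMap:
    """Invert :func:`normalize` using the recorded (min, max) span."""
    if h.norm_state != UNIT_NORMALIZED or h.norm_params is None:
        raise StateError("map is not in the unit-normalized state")
    lo, hi = h.norm_params
    return HeightMap(
        values=h.values * (hi - lo) + lo,
        pixel_size=h.pixel_size,
        unit=h.unit,
        norm_state=RAW,
        norm_params=None,
    )
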