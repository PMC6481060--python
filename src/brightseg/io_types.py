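"""Core raster types, pixel calibration, and image readers/writers.

The pipeline works on single-channel rasters.  :class:`Image` carries the
pixel array together with its bit depth (8 or 16) and an optional physical
pixel size; :class:`BinaryMask` carries boolean rasters (edge maps and
segmentation results).  Readers accept grayscale or RGB TIFF/PNG; masks are
written 0/255 in the ImageJ binary convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "PixelCalibration",
    "Image",
    "BinaryMask",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "to_8bit",
]

# ITU-R 601 luminance weights for RGB -> grayscale conversion.
_LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel size in nm/pixel; must be strictly positive."""

    nm_per_pixel: float

    def __post_init__(self) -> None:
        if not self.nm_per_pixel > 0:
            raise ValueError(f"nm_per_pixel must be > 0, got {self.nm_per_pixel}")

    @property
    def um_per_pixel(self) -> float:
        return self.nm_per_pixel / 1000.0


@dataclass(frozen=True)
class Image:
    """A 2-D grayscale raster with a declared bit depth.

    Invariants: pixels are non-negative, bounded by ``2**bit_depth - 1``,
    and the raster has at least one row and column.
    """

    pixels: np.ndarray
    bit_depth: int
    calibration: Optional[PixelCalibration] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise ValueError(
                f"pixel values outside [0, {2**self.bit_depth - 1}] for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean raster, same shape contract as the image it derives from."""

    pixels: np.ndarray
    calibration: Optional[PixelCalibration] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


def _rgb_to_luminance(arr: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance, rounded to the nearest integer."""
    r, g, b = (arr[..., i].astype(np.float64) for i in range(3))
    w_r, w_g, w_b = _LUMA_WEIGHTS
    luma = w_r * r + w_g * g + w_b * b
    return np.rint(luma).astype(np.int64)


def read_image(path, calibration: Optional[PixelCalibration] = None) -> Image:
    """Read a TIFF or PNG image as a grayscale :class:`Image`.

    RGB(A) inputs are converted to luminance with ITU-R 601 weights
    (0.299/0.587/0.114), rounded to integer; bit depth is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - reraise with the path attached
        raise IOError(f"could not read image {path}: {exc}") from exc

    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
        bit_depth = 8
    else:
        raise ValueError(
            f"unsupported sample format {arr.dtype} in {path}: expected 8- or 16-bit integer"
        )

    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[-1] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[-1]} in {path}")
        arr = _rgb_to_luminance(arr)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")

    return Image(pixels=np.asarray(arr, dtype=np.int64), bit_depth=bit_depth, calibration=calibration)


def write_image(img: Image, path) -> None:
    """Write an :class:`Image` as single-channel TIFF or PNG at its bit depth."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = img.pixels.astype(dtype)
    _write_array(arr, path)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as an 8-bit image, foreground=255 / background=0."""
    path = Path(path)
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    _write_array(arr, path)


def _write_array(arr: np.ndarray, path: Path) -> None:
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, arr)
        else:
            iio.imwrite(path, arr)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write image {path}: {exc}") from exc


def read_mask(path, threshold: int = 128) -> BinaryMask:
    """Read a mask image; pixels >= ``threshold`` are foreground."""
    img = read_image(path)
    return BinaryMask(pixels=img.pixels >= threshold, calibration=img.calibration)


def to_8bit(img: Image) -> Image:
    """Convert to 8 bit using min-max display-range scaling.

    8-bit input is returned unchanged.  A constant 16-bit image (degenerate
    display range) maps to 0.  The mapping is monotone in pixel intensity.
    """
    if img.bit_depth == 8:
        return img
    px = img.pixels
    lo, hi = int(px.min()), int(px.max())
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = np.rint((px - lo) * (255.0 / (hi - lo))).astype(np.int64)
    return Image(pixels=out, bit_depth=8, calibration=img.calibration)
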