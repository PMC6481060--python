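"""Maximum filter with circular-radius kernels and count-based binary morphology.

The binary operations reproduce the ImageJ "Binary Options" semantics: one
erosion pass removes a foreground pixel iff at least ``count`` of its eight
neighbours are background; one dilation pass adds a background pixel iff at
least ``count`` of its eight neighbours are foreground.  ``pad`` controls
how out-of-image neighbours are treated during erosion (foreground when
true, protecting the image border, as the "pad" macro option does);
dilation always treats out-of-image neighbours as background.

All binary operations accept boolean arrays with optional leading batch
axes (shape ``(..., H, W)``) as well as :class:`~brightseg.io_types.BinaryMask`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_types import BinaryMask, Image

__all__ = [
    "MorphOptions",
    "CircularKernel",
    "make_circular_kernel",
    "maximum_filter",
    "count_erode",
    "count_dilate",
    "binary_close",
    "binary_open",
]


@dataclass(frozen=True)
class MorphOptions:
    """iterations: repeat count >= 1; count: neighbour threshold in 1..8;
    pad: treat out-of-image neighbours as foreground during erosion."""

    iterations: int = 1
    count: int = 3
    pad: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if not 1 <= self.count <= 8:
            raise ValueError(f"count must be in 1..8, got {self.count}")


@dataclass(frozen=True)
class CircularKernel:
    """Circular neighbourhood: all integer offsets with dy^2+dx^2 <= radius^2+1."""

    radius: float
    offsets: frozenset[tuple[int, int]]

    @property
    def footprint(self) -> np.ndarray:
        """Boolean footprint array centred on (0, 0)."""
        r = max(max(abs(dy), abs(dx)) for dy, dx in self.offsets)
        fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        for dy, dx in self.offsets:
            fp[dy + r, dx + r] = True
        return fp


def make_circular_kernel(radius: float) -> CircularKernel:
    """Enumerate the offsets of the circular rank-filter kernel.

    Inclusion rule: ``dy**2 + dx**2 <= radius**2 + 1``, which reproduces the
    reference kernels for the fractional radii the resolution table uses
    (1.25, 1.67, 2.5).  The kernel always contains the origin and is
    symmetric under negation.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    limit = radius * radius + 1.0
    span = int(np.floor(np.sqrt(limit)))
    offsets = {
        (dy, dx)
        for dy in range(-span, span + 1)
        for dx in range(-span, span + 1)
        if dy * dy + dx * dx <= limit
    }
    return CircularKernel(radius=radius, offsets=frozenset(offsets))


def maximum_filter(img: Image | np.ndarray, radius: float) -> Image | np.ndarray:
    """Replace each pixel by the maximum over the circular kernel.

    Out-of-image positions are ignored (the window shrinks at borders);
    because pixel values are non-negative this equals a zero-padded rank
    filter.  On a 0/255 edge raster this acts as a dilation by the kernel.
    """
    kernel = make_circular_kernel(radius)
    if isinstance(img, Image):
        out = ndimage.maximum_filter(img.pixels, footprint=kernel.footprint, mode="constant", cval=0)
        return Image(pixels=out, bit_depth=img.bit_depth, calibration=img.calibration)
    arr = np.asarray(img)
    if arr.dtype == bool:
        return ndimage.maximum_filter(arr.astype(np.uint8), footprint=kernel.footprint, mode="constant", cval=0).astype(bool)
    return ndimage.maximum_filter(arr, footprint=kernel.footprint, mode="constant", cval=0)


def _neighbor_count(fg: np.ndarray, pad_value: bool) -> np.ndarray:
    """Number of true 8-neighbours of each pixel, batched over leading axes."""
    pad_width = [(0, 0)] * (fg.ndim - 2) + [(1, 1), (1, 1)]
    padded = np.pad(fg, pad_width, mode="constant", constant_values=pad_value)
    count = np.zeros(fg.shape, dtype=np.int8)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            count += padded[..., 1 + dy : padded.shape[-2] - 1 + dy, 1 + dx : padded.shape[-1] - 1 + dx]
    return count


def _erode_once(mask: np.ndarray, count: int, pad: bool) -> np.ndarray:
    # out-of-image neighbours are foreground when pad=True, so they never
    # contribute to the background count that triggers removal
    bg_neighbors = 8 - _neighbor_count(mask, pad_value=pad)
    return mask & ~(bg_neighbors >= count)


def _dilate_once(mask: np.ndarray, count: int) -> np.ndarray:
    fg_neighbors = _neighbor_count(mask, pad_value=False)
    return mask | (fg_neighbors >= count)


def _as_bool_array(mask: BinaryMask | np.ndarray) -> tuple[np.ndarray, BinaryMask | None]:
    if isinstance(mask, BinaryMask):
        return mask.pixels, mask
    return np.asarray(mask, dtype=bool), None


def _wrap(result: np.ndarray, template: BinaryMask | None):
    if template is not None:
        return BinaryMask(pixels=result, calibration=template.calibration)
    return result


def count_erode(mask: BinaryMask | np.ndarray, opts: MorphOptions):
    """Iterated count-based erosion (see module docstring for semantics)."""
    arr, template = _as_bool_array(mask)
    for _ in range(opts.iterations):
        arr = _erode_once(arr, opts.count, opts.pad)
    return _wrap(arr, template)


def count_dilate(mask: BinaryMask | np.ndarray, opts: MorphOptions):
    """Iterated count-based dilation; out-of-image neighbours are background."""
    arr, template = _as_bool_array(mask)
    for _ in range(opts.iterations):
        arr = _dilate_once(arr, opts.count)
    return _wrap(arr, template)


def binary_close(mask: BinaryMask | np.ndarray, opts: MorphOptions):
    """Dilate ``iterations`` times then erode ``iterations`` times (fills holes)."""
    arr, template = _as_bool_array(mask)
    for _ in range(opts.iterations):
        arr = _dilate_once(arr, opts.count)
    for _ in range(opts.iterations):
        arr = _erode_once(arr, opts.count, opts.pad)
    return _wrap(arr, template)


def binary_open(mask: BinaryMask | np.ndarray, opts: MorphOptions):
    """Erode ``iterations`` times then dilate ``iterations`` times (removes specks)."""
    arr, template = _as_bool_array(mask)
    for _ in range(opts.iterations):
        arr = _erode_once(arr, opts.count, opts.pad)
    for _ in range(opts.iterations):
        arr = _dilate_once(arr, opts.count)
    return _wrap(arr, template)
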