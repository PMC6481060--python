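"""Canny edge detection with the plugin semantics the pipeline expects.

Stages: Gaussian-derivative gradient estimation (separable, kernel
half-width ceil(4*sigma), truncated tails renormalized, replicated borders),
non-maximum suppression with linear interpolation along the gradient
direction, and dual-threshold hysteresis with 8-connected linking.

The low/high thresholds are compared against the gradient magnitude scaled
by :data:`MAGNITUDE_SCALE`, a frozen calibration constant chosen so that the
conventional defaults (low 0.1, high 8.0) discriminate textured cell
interiors from smooth background on 8-bit input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_types import BinaryMask, Image

__all__ = [
    "MAGNITUDE_SCALE",
    "CannyParams",
    "gaussian_gradient",
    "non_maximum_suppression",
    "hysteresis",
    "canny",
]

# Thresholds are quoted in scaled gradient units: raw 8-bit gradient
# magnitude times this constant. Frozen; exposed for sensitivity analysis.
MAGNITUDE_SCALE = 100.0 / 255.0


@dataclass(frozen=True)
class CannyParams:
    """Gaussian smoothing scale (sigma, px) and hysteresis thresholds."""

    gaussian_kernel_radius: float = 1.75
    low_threshold: float = 0.1
    high_threshold: float = 8.0

    def __post_init__(self) -> None:
        if not self.gaussian_kernel_radius > 0:
            raise ValueError("gaussian_kernel_radius must be > 0")
        if not (0 < self.low_threshold <= self.high_threshold):
            raise ValueError(
                f"need 0 < low <= high, got low={self.low_threshold}, high={self.high_threshold}"
            )


def _gaussian_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Truncated Gaussian and its first derivative, half-width ceil(4*sigma).

    The smoothing kernel is renormalized to unit sum after truncation; the
    derivative kernel is -x/sigma^2 times the renormalized Gaussian, so a
    unit-slope ramp yields unit response up to truncation error.
    """
    half = int(math.ceil(4.0 * sigma))
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    dg = -(x / sigma**2) * g
    return g, dg


def gaussian_gradient(img: Image | np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient of the Gaussian-smoothed image.

    Returns ``(gx, gy, magnitude)`` where ``gx`` is the derivative along
    columns (x) and ``gy`` along rows (y).  Borders are edge-replicated.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    arr = np.asarray(img.pixels if isinstance(img, Image) else img, dtype=np.float64)
    g, dg = _gaussian_kernels(radius)
    # correlate1d with a symmetric g equals convolution; dg is antisymmetric,
    # so flip it to get true convolution semantics for the derivative.
    gx = ndimage.correlate1d(arr, dg[::-1], axis=1, mode="nearest")
    gx = ndimage.correlate1d(gx, g, axis=0, mode="nearest")
    gy = ndimage.correlate1d(arr, dg[::-1], axis=0, mode="nearest")
    gy = ndimage.correlate1d(gy, g, axis=1, mode="nearest")
    magnitude = np.hypot(gx, gy)
    return gx, gy, magnitude


def non_maximum_suppression(gx: np.ndarray, gy: np.ndarray, magnitude: np.ndarray) -> np.ndarray:
    """Thin the gradient magnitude to local ridges.

    A pixel survives iff its magnitude is strictly greater than the
    neighbour interpolated one pixel forward along the gradient direction
    and >= the backward neighbour.  The asymmetric tie-break resolves the
    exact two-pixel tie an ideal intensity step produces (keeping the
    bright-side pixel) so ideal edges thin to single-pixel curves, while an
    isolated maximum is always kept.  Suppressed pixels are zeroed;
    out-of-image samples count as zero magnitude.
    """
    gx = np.asarray(gx, dtype=np.float64)
    gy = np.asarray(gy, dtype=np.float64)
    mag = np.asarray(magnitude, dtype=np.float64)
    if not (gx.shape == gy.shape == mag.shape):
        raise ValueError("gx, gy and magnitude must share one shape")

    h, w = mag.shape
    padded = np.zeros((h + 2, w + 2), dtype=np.float64)
    padded[1:-1, 1:-1] = mag

    rows, cols = np.indices((h, w))
    rows = rows + 1  # indices into the padded array
    cols = cols + 1

    ax = np.abs(gx)
    ay = np.abs(gy)
    sx = np.where(gx >= 0, 1, -1)
    sy = np.where(gy >= 0, 1, -1)

    # Interpolation weight toward the minor axis; safe where both are 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        w_x = np.where(ax > 0, ay / ax, 0.0)  # used when |gx| >= |gy|
        w_y = np.where(ay > 0, ax / ay, 0.0)  # used when |gy| >  |gx|

    horiz = ax >= ay

    # Major step along x, minor along y.
    m1_h = (1 - w_x) * padded[rows, cols + sx] + w_x * padded[rows + sy, cols + sx]
    m2_h = (1 - w_x) * padded[rows, cols - sx] + w_x * padded[rows - sy, cols - sx]
    # Major step along y, minor along x.
    m1_v = (1 - w_y) * padded[rows + sy, cols] + w_y * padded[rows + sy, cols + sx]
    m2_v = (1 - w_y) * padded[rows - sy, cols] + w_y * padded[rows - sy, cols - sx]

    m1 = np.where(horiz, m1_h, m1_v)
    m2 = np.where(horiz, m2_h, m2_v)

    keep = (mag > m1) & (mag >= m2) & (mag > 0)
    return np.where(keep, mag, 0.0)


def hysteresis(thinned: np.ndarray, low: float, high: float) -> BinaryMask:
    """Dual-threshold linking: seeds are pixels >= high; pixels >= low that
    are 8-connected (transitively) to a seed are included."""
    if low > high:
        raise ValueError(f"low ({low}) must be <= high ({high})")
    arr = np.asarray(thinned, dtype=np.float64)
    weak = arr >= low
    strong = arr >= high
    if not strong.any():
        return BinaryMask(pixels=np.zeros_like(weak))
    structure = np.ones((3, 3), dtype=bool)
    labels, _ = ndimage.label(weak, structure=structure)
    seed_labels = np.unique(labels[strong])
    seed_labels = seed_labels[seed_labels != 0]
    mask = np.isin(labels, seed_labels)
    return BinaryMask(pixels=mask)


def canny(img: Image, params: CannyParams) -> BinaryMask:
    """Full detector: gradient -> non-maximum suppression -> hysteresis.

    Thresholds apply to the NMS magnitude scaled by :data:`MAGNITUDE_SCALE`.
    """
    if img.bit_depth != 8:
        raise ValueError(f"canny expects an 8-bit image, got {img.bit_depth}-bit")
    gx, gy, mag = gaussian_gradient(img, params.gaussian_kernel_radius)
    thin = non_maximum_suppression(gx, gy, mag)
    scaled = thin * MAGNITUDE_SCALE
    mask = hysteresis(scaled, params.low_threshold, params.high_threshold)
    return BinaryMask(pixels=mask.pixels, calibration=img.calibration)
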