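"""Histogram equalization for 8-bit brightfield images.

ImageJ's "Enhance Contrast... equalize" is the model: by default the
histogram counts are replaced by their square roots before the cumulative
mapping is built, which tempers the influence of dominant background bins;
the classic textbook CDF equalization is available via ``classic=True``.
The ``saturated`` option of the dialog is accepted for macro fidelity but,
as in the original, has no effect on the equalize path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_types import Image

__all__ = ["EqualizeOptions", "equalize_histogram", "equalization_lut"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EqualizeOptions:
    """Options for :func:`equalize_histogram`.

    saturated_percent: fraction of pixels allowed to saturate, in [0, 100].
        Accepted and logged for traceability of the macro line, but ignored
        by the equalize mapping itself (matching the reference behaviour).
    classic: use raw histogram counts instead of their square roots.
    """

    saturated_percent: float = 0.0
    classic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturated_percent <= 100.0:
            raise ValueError(f"saturated_percent must be in [0, 100], got {self.saturated_percent}")


def equalization_lut(histogram: np.ndarray, classic: bool = False) -> np.ndarray:
    """Build the 256-entry equalization lookup table from an 8-bit histogram.

    Weighted counts (square roots unless ``classic``) are accumulated
    inclusively and scaled so the full cumulative sum maps to 255; each
    entry is the floor of the scaled cumulative sum.  The mapping is
    non-decreasing by construction.  A histogram with a single occupied bin
    yields the identity table (nothing to equalize).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {hist.shape}")
    if np.count_nonzero(hist) <= 1:
        return np.arange(256, dtype=np.int64)
    weighted = hist if classic else np.sqrt(hist)
    cum = np.cumsum(weighted)
    total = cum[-1]
    lut = np.floor(cum * (255.0 / total)).astype(np.int64)
    return np.clip(lut, 0, 255)


def equalize_histogram(img: Image, opts: EqualizeOptions | None = None) -> Image:
    """Equalize the histogram of an 8-bit image.

    The output is 8 bit; the intensity mapping is a non-decreasing function
    of the input intensity, so pixel ordering is preserved.
    """
    if img.bit_depth != 8:
        raise ValueError(f"equalize_histogram requires an 8-bit image, got {img.bit_depth}-bit")
    opts = opts or EqualizeOptions()
    if opts.saturated_percent != 0.0:
        logger.info(
            "saturated_percent=%s accepted but has no effect on equalization",
            opts.saturated_percent,
        )
    hist = np.bincount(img.pixels.ravel().astype(np.int64), minlength=256)[:256]
    lut = equalization_lut(hist, classic=opts.classic)
    return Image(pixels=lut[img.pixels], bit_depth=8, calibration=img.calibration)
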