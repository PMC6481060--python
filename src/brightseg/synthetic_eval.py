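"""Synthetic brightfield scenes with ground truth, and segmentation metrics.

The generator emulates what a transmitted-light channel of adherent cells
looks like to an edge-based segmenter: elliptical cell bodies whose
interiors carry high-frequency texture (organelles, membrane ruffling) and
whose borders are darker than the surround, sitting on a smoothly varying,
mildly noisy background, optionally with small high-contrast debris blobs
that do not belong to the ground truth.

Randomness comes from numpy's PCG64 generator (``numpy.random.default_rng``)
with explicit seeding; scenes are bit-reproducible across platforms for a
fixed (params, seed).  Cell placement, debris placement and pixel noise use
independent seed-derived streams, so increasing ``n_debris`` leaves the
cells and noise of a given seed unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_types import BinaryMask, Image, PixelCalibration

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "EvaluationRecord",
    "generate_scene",
    "dice",
    "iou",
    "area_difference_percent",
    "evaluate_batch",
    "evaluate_pair",
]

# Rim thickness of the cell border, in units of the ellipse's normalized
# radius (the rim occupies normalized radii in [1 - RIM_FRACTION, 1]).
_RIM_FRACTION = 0.12
_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters; defaults emulate a high-magnification field.

    All intensities are 8-bit counts; radii are pixels.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 5
    cell_radius_range: tuple[float, float] = (40.0, 80.0)
    interior_texture_amp: float = 45.0
    texture_scale_px: float = 2.0
    border_contrast: float = 60.0
    background_level: float = 150.0
    background_noise_sd: float = 2.0
    illumination_gradient_amp: float = 10.0
    n_debris: int = 3
    debris_radius_range: tuple[float, float] = (2.0, 5.0)
    nm_per_pixel: float = 110.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("frame must be at least 1x1")
        if self.n_cells < 0 or self.n_debris < 0:
            raise ValueError("counts must be non-negative")
        for name in ("interior_texture_amp", "texture_scale_px", "border_contrast",
                     "background_noise_sd", "illumination_gradient_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cell_radius_range", "debris_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class SyntheticScene:
    image: Image
    truth: BinaryMask
    params: SceneParams
    seed: int


@dataclass(frozen=True)
class EvaluationRecord:
    """Per-image agreement between an automated and a reference mask."""

    dice: float
    iou: float
    area_diff_percent: float


def _place_ellipses(rng: np.random.Generator, params: SceneParams):
    """Sample non-crowded ellipse (cy, cx, a, b, theta) tuples.

    Centres keep at least 60% of the combined major radii apart, so cells
    stay mostly separate while still allowed to touch; raises if the frame
    cannot host ``n_cells`` after bounded retries.
    """
    lo, hi = params.cell_radius_range
    placed: list[tuple[float, float, float, float, float]] = []
    for _ in range(params.n_cells):
        ok = False
        for _attempt in range(_PLACEMENT_RETRIES):
            a = rng.uniform(lo, hi)
            b = rng.uniform(0.6 * a, a)
            theta = rng.uniform(0.0, math.pi)
            r = max(a, b)
            if 2 * r >= min(params.width, params.height):
                continue
            cy = rng.uniform(r, params.height - r)
            cx = rng.uniform(r, params.width - r)
            if all(
                math.hypot(cy - py, cx - px) >= 0.6 * (r + max(pa, pb))
                for py, px, pa, pb, _t in placed
            ):
                ok = True
                placed.append((cy, cx, a, b, theta))
                break
        if not ok:
            raise RuntimeError(
                f"could not place {params.n_cells} cells of radius {lo}-{hi} px "
                f"in a {params.width}x{params.height} frame after {_PLACEMENT_RETRIES} retries"
            )
    return placed


def _correlated_texture(rng: np.random.Generator, shape, params: SceneParams) -> np.ndarray:
    """Intracellular texture: Gaussian noise smoothed to the organelle scale.

    White noise is low-pass filtered at ``texture_scale_px`` (about 0.5 um
    granule size at high magnification) and rescaled so its standard
    deviation is half of ``interior_texture_amp``; values therefore stay
    mostly within +/- the amplitude, as in the uncorrelated limit.
    """
    from scipy import ndimage as _ndi

    noise = rng.standard_normal(shape)
    if params.texture_scale_px > 0:
        noise = _ndi.gaussian_filter(noise, params.texture_scale_px, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise * (params.interior_texture_amp / 2.0)


def _ellipse_norm_radius(shape, cy, cx, a, b, theta) -> np.ndarray:
    """Normalized elliptical radius (<=1 inside the ellipse) for every pixel."""
    yy, xx = np.indices(shape, dtype=np.float64)
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def generate_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Render one scene; deterministic for a fixed (params, seed)."""
    rng_cells = np.random.default_rng([seed, 0])
    rng_debris = np.random.default_rng([seed, 1])
    rng_noise = np.random.default_rng([seed, 2])
    shape = (params.height, params.width)

    yy, xx = np.indices(shape, dtype=np.float64)
    denom = max(params.width + params.height - 2, 1)
    gradient = params.illumination_gradient_amp * (yy + xx) / denom
    canvas = params.background_level + gradient
    if params.background_noise_sd > 0:
        canvas = canvas + rng_noise.normal(0.0, params.background_noise_sd, shape)

    truth = np.zeros(shape, dtype=bool)
    for cy, cx, a, b, theta in _place_ellipses(rng_cells, params):
        nr = _ellipse_norm_radius(shape, cy, cx, a, b, theta)
        inside = nr <= 1.0
        rim = inside & (nr >= 1.0 - _RIM_FRACTION)
        interior = inside & ~rim
        texture = _correlated_texture(rng_noise, shape, params)
        canvas = np.where(interior, params.background_level + texture, canvas)
        canvas = np.where(rim, params.background_level - params.border_contrast, canvas)
        truth |= inside

    lo, hi = params.debris_radius_range
    for _ in range(params.n_debris):
        r = rng_debris.uniform(lo, hi)
        cy = rng_debris.uniform(r, params.height - r)
        cx = rng_debris.uniform(r, params.width - r)
        blob = _ellipse_norm_radius(shape, cy, cx, r, r, 0.0) <= 1.0
        # debris is dark, high-contrast, and deliberately outside the truth
        canvas = np.where(blob & ~truth, params.background_level - 2 * params.border_contrast, canvas)

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.int64)
    image = Image(pixels=pixels, bit_depth=8, calibration=PixelCalibration(params.nm_per_pixel))
    return SyntheticScene(
        image=image,
        truth=BinaryMask(pixels=truth, calibration=image.calibration),
        params=params,
        seed=seed,
    )


def _check_shapes(a: BinaryMask, b: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a.pixels, b.pixels


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|a&b|/(|a|+|b|); two empty masks agree perfectly (1)."""
    pa, pb = _check_shapes(a, b)
    denom = int(pa.sum()) + int(pb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((pa & pb).sum()) / denom


def iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union; two empty masks agree perfectly (1)."""
    pa, pb = _check_shapes(a, b)
    union = int((pa | pb).sum())
    if union == 0:
        return 1.0
    return int((pa & pb).sum()) / union


def area_difference_percent(auto: BinaryMask, ref: BinaryMask) -> float:
    """Signed area difference (auto - ref)/ref x 100, ref taken as 100%."""
    pa, pr = _check_shapes(auto, ref)
    ref_area = int(pr.sum())
    if ref_area == 0:
        raise ValueError("reference mask is empty; area difference is undefined")
    return (int(pa.sum()) - ref_area) / ref_area * 100.0


def evaluate_pair(auto: BinaryMask, ref: BinaryMask) -> EvaluationRecord:
    return EvaluationRecord(
        dice=dice(auto, ref),
        iou=iou(auto, ref),
        area_diff_percent=area_difference_percent(auto, ref),
    )


def evaluate_batch(pairs: Sequence[tuple[BinaryMask, BinaryMask]]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of the signed area
    differences over (auto, ref) pairs; requires at least two pairs."""
    if len(pairs) < 2:
        raise ValueError(f"evaluate_batch needs >= 2 pairs, got {len(pairs)}")
    diffs = np.array([area_difference_percent(auto, ref) for auto, ref in pairs])
    return float(diffs.mean()), float(diffs.std(ddof=1))
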