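"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the operation definitions
(per-pixel loops, explicit neighbour enumeration, breadth-first search) and
deliberately shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------- morphology

def neighbor_positions(r: int, c: int):
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy or dx:
                yield r + dy, c + dx


def erode_oracle(mask: np.ndarray, count: int, pad: bool) -> np.ndarray:
    """Remove a foreground pixel iff >= count of its 8 neighbours are
    background; out-of-image neighbours are foreground when pad is true."""
    h, w = mask.shape
    out = mask.copy()
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            bg = 0
            for rr, cc in neighbor_positions(r, c):
                if 0 <= rr < h and 0 <= cc < w:
                    bg += not mask[rr, cc]
                else:
                    bg += not pad
            if bg >= count:
                out[r, c] = False
    return out


def dilate_oracle(mask: np.ndarray, count: int) -> np.ndarray:
    """Add a background pixel iff >= count of its 8 neighbours are
    foreground; out-of-image neighbours are background."""
    h, w = mask.shape
    out = mask.copy()
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                continue
            fg = 0
            for rr, cc in neighbor_positions(r, c):
                if 0 <= rr < h and 0 <= cc < w:
                    fg += bool(mask[rr, cc])
            if fg >= count:
                out[r, c] = True
    return out


def erode_oracle_batch(masks: np.ndarray, count: int, pad: bool) -> np.ndarray:
    """Same rule as erode_oracle, vectorized only over the batch axis:
    neighbours are enumerated per pixel with explicit bounds checks."""
    n, h, w = masks.shape
    out = masks.copy()
    for r in range(h):
        for c in range(w):
            bg = np.zeros(n, dtype=np.int32)
            for rr, cc in neighbor_positions(r, c):
                if 0 <= rr < h and 0 <= cc < w:
                    bg += ~masks[:, rr, cc]
                else:
                    bg += 0 if pad else 1
            remove = masks[:, r, c] & (bg >= count)
            out[remove, r, c] = False
    return out


def dilate_oracle_batch(masks: np.ndarray, count: int) -> np.ndarray:
    n, h, w = masks.shape
    out = masks.copy()
    for r in range(h):
        for c in range(w):
            fg = np.zeros(n, dtype=np.int32)
            for rr, cc in neighbor_positions(r, c):
                if 0 <= rr < h and 0 <= cc < w:
                    fg += masks[:, rr, cc]
            add = ~masks[:, r, c] & (fg >= count)
            out[add, r, c] = True
    return out


def kernel_offsets_oracle(radius: float) -> set[tuple[int, int]]:
    """Enumerate the circular kernel by the dy^2+dx^2 <= radius^2+1 rule."""
    limit = radius * radius + 1.0
    span = int(math.isqrt(int(limit))) + 2
    return {
        (dy, dx)
        for dy in range(-span, span + 1)
        for dx in range(-span, span + 1)
        if dy * dy + dx * dx <= limit
    }


def maximum_filter_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    """Shift-free per-pixel maximum over the enumerated kernel offsets,
    ignoring out-of-image positions (shrinking window)."""
    offsets = kernel_offsets_oracle(radius)
    h, w = img.shape
    out = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            best = None
            for dy, dx in offsets:
                rr, cc = r + dy, c + dx
                if 0 <= rr < h and 0 <= cc < w:
                    v = img[rr, cc]
                    best = v if best is None or v > best else best
            out[r, c] = best
    return out


def maximum_filter_shift_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    """Kernel enumeration via explicit shifted copies: for every offset the
    image is shifted and an elementwise running maximum is kept; positions a
    shift would take from outside the image do not participate."""
    offsets = kernel_offsets_oracle(radius)
    h, w = img.shape
    out = np.full((h, w), np.iinfo(np.int64).min, dtype=np.int64)
    for dy, dx in offsets:
        src_r = slice(max(dy, 0), h + min(dy, 0))
        src_c = slice(max(dx, 0), w + min(dx, 0))
        dst_r = slice(max(-dy, 0), h + min(-dy, 0))
        dst_c = slice(max(-dx, 0), w + min(-dx, 0))
        out[dst_r, dst_c] = np.maximum(out[dst_r, dst_c], img[src_r, src_c])
    return out


# ----------------------------------------------------------- edge detection

def gaussian_kernels_oracle(sigma: float):
    half = int(math.ceil(4.0 * sigma))
    xs = list(range(-half, half + 1))
    g = [math.exp(-0.5 * (x / sigma) ** 2) for x in xs]
    s = sum(g)
    g = [v / s for v in g]
    dg = [-(x / sigma**2) * v for x, v in zip(xs, g)]
    return xs, g, dg


def gaussian_gradient_oracle(img: np.ndarray, sigma: float):
    """Dense 2-D convolution (true convolution, replicated borders)."""
    xs, g, dg = gaussian_kernels_oracle(sigma)
    h, w = img.shape

    def sample(r, c):
        return img[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]

    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            sx = sy = 0.0
            for i, u in enumerate(xs):
                for j, v in enumerate(xs):
                    # convolution: kernel index u,v samples the image at (r-u, c-v)
                    val = sample(r - u, c - v)
                    sx += g[i] * dg[j] * val
                    sy += dg[i] * g[j] * val
            gx[r, c] = sx
            gy[r, c] = sy
    return gx, gy, np.hypot(gx, gy)


def nms_oracle(gx: np.ndarray, gy: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Directional comparison per pixel: strict > forward, >= backward."""
    h, w = mag.shape

    def sample(r, c):
        if 0 <= r < h and 0 <= c < w:
            return mag[r, c]
        return 0.0

    out = np.zeros_like(mag)
    for r in range(h):
        for c in range(w):
            m = mag[r, c]
            if m <= 0:
                continue
            ax, ay = abs(gx[r, c]), abs(gy[r, c])
            sx = 1 if gx[r, c] >= 0 else -1
            sy = 1 if gy[r, c] >= 0 else -1
            if ax >= ay:
                t = ay / ax if ax > 0 else 0.0
                fwd = (1 - t) * sample(r, c + sx) + t * sample(r + sy, c + sx)
                bwd = (1 - t) * sample(r, c - sx) + t * sample(r - sy, c - sx)
            else:
                t = ax / ay
                fwd = (1 - t) * sample(r + sy, c) + t * sample(r + sy, c + sx)
                bwd = (1 - t) * sample(r - sy, c) + t * sample(r - sy, c - sx)
            if m > fwd and m >= bwd:
                out[r, c] = m
    return out


def hysteresis_oracle(arr: np.ndarray, low: float, high: float) -> np.ndarray:
    """Breadth-first flood fill from >= high seeds through >= low pixels."""
    h, w = arr.shape
    out = np.zeros((h, w), dtype=bool)
    queue = deque((r, c) for r in range(h) for c in range(w) if arr[r, c] >= high)
    for r, c in queue:
        out[r, c] = True
    while queue:
        r, c = queue.popleft()
        for rr, cc in neighbor_positions(r, c):
            if 0 <= rr < h and 0 <= cc < w and not out[rr, cc] and arr[rr, cc] >= low:
                out[rr, cc] = True
                queue.append((rr, cc))
    return out
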