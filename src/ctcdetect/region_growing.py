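"""Seeded region growing inside a nucleus bounding box.

Seeds are the pixels of a designated seed region whose gray value
falls in the 80-95% band of the bounding-box histogram; the region
then expands over 8-neighborhoods under two conditions evaluated at
the already-accepted center point c for each neighbor q:

1. similarity: ``|gray(q) - gray(c)| < gray(c) * p``;
2. signal:     ``gray(c) > local_background + local_sd``,

iterated to a fixed point.  The fixed point is order-independent:
every accepted point eventually tests all eight of its neighbors, so a
pixel belongs to the mask iff some admissible chain reaches it from a
seed.  The implementation uses synchronous frontier sweeps (vectorized
over the box); the test suite checks it against an independent
breadth-first-search oracle.

For the green (STEAM) and red (CD45) channels there may be no target
at all inside the box; a channel is declared empty when the mean gray
under the nucleus mask is within one standard deviation of both the
global and the local background mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BoundingBox
from .params import DetectionParams

__all__ = [
    "GrowthContext",
    "CellSegmentation",
    "central_window",
    "select_seeds",
    "grow",
    "morph_cleanup",
    "detect_channel_target",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _mode_lowest(values: np.ndarray) -> int:
    """Most frequent gray value; ties resolved to the lowest value."""
    counts = np.bincount(np.asarray(values, dtype=np.uint8).ravel(), minlength=256)
    return int(np.argmax(counts))


@dataclass(frozen=True)
class GrowthContext:
    """Gray sub-raster of one channel plus its background statistics.

    Backgrounds are histogram modes (dark membrane in IF images);
    spreads are population standard deviations of the raw gray values,
    taken over the bounding box (local) or the whole channel (global).
    """

    bbox: BoundingBox
    gray: np.ndarray
    local_background: int
    local_sd: float
    global_background: int
    global_sd: float

    @classmethod
    def from_channel(
        cls,
        channel: np.ndarray,
        bbox: BoundingBox,
        global_background: int | None = None,
        global_sd: float | None = None,
    ) -> "GrowthContext":
        """Build the context for ``bbox`` within a full channel raster.

        Global statistics can be passed in to avoid recomputing them
        for every candidate of the same image.
        """
        channel = np.asarray(channel, dtype=np.uint8)
        sub = channel[bbox.slices]
        if global_background is None:
            global_background = _mode_lowest(channel)
        if global_sd is None:
            global_sd = float(channel.std())
        return cls(
            bbox=bbox,
            gray=sub,
            local_background=_mode_lowest(sub),
            local_sd=float(sub.std()),
            global_background=int(global_background),
            global_sd=float(global_sd),
        )


@dataclass
class CellSegmentation:
    """Per-candidate binary masks inside one bounding box."""

    bbox: BoundingBox
    nucleus_mask: np.ndarray
    green_mask: np.ndarray
    red_mask: np.ndarray
    green_present: bool
    red_present: bool

    def __post_init__(self) -> None:
        shape = self.nucleus_mask.shape
        if self.green_mask.shape != shape or self.red_mask.shape != shape:
            raise ValueError("segmentation masks must share the bbox shape")
        if not self.green_present and self.green_mask.any():
            raise ValueError("green flagged absent but mask non-empty")
        if not self.red_present and self.red_mask.any():
            raise ValueError("red flagged absent but mask non-empty")


def central_window(shape: tuple[int, int], size: int) -> np.ndarray:
    """Boolean mask of the central ``size x size`` square of ``shape``.

    Clipped for boxes smaller than the window.
    """
    h, w = shape
    r0 = max((h - size) // 2, 0)
    c0 = max((w - size) // 2, 0)
    mask = np.zeros(shape, dtype=bool)
    mask[r0 : min(r0 + size, h), c0 : min(c0 + size, w)] = True
    return mask


def _nearest_rank(sorted_values: np.ndarray, q: float) -> int:
    """Nearest-rank percentile of a pre-sorted 1-D array."""
    n = sorted_values.size
    idx = max(1, math.ceil(q * n))
    return int(sorted_values[min(idx, n) - 1])


def select_seeds(
    ctx: GrowthContext, params: DetectionParams, seed_region: np.ndarray
) -> np.ndarray:
    """Seed pixels: seed-region pixels inside the [P80, P95] gray band.

    Percentiles (nearest-rank) are taken over the *entire* bounding
    box, not just the seed region; a constant box degenerates to
    P80 = P95 and every seed-region pixel qualifies.
    """
    seed_region = np.asarray(seed_region, dtype=bool)
    if seed_region.shape != ctx.gray.shape:
        raise ValueError("seed_region must match the bounding-box shape")
    if not seed_region.any():
        return np.zeros_like(seed_region)
    flat = np.sort(ctx.gray, axis=None)
    lo = _nearest_rank(flat, params.seed_lo)
    hi = _nearest_rank(flat, params.seed_hi)
    return seed_region & (ctx.gray >= lo) & (ctx.gray <= hi)


def _shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Array shifted by (dr, dc); vacated cells take ``fill``."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rs_src = slice(max(-dr, 0), h + min(-dr, 0))
    cs_src = slice(max(-dc, 0), w + min(-dc, 0))
    out[rs, cs] = arr[rs_src, cs_src]
    return out


def grow(
    ctx: GrowthContext, seeds: np.ndarray, params: DetectionParams
) -> np.ndarray:
    """Grow the seed set to its fixed point under the two conditions.

    Seeds are always part of the result; growth never leaves the
    bounding box.  Implemented as synchronous frontier expansion.
    """
    seeds = np.asarray(seeds, dtype=bool)
    if seeds.shape != ctx.gray.shape:
        raise ValueError("seeds must match the bounding-box shape")
    gray = ctx.gray.astype(np.float64)
    signal_floor = ctx.local_background + ctx.local_sd
    can_expand = gray > signal_floor  # condition (2), a property of the center
    mask = seeds.copy()
    frontier = seeds.copy()
    while frontier.any():
        centers = frontier & can_expand
        if not centers.any():
            break
        new = np.zeros_like(mask)
        for dr, dc in _OFFSETS:
            c_act = _shift(centers, dr, dc, False)
            c_gray = _shift(gray, dr, dc, 0.0)
            cand = c_act & ~mask & (np.abs(gray - c_gray) < c_gray * params.p)
            new |= cand
        mask |= new
        frontier = new
    return mask


def morph_cleanup(mask: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Binary opening then closing with a (2r+1)-square element.

    Removes discrete specks and fills small interior holes, as the
    post-growth cleanup step.
    """
    mask = np.asarray(mask, dtype=bool)
    if params.morph_radius == 0 or not mask.any():
        return mask.copy()
    size = 2 * params.morph_radius + 1
    structure = np.ones((size, size), dtype=bool)
    opened = ndimage.binary_opening(mask, structure=structure)
    return ndimage.binary_closing(opened, structure=structure)


def detect_channel_target(
    ctx: GrowthContext,
    blue_mask: np.ndarray,
    params: DetectionParams,
) -> tuple[bool, np.ndarray]:
    """Decide whether the green/red channel holds a target; segment it if so.

    The mean gray of the channel under the (cleaned) nucleus mask is
    compared to the global and local background modes; the channel is
    declared empty when it is within one standard deviation of both
    (a zero deviation with a zero difference also counts as empty —
    the degenerate constant-channel case).  When a target is present,
    growth is re-run with the nucleus area as the seed region.
    """
    blue_mask = np.asarray(blue_mask, dtype=bool)
    empty = np.zeros_like(blue_mask)
    if not blue_mask.any():
        return False, empty
    m = float(ctx.gray[blue_mask].mean())
    dg = abs(m - ctx.global_background)
    dl = abs(m - ctx.local_background)
    no_global = dg < ctx.global_sd or dg == 0.0
    no_local = dl < ctx.local_sd or dl == 0.0
    if no_global and no_local:
        return False, empty
    seeds = select_seeds(ctx, params, blue_mask)
    mask = morph_cleanup(grow(ctx, seeds, params), params)
    return True, mask
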