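"""Nucleus candidate detection in the DAPI (blue) channel.

The blue channel is binarized with Otsu's method, its 8-connected
foreground components are measured, and components are gated by size:
anything at filter-hole scale or below (h1 = w1 = 46 px against the
~56 px holes) or at hole-lattice scale or above (h2 = w2 = 200 px
against the 180 px spacing) is discarded as background structure or
large contamination.  Survivors get a 3x-expanded analysis box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import measure

from .geometry import BoundingBox
from .params import DetectionParams

__all__ = [
    "ConnectedRegion",
    "otsu_threshold",
    "binarize_blue",
    "find_regions",
    "filter_regions",
    "make_bounding_box",
]


@dataclass(frozen=True, eq=False)
class ConnectedRegion:
    """One 8-connected foreground component of the binarized blue channel.

    ``W`` and ``H`` are the tight-box extents (max col/row span), the
    quantities the size gates act on.
    """

    coords: np.ndarray  # (N, 2) array of (row, col)
    W: int
    H: int
    bbox: BoundingBox
    centroid: tuple[float, float]

    @property
    def area(self) -> int:
        return len(self.coords)


def otsu_threshold(gray: np.ndarray) -> int | None:
    """Exhaustive Otsu threshold over all 8-bit cut points.

    Returns the smallest t in [0, 255] maximizing the between-class
    variance of the split {<= t} vs {> t}, or None for a constant
    raster (no split exists).
    """
    gray = np.asarray(gray, dtype=np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        return None
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # weight of class {<= t}
    s0 = np.cumsum(hist * levels)
    w1 = total - w0
    mu_total = s0[-1]
    # between-class variance w0*w1*(mu0-mu1)^2, guarded against empty classes
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (mu_total - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def binarize_blue(blue: np.ndarray) -> np.ndarray:
    """Otsu-binarize the DAPI channel; foreground = pixels above threshold.

    A constant raster carries no nucleus signal and yields an
    all-background mask.
    """
    t = otsu_threshold(blue)
    if t is None:
        return np.zeros(np.asarray(blue).shape, dtype=bool)
    return np.asarray(blue) > t


def find_regions(mask: np.ndarray) -> list[ConnectedRegion]:
    """Maximal 8-connected foreground components, in label order."""
    labeled = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = []
    for props in measure.regionprops(labeled):
        r0, c0, r1, c1 = props.bbox  # half-open
        regions.append(
            ConnectedRegion(
                coords=np.asarray(props.coords),
                W=c1 - c0,
                H=r1 - r0,
                bbox=BoundingBox(r0, c0, r1, c1),
                centroid=tuple(props.centroid),
            )
        )
    return regions


def filter_regions(
    regions: Sequence[ConnectedRegion], params: DetectionParams
) -> list[ConnectedRegion]:
    """Keep regions with h1 < H < h2 and w1 < W < w2 (strict), order preserved."""
    return [
        r
        for r in regions
        if params.h1 < r.H < params.h2 and params.w1 < r.W < params.w2
    ]


def make_bounding_box(
    region: ConnectedRegion,
    params: DetectionParams,
    image_shape: tuple[int, int],
) -> BoundingBox:
    """Expand the tight nucleus box by ``expand_factor`` per axis.

    The expansion is centered; an odd pixel remainder goes to the
    bottom/right.  The result is clipped to the image and always
    contains the tight box.
    """
    tb = region.bbox
    new_h = int(round(params.expand_factor * tb.height))
    new_w = int(round(params.expand_factor * tb.width))
    pad_top = (new_h - tb.height) // 2
    pad_left = (new_w - tb.width) // 2
    box = BoundingBox(
        tb.row0 - pad_top,
        tb.col0 - pad_left,
        tb.row0 - pad_top + new_h,
        tb.col0 - pad_left + new_w,
    )
    return box.clip(*image_shape)
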