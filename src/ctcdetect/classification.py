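"""Karyoplasmic-ratio measurement and CTC/leukocyte classification.

The karyoplasmic ratio (KR) of a segmented cell is the DAPI (nucleus)
area divided by the total cell area, where total cell area is the
union of the binarized DAPI, STEAM and CD45 masks; Red_prop is the
CD45 area over the same denominator.  A candidate is called a CTC iff

    KR > K  and  Red_prop < R  (strict; defaults K = 0.70, R = 0.35)

and, by default, a STEAM cytoplasm target was detected — a completely
unstained nucleus would otherwise score KR = 1 and pass trivially.
``process_image`` chains the whole per-image pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import BoundingBox
from .image_io import MultiChannelImage
from .nucleus_detection import (
    binarize_blue,
    filter_regions,
    find_regions,
    make_bounding_box,
)
from .params import CTC, NON_CTC, DetectionParams
from .region_growing import (
    CellSegmentation,
    GrowthContext,
    central_window,
    detect_channel_target,
    grow,
    morph_cleanup,
    select_seeds,
    _mode_lowest,
)

__all__ = [
    "CellMeasurement",
    "MeasurementError",
    "compute_kr",
    "compute_red_prop",
    "classify",
    "segment_candidate",
    "process_image",
    "measurements_to_frame",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "source_id",
    "row0",
    "col0",
    "row1",
    "col1",
    "nucleus_area",
    "cell_area",
    "KR",
    "Red_prop",
    "green_present",
    "red_present",
    "label",
]


class MeasurementError(ValueError):
    """A candidate cannot be measured (e.g. empty nucleus mask)."""


@dataclass(frozen=True)
class CellMeasurement:
    """Measurements and label for one nucleus candidate."""

    bbox: BoundingBox
    kr: float
    red_prop: float
    nucleus_area: int
    cell_area: int
    green_present: bool
    red_present: bool
    label: str
    source_id: str = ""


def _cell_union(seg: CellSegmentation) -> np.ndarray:
    return seg.nucleus_mask | seg.green_mask | seg.red_mask


def compute_kr(seg: CellSegmentation) -> float:
    """Karyoplasmic ratio: nucleus area / total cell area."""
    n = int(seg.nucleus_mask.sum())
    if n == 0:
        raise MeasurementError("empty nucleus mask")
    return n / int(_cell_union(seg).sum())


def compute_red_prop(seg: CellSegmentation) -> float:
    """CD45 proportion: red area / total cell area (0 when red absent)."""
    if not seg.nucleus_mask.any():
        raise MeasurementError("empty nucleus mask")
    r = int(seg.red_mask.sum())
    if r == 0:
        return 0.0
    return r / int(_cell_union(seg).sum())


def classify(
    kr: float,
    red_prop: float,
    green_present: bool,
    params: DetectionParams,
) -> str:
    """Apply the K/R decision rule (strict inequalities)."""
    is_ctc = kr > params.kr_threshold and red_prop < params.red_prop_threshold
    if params.require_green:
        is_ctc = is_ctc and green_present
    return CTC if is_ctc else NON_CTC


def segment_candidate(
    image: MultiChannelImage,
    bbox: BoundingBox,
    params: DetectionParams,
    global_stats: dict[str, tuple[int, float]] | None = None,
) -> CellSegmentation:
    """Segment nucleus, green and red targets inside one bounding box.

    ``global_stats`` maps channel name to precomputed (background mode,
    standard deviation) for the whole raster; omitted entries are
    computed on the fly.
    """
    global_stats = global_stats or {}

    def ctx_for(name: str, channel: np.ndarray) -> GrowthContext:
        bg, sd = global_stats.get(name, (None, None))
        return GrowthContext.from_channel(channel, bbox, bg, sd)

    blue_ctx = ctx_for("blue", image.blue)
    seeds = select_seeds(blue_ctx, params, central_window(blue_ctx.gray.shape, params.seed_window))
    nucleus = morph_cleanup(grow(blue_ctx, seeds, params), params)
    if not nucleus.any():
        raise MeasurementError(f"no nucleus target grown in box {bbox}")

    green_present, green_mask = detect_channel_target(
        ctx_for("green", image.green), nucleus, params
    )
    red_present, red_mask = detect_channel_target(
        ctx_for("red", image.red), nucleus, params
    )
    return CellSegmentation(
        bbox=bbox,
        nucleus_mask=nucleus,
        green_mask=green_mask,
        red_mask=red_mask,
        green_present=green_present,
        red_present=red_present,
    )


def process_image(
    image: MultiChannelImage, params: DetectionParams | None = None
) -> list[CellMeasurement]:
    """Run the full per-image pipeline.

    Binarize blue, find and size-gate nucleus regions, grow each
    candidate's masks, measure KR and Red_prop, classify.  Returns one
    measurement per surviving candidate (empty list when no region
    passes the gates).  Candidates whose nucleus cannot be grown are
    dropped with a warning.
    """
    params = params or DetectionParams()
    candidates = filter_regions(find_regions(binarize_blue(image.blue)), params)
    if not candidates:
        return []
    global_stats = {
        name: (_mode_lowest(chan), float(chan.std()))
        for name, chan in (
            ("blue", image.blue),
            ("green", image.green),
            ("red", image.red),
        )
    }
    results: list[CellMeasurement] = []
    for region in candidates:
        bbox = make_bounding_box(region, params, image.shape)
        try:
            seg = segment_candidate(image, bbox, params, global_stats)
            kr = compute_kr(seg)
            red_prop = compute_red_prop(seg)
        except MeasurementError as exc:
            logger.warning("%s: dropped candidate at %s: %s", image.source_id, bbox, exc)
            continue
        results.append(
            CellMeasurement(
                bbox=bbox,
                kr=kr,
                red_prop=red_prop,
                nucleus_area=int(seg.nucleus_mask.sum()),
                cell_area=int(_cell_union(seg).sum()),
                green_present=seg.green_present,
                red_present=seg.red_present,
                label=classify(kr, red_prop, seg.green_present, params),
                source_id=image.source_id,
            )
        )
    return results


def measurements_to_frame(measurements: Sequence[CellMeasurement]) -> pd.DataFrame:
    """Detection report table, one row per candidate."""
    rows = [
        {
            "source_id": m.source_id,
            "row0": m.bbox.row0,
            "col0": m.bbox.col0,
            "row1": m.bbox.row1,
            "col1": m.bbox.col1,
            "nucleus_area": m.nucleus_area,
            "cell_area": m.cell_area,
            "KR": m.kr,
            "Red_prop": m.red_prop,
            "green_present": m.green_present,
            "red_present": m.red_present,
            "label": m.label,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
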