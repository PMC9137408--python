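"""Tunable parameters of the detection pipeline.

Defaults follow the published operating point of the membrane-filtration
CTC assay the pipeline targets: size gates bracketing the 56 px filter
holes and the 180 px hole lattice (h1 = w1 = 46, h2 = w2 = 200), a 3x
analysis window around each nucleus, seed selection from the 80-95%
band of the window's gray histogram, and the decision thresholds
KR > 0.70 (karyoplasmic ratio) and CD45 proportion < 0.35.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

#: Class labels used throughout the package.
CTC = "CTC"
NON_CTC = "non-CTC"


@dataclass(frozen=True)
class DetectionParams:
    """Parameter set for segmentation and classification.

    Attributes
    ----------
    h1, h2 : int
        Lower/upper gate (exclusive) on the pixel height of a nucleus
        connected region.  Regions are kept iff ``h1 < H < h2``.
    w1, w2 : int
        Same gates for the pixel width.
    expand_factor : float
        The tight nucleus box is enlarged by this factor (per axis,
        centered) to form the analysis bounding box.
    seed_window : int
        Side of the central square of the bounding box from which blue
        seeds are drawn.
    seed_lo, seed_hi : float
        Seed gray values must lie inside the closed percentile band
        ``[P(seed_lo), P(seed_hi)]`` of the bounding-box histogram
        (fractions in [0, 1]).
    p : float
        Region-growing similarity factor: a neighbor q of an accepted
        point c joins iff ``|gray(q) - gray(c)| < gray(c) * p``.
        Not fixed by the published description; 0.2 by default.
    kr_threshold : float
        K — a cell is a CTC candidate only if its karyoplasmic ratio
        exceeds this (strict).
    red_prop_threshold : float
        R — a cell is rejected as a leukocyte if the CD45 (red) area
        proportion reaches this (CTC requires ``Red_prop < R``, strict).
    morph_radius : int
        Radius of the square structuring element (side 2r+1) used for
        the post-growth opening and closing.
    require_green : bool
        If true (default), a CTC call additionally requires a detected
        STEAM (green) cytoplasm target; a bare nucleus with no stain at
        all would otherwise score KR = 1 and be called a CTC.
    """

    h1: int = 46
    h2: int = 200
    w1: int = 46
    w2: int = 200
    expand_factor: float = 3.0
    seed_window: int = 11
    seed_lo: float = 0.80
    seed_hi: float = 0.95
    p: float = 0.2
    kr_threshold: float = 0.70
    red_prop_threshold: float = 0.35
    morph_radius: int = 1
    require_green: bool = True

    def __post_init__(self) -> None:
        errors = []
        if not (0 < self.h1 < self.h2):
            errors.append("h1/h2: need 0 < h1 < h2")
        if not (0 < self.w1 < self.w2):
            errors.append("w1/w2: need 0 < w1 < w2")
        if self.expand_factor < 1:
            errors.append("expand_factor: must be >= 1")
        if self.seed_window < 1 or self.seed_window % 2 == 0:
            errors.append("seed_window: must be a positive odd integer")
        if not (0 <= self.seed_lo < self.seed_hi <= 1):
            errors.append("seed_lo/seed_hi: need 0 <= lo < hi <= 1")
        if self.p <= 0:
            errors.append("p: must be > 0")
        if not (0 <= self.kr_threshold <= 1):
            errors.append("kr_threshold: must be in [0, 1]")
        if not (0 <= self.red_prop_threshold <= 1):
            errors.append("red_prop_threshold: must be in [0, 1]")
        if self.morph_radius < 0:
            errors.append("morph_radius: must be >= 0")
        if errors:
            raise ValueError("invalid DetectionParams: " + "; ".join(errors))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "DetectionParams":
        """Build params from a dict, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown parameter fields: {', '.join(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_yaml(cls, path) -> "DetectionParams":
        """Load params from a YAML (or JSON — valid YAML) file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
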