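"""Ground-truthed synthetic immunofluorescence membrane scenes.

Emulates the imaging setup of a membrane-filtration CTC assay: a dark
membrane background perforated by a square lattice of darker filter
holes (~56 px diameter, 180 px center-to-center), on which cells are
rendered as a bright nucleus disc in the DAPI (blue) channel plus a
larger concentric cytoplasm disc in the STEAM (green) channel for
tumor cells or the CD45 (red) channel for leukocytes.  Gaussian noise
is added per channel and clipped to 8 bits.

Cell populations mirror the clinical regimes: tumor cells target a
karyoplasmic ratio (nucleus area / cell area) around 0.75-0.89 and
leukocytes around 0.39-0.52; "small CTCs" sit just above the size
gate with a near-unity KR; occasional oversized debris blobs exercise
the upper size gate.  Every rendered cell is logged in a truth table
with its tight box, planted pixel-count KR and true label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import MultiChannelImage, write_composite
from .params import CTC, NON_CTC

__all__ = [
    "CellSpec",
    "SyntheticSceneSpec",
    "generate_scene",
    "sample_cells",
    "sample_kinds",
    "random_scene_spec",
    "generate_benchmark",
    "DEFAULT_MIX",
    "KINDS",
]

KIND_CTC = "CTC"
KIND_SMALL_CTC = "small_CTC"
KIND_LEUKOCYTE = "leukocyte"
KIND_DEBRIS = "debris"
KINDS = (KIND_CTC, KIND_SMALL_CTC, KIND_LEUKOCYTE, KIND_DEBRIS)

#: Population mix: CTC prevalence among cells ~24% (258 of 1,067 in the
#: clinical validation set), a minority of them below normal cell size,
#: plus occasional large contamination.
DEFAULT_MIX = {
    KIND_CTC: 0.19,
    KIND_SMALL_CTC: 0.05,
    KIND_LEUKOCYTE: 0.73,
    KIND_DEBRIS: 0.03,
}

TRUTH_COLUMNS = [
    "source_id",
    "row0",
    "col0",
    "row1",
    "col1",
    "label",
    "kind",
    "planted_kr",
    "overlaps",
]


@dataclass(frozen=True)
class CellSpec:
    """One cell to render: concentric nucleus and cytoplasm discs."""

    center: tuple[int, int]
    nucleus_radius: int
    cell_radius: int
    kind: str
    blue_intensity: int
    green_intensity: int
    red_intensity: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.nucleus_radius > self.cell_radius:
            raise ValueError("nucleus_radius must not exceed cell_radius")
        if self.kind in (KIND_CTC, KIND_SMALL_CTC):
            if self.green_intensity <= 0 or self.red_intensity != 0:
                raise ValueError("tumor cells stain green, never red")
        if self.kind == KIND_LEUKOCYTE:
            if self.red_intensity <= 0 or self.green_intensity != 0:
                raise ValueError("leukocytes stain red, never green")

    @property
    def true_label(self) -> str:
        return CTC if self.kind in (KIND_CTC, KIND_SMALL_CTC) else NON_CTC


@dataclass
class SyntheticSceneSpec:
    """Full description of one scene; rendering is a pure function of it."""

    height: int = 720
    width: int = 960
    hole_diameter: int = 56
    hole_spacing: int = 180
    cells: list[CellSpec] = field(default_factory=list)
    noise_sd: float = 3.0
    background_level: int = 12
    hole_level: int = 2
    seed: int = 0
    source_id: str = "scene"

    def __post_init__(self) -> None:
        if self.hole_spacing <= self.hole_diameter:
            raise ValueError("hole_spacing must exceed hole_diameter")
        for cell in self.cells:
            r, c = cell.center
            rad = cell.cell_radius
            if not (rad <= r < self.height - rad and rad <= c < self.width - rad):
                raise ValueError(f"cell at {cell.center} extends outside the scene")


def _disc_mask(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    """Boolean disc: pixels whose center is within ``radius`` of ``center``."""
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return rr * rr + cc * cc <= radius * radius


def _hole_mask(spec: SyntheticSceneSpec) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    r_hole = spec.hole_diameter // 2
    start = spec.hole_spacing // 2
    for hr in range(start, spec.height, spec.hole_spacing):
        for hc in range(start, spec.width, spec.hole_spacing):
            mask |= _disc_mask(mask.shape, (hr, hc), r_hole)
    return mask


def generate_scene(spec: SyntheticSceneSpec) -> tuple[MultiChannelImage, pd.DataFrame]:
    """Render a scene and its per-cell ground-truth table.

    The planted KR of a cell is the pixel-count ratio of its rendered
    nucleus disc to its full cell disc.  Overlapping cells are
    rendered as specified but flagged in the truth table.
    """
    shape = (spec.height, spec.width)
    channels = {
        name: np.full(shape, float(spec.background_level)) for name in ("blue", "green", "red")
    }
    holes = _hole_mask(spec)
    for arr in channels.values():
        arr[holes] = spec.hole_level

    rows = []
    for i, cell in enumerate(spec.cells):
        nucleus = _disc_mask(shape, cell.center, cell.nucleus_radius)
        body = _disc_mask(shape, cell.center, cell.cell_radius)
        if cell.green_intensity > 0:
            channels["green"][body] = cell.green_intensity
        if cell.red_intensity > 0:
            channels["red"][body] = cell.red_intensity
        channels["blue"][nucleus] = cell.blue_intensity
        overlaps = any(
            math.dist(cell.center, other.center) < cell.cell_radius + other.cell_radius
            for j, other in enumerate(spec.cells)
            if j != i
        )
        r, c = cell.center
        rad = cell.cell_radius
        rows.append(
            {
                "source_id": spec.source_id,
                "row0": r - rad,
                "col0": c - rad,
                "row1": r + rad + 1,
                "col1": c + rad + 1,
                "label": cell.true_label,
                "kind": cell.kind,
                "planted_kr": int(nucleus.sum()) / int(body.sum()),
                "overlaps": overlaps,
            }
        )

    rng = np.random.default_rng(spec.seed)
    rasters = {}
    for name, arr in channels.items():
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, shape)
        rasters[name] = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    image = MultiChannelImage(
        blue=rasters["blue"],
        green=rasters["green"],
        red=rasters["red"],
        source_id=spec.source_id,
    )
    return image, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def sample_kinds(rng: np.random.Generator, n: int, mix: dict[str, float]) -> list[str]:
    """Draw ``n`` cell kinds from the population mix (must sum to 1)."""
    kinds = sorted(mix)
    probs = np.array([mix[k] for k in kinds], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("mix proportions must be non-negative and sum to 1")
    return [str(k) for k in rng.choice(kinds, size=n, p=probs)]


def _sample_geometry(rng: np.random.Generator, kind: str) -> tuple[int, int]:
    """Nucleus/cell radii for one cell, targeting the clinical KR bands."""
    if kind == KIND_CTC:
        nucleus = int(rng.integers(25, 33))
        kr = float(np.clip(rng.normal(0.82, 0.04), 0.75, 0.89))
        cell = max(nucleus + 1, round(nucleus / math.sqrt(kr)))
    elif kind == KIND_SMALL_CTC:
        # just above the lower size gate; near-unity KR
        cell = int(rng.integers(24, 26))
        nucleus = cell - 1
    elif kind == KIND_LEUKOCYTE:
        nucleus = int(rng.integers(24, 29))
        kr = float(np.clip(rng.normal(0.46, 0.035), 0.39, 0.52))
        cell = round(nucleus / math.sqrt(kr))
    elif kind == KIND_DEBRIS:
        nucleus = cell = int(rng.integers(102, 116))  # diameter > upper gate
    else:  # pragma: no cover
        raise ValueError(kind)
    return nucleus, cell


def _make_cell(
    rng: np.random.Generator,
    kind: str,
    center: tuple[int, int],
    nucleus: int,
    cell: int,
) -> CellSpec:
    blue = int(rng.integers(180, 221))
    green = red = 0
    if kind in (KIND_CTC, KIND_SMALL_CTC):
        green = int(rng.integers(140, 181))
    elif kind == KIND_LEUKOCYTE:
        red = int(rng.integers(140, 181))
    return CellSpec(
        center=center,
        nucleus_radius=nucleus,
        cell_radius=cell,
        kind=kind,
        blue_intensity=blue,
        green_intensity=green,
        red_intensity=red,
    )


def sample_cells(
    rng: np.random.Generator,
    height: int,
    width: int,
    n_cells: int,
    mix: dict[str, float] | None = None,
    max_tries: int = 400,
) -> list[CellSpec]:
    """Place ``n_cells`` non-overlapping cells drawn from ``mix``.

    Placement keeps each cell's expanded analysis box clear of its
    neighbors' cytoplasm so that per-candidate statistics stay clean;
    cells that cannot be placed after ``max_tries`` rejections are
    skipped (large debris on a crowded scene).
    """
    mix = mix if mix is not None else DEFAULT_MIX
    kinds = sample_kinds(rng, n_cells, mix)
    # place the big objects first so they still find room
    kinds.sort(key=lambda k: 0 if k == KIND_DEBRIS else 1)
    placed: list[CellSpec] = []
    for kind in kinds:
        nucleus, cell_r = _sample_geometry(rng, kind)
        margin = max(cell_r, 3 * nucleus // 2) + 8
        if height - 2 * margin <= 0 or width - 2 * margin <= 0:
            continue
        for _ in range(max_tries):
            r = int(rng.integers(margin, height - margin))
            c = int(rng.integers(margin, width - margin))
            clear = all(
                math.dist((r, c), other.center)
                > 3 * max(nucleus, other.nucleus_radius) + cell_r + other.cell_radius
                for other in placed
            )
            if clear:
                placed.append(_make_cell(rng, kind, (r, c), nucleus, cell_r))
                break
    return placed


def random_scene_spec(
    seed: int,
    n_cells: int = 10,
    height: int = 720,
    width: int = 960,
    mix: dict[str, float] | None = None,
    noise_sd: float = 3.0,
    source_id: str = "scene",
) -> SyntheticSceneSpec:
    """A fully random scene specification, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    cells = sample_cells(rng, height, width, n_cells, mix)
    return SyntheticSceneSpec(
        height=height,
        width=width,
        cells=cells,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        source_id=source_id,
    )


def generate_benchmark(
    outdir,
    n_scenes: int,
    seed: int,
    cells_per_scene: int = 10,
    mix: dict[str, float] | None = None,
    height: int = 720,
    width: int = 960,
    noise_sd: float = 3.0,
) -> pd.DataFrame:
    """Write a benchmark dataset: PNG scenes, truth CSV and a spec file.

    Returns the combined truth table.  Scene seeds are derived
    deterministically from ``seed``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    truths = []
    for i, child in enumerate(root.spawn(n_scenes)):
        scene_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        sid = f"scene_{i:03d}"
        spec = random_scene_spec(
            scene_seed,
            n_cells=cells_per_scene,
            height=height,
            width=width,
            mix=mix,
            noise_sd=noise_sd,
            source_id=sid,
        )
        image, truth = generate_scene(spec)
        write_composite(image, outdir / f"{sid}.png")
        truths.append(truth)
    combined = pd.concat(truths, ignore_index=True)
    combined.to_csv(outdir / "truth.csv", index=False)
    manifest = {
        "n_scenes": n_scenes,
        "seed": seed,
        "cells_per_scene": cells_per_scene,
        "mix": mix if mix is not None else DEFAULT_MIX,
        "height": height,
        "width": width,
        "noise_sd": noise_sd,
    }
    with open(outdir / "benchmark_spec.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return combined
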