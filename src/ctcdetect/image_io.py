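"""Reading and writing three-channel immunofluorescence images.

The assay images one field of view in three dyes: DAPI (nucleus, blue),
the STEAM antibody cocktail (tumor cytoplasm, green) and CD45
(leukocyte marker, red).  A composite 24-bit RGB file is split into its
raw planes — no luminance mixing, no scaling — or three per-channel
exports are assembled into the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import imageio.v3 as iio
import numpy as np

from .geometry import BoundingBox
from .params import CTC

if TYPE_CHECKING:  # pragma: no cover
    from .classification import CellMeasurement

__all__ = [
    "MultiChannelImage",
    "ChannelError",
    "ShapeError",
    "load_composite",
    "load_channels",
    "write_composite",
    "write_annotated",
]

#: RGB plane index for each channel role.
_PLANE = {"red": 0, "green": 1, "blue": 2}


class ChannelError(ValueError):
    """A file does not carry the color planes its role requires."""


class ShapeError(ValueError):
    """Per-channel files disagree in size."""


@dataclass
class MultiChannelImage:
    """Aligned 8-bit grayscale rasters for one field of view."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        rasters = {"blue": self.blue, "green": self.green, "red": self.red}
        for name, arr in rasters.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ShapeError(f"{name} raster must be 2-D, got {arr.shape}")
            if arr.dtype != np.uint8:
                if arr.min() < 0 or arr.max() > 255:
                    raise ValueError(f"{name} raster values outside [0, 255]")
                arr = arr.astype(np.uint8)
            setattr(self, name, arr)
        if not (self.blue.shape == self.green.shape == self.red.shape):
            raise ShapeError(
                "channel rasters differ in shape: "
                f"blue {self.blue.shape}, green {self.green.shape}, "
                f"red {self.red.shape}"
            )

    @property
    def height(self) -> int:
        return self.blue.shape[0]

    @property
    def width(self) -> int:
        return self.blue.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def to_rgb(self) -> np.ndarray:
        """Stack the channels into an (H, W, 3) RGB array."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


def _read_array(path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def _as_color(arr: np.ndarray, path) -> np.ndarray:
    """Return an (H, W, >=3) color array or raise ChannelError."""
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ChannelError(
            f"{path}: expected a 3-channel color image, got shape {arr.shape}"
        )
    return arr


def load_composite(path, source_id: str | None = None) -> MultiChannelImage:
    """Split a composite RGB image into raw dye-channel rasters.

    The R, G and B planes are taken verbatim as the CD45, STEAM and
    DAPI rasters; pixel values are never rescaled.
    """
    arr = _as_color(_read_array(path), path)
    sid = source_id if source_id is not None else Path(path).stem
    return MultiChannelImage(
        blue=arr[..., 2].copy(),
        green=arr[..., 1].copy(),
        red=arr[..., 0].copy(),
        source_id=sid,
    )


def _read_channel(path, role: str) -> np.ndarray:
    """Read one per-channel export; color files contribute their designated plane."""
    arr = _read_array(path)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim == 3 and arr.shape[-1] >= 3:
        return arr[..., _PLANE[role]].copy()
    raise ChannelError(f"{path}: cannot interpret shape {arr.shape} as a {role} channel")


def load_channels(
    blue_path, green_path, red_path, source_id: str | None = None
) -> MultiChannelImage:
    """Assemble a field of view from three per-channel files."""
    blue = _read_channel(blue_path, "blue")
    green = _read_channel(green_path, "green")
    red = _read_channel(red_path, "red")
    if not (blue.shape == green.shape == red.shape):
        raise ShapeError(
            f"channel files differ in size: blue {blue.shape}, "
            f"green {green.shape}, red {red.shape}"
        )
    sid = source_id if source_id is not None else Path(blue_path).stem
    return MultiChannelImage(blue=blue, green=green, red=red, source_id=sid)


def write_composite(image: MultiChannelImage, out_path) -> None:
    """Write the RGB composite (use PNG for lossless round trips)."""
    iio.imwrite(out_path, image.to_rgb())


def _draw_rect(rgb: np.ndarray, box: BoundingBox, color=(255, 0, 0), thickness: int = 2) -> None:
    """Draw a rectangle border just inside ``box`` (in place)."""
    h, w = rgb.shape[:2]
    b = box.clip(h, w)
    t = min(thickness, b.height, b.width)
    rgb[b.row0 : b.row0 + t, b.col0 : b.col1] = color
    rgb[b.row1 - t : b.row1, b.col0 : b.col1] = color
    rgb[b.row0 : b.row1, b.col0 : b.col0 + t] = color
    rgb[b.row0 : b.row1, b.col1 - t : b.col1] = color


def write_annotated(
    image: MultiChannelImage,
    detections: Iterable["CellMeasurement"],
    out_path,
) -> None:
    """Write the composite with a red box around every CTC call.

    Only detections labeled CTC are boxed; pixels away from the 2 px
    borders are left untouched, so a detection-free image round-trips
    bit-identically through a lossless format.
    """
    rgb = image.to_rgb().copy()
    for det in detections:
        if det.label == CTC:
            _draw_rect(rgb, det.bbox)
    iio.imwrite(out_path, rgb)
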