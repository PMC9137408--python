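"""Pixel-grid geometry primitives.

Coordinates are row-major and 0-based; boxes are half-open
``[row0, row1) x [col0, col1)`` so that areas and widths are plain
differences.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel rectangle."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate box {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row0 + self.row1) / 2.0, (self.col0 + self.col1) / 2.0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def contains_point(self, row: float, col: float) -> bool:
        return self.row0 <= row < self.row1 and self.col0 <= col < self.col1

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.row0 <= other.row0
            and self.col0 <= other.col0
            and self.row1 >= other.row1
            and self.col1 >= other.col1
        )

    def clip(self, height: int, width: int) -> "BoundingBox":
        """Intersect with an image of the given shape."""
        return BoundingBox(
            max(self.row0, 0),
            max(self.col0, 0),
            min(self.row1, height),
            min(self.col1, width),
        )
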