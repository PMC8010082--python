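"""Raster grid metadata shared by every raster in a scene.

All products in this package live on a single 30 m grid (the resolution of
the published oil-palm map). A :class:`RasterGrid` carries shape, pixel
size and a simple affine georeference (origin + pixel size, north-up); two
rasters may be combined only when their grids compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


class GridMismatchError(ValueError):
    """Raised when an operation combines rasters on different grids."""


@dataclass(frozen=True)
class RasterGrid:
    rows: int
    cols: int
    pixel_size: float = 30.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid extent must be positive, got {self.rows}x{self.cols}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size ** 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RasterGrid":
        return cls(**d)


def require_same_grid(*grids: RasterGrid) -> None:
    """Raise :class:`GridMismatchError` unless all grids are identical."""
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridMismatchError(f"grids differ: {first} vs {g}")
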