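"""Grid geometry shared by all raster-facing modules.

Conventions (used everywhere in the package):

* projected metric CRS, identified by an opaque label (e.g. ``"EPSG:25831"``);
* north-up rasters, 0-based pixel indexing, pixel ``(0, 0)`` at the top-left;
* the transform stores the *corner* of the top-left pixel, so the centre of
  pixel ``(row, col)`` is ``(origin_x + (col + 0.5) * px, origin_y - (row + 0.5) * px)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridTransform", "CrsMismatchError", "AlignmentError", "ensure_aligned"]


class CrsMismatchError(ValueError):
    """Raster and vector layers are in different CRSs; reproject upstream."""


class AlignmentError(ValueError):
    """Two grids that must share shape/transform do not."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeferencing: top-left corner and square pixel size."""

    origin_x: float
    origin_y: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def cell_centres(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) pixel-centre coordinates."""
        nrow, ncol = shape
        xs = self.origin_x + (np.arange(ncol) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(nrow) + 0.5) * self.pixel_size
        return xs, ys

    def centre_mesh(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = self.cell_centres(shape)
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the pixel containing a point (no bounds check)."""
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def pixel_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one pixel's footprint."""
        x0 = self.origin_x + col * self.pixel_size
        y1 = self.origin_y - row * self.pixel_size
        return x0, y1 - self.pixel_size, x0 + self.pixel_size, y1

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        nrow, ncol = shape
        return (
            self.origin_x,
            self.origin_y - nrow * self.pixel_size,
            self.origin_x + ncol * self.pixel_size,
            self.origin_y,
        )


def ensure_aligned(*layers) -> None:
    """Raise :class:`AlignmentError` unless all layers share shape and transform.

    Each layer must expose ``.values`` (2-D array) and ``.transform``.
    """
    ref = layers[0]
    for other in layers[1:]:
        if other.values.shape != ref.values.shape:
            raise AlignmentError(
                f"grid shapes differ: {ref.values.shape} vs {other.values.shape}"
            )
        if other.transform != ref.transform:
            raise AlignmentError(
                f"grid transforms differ: {ref.transform} vs {other.transform}"
            )
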