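"""Minimal georeferencing helpers: a 6-parameter affine transform and grid math.

Rasters in this package are north-up regular grids, so only the diagonal
terms of the affine are ever non-trivial; the full 6-parameter form is kept
for interoperability with GeoTIFF-style geotransforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator


@dataclass(frozen=True)
class Affine:
    """Affine map from (col, row) pixel space to map coordinates.

    x = a*col + b*row + c ;  y = d*col + e*row + f
    (col, row) refer to the pixel's upper-left corner, GDAL convention.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """North-up transform with pixel width ``xsize`` and height ``ysize`` (>0)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def xy(self, row: float, col: float, offset: str = "center") -> tuple[float, float]:
        """Map coordinates of a pixel; ``offset`` is 'center' or 'ul'."""
        if offset == "center":
            col, row = col + 0.5, row + 0.5
        x = self.a * col + self.b * row + self.c
        y = self.d * col + self.e * row + self.f
        return x, y

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Pixel indices containing map point (x, y); north-up grids only."""
        if self.b or self.d:
            raise ValueError("rowcol supports only north-up (non-rotated) transforms")
        col = int((x - self.c) // self.a)
        row = int((y - self.f) // self.e)
        return row, col

    def to_list(self) -> list[float]:
        return [self.a, self.b, self.c, self.d, self.e, self.f]

    @classmethod
    def from_list(cls, v: list[float]) -> "Affine":
        return cls(*map(float, v))

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_list())


def bounds(transform: Affine, shape: tuple[int, int]) -> tuple[float, float, float, float]:
    """(xmin, ymin, xmax, ymax) of a north-up raster with (rows, cols) shape."""
    rows, cols = shape
    x0, y0 = transform.xy(0, 0, offset="ul")
    x1, y1 = transform.xy(rows, cols, offset="ul")
    return min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)
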