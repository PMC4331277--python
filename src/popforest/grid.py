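"""Raster grid template shared by every layer in a mapping run.

All pipeline rasters live on one :class:`GridTemplate`: identical origin,
pixel size, dimensions and CRS.  Pixel-centre semantics throughout — a pixel
(row, col) represents the point at the centre of its cell, rows increase
southward from the top-left origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: CRS identifiers treated as geographic (degree) systems; buffering and
#: distance work is rejected on these.
_GEOGRAPHIC_TOKENS = ("4326", "wgs84", "longlat", "degree", "geographic")


def is_geographic(crs_id: str | None) -> bool:
    """Heuristically classify a CRS identifier as geographic (degrees)."""
    if crs_id is None:
        return False
    return any(tok in str(crs_id).lower() for tok in _GEOGRAPHIC_TOKENS)


@dataclass(frozen=True)
class GridTemplate:
    """The analysis raster frame every layer must align to.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates of the *top-left corner* of the grid (projected metres
        for metric work).
    pixel_width, pixel_height
        Cell size, positive scalars, in CRS units.
    n_rows, n_cols
        Grid dimensions.
    crs_id
        Free-form coordinate reference system identifier.  Synthetic
        landscapes use ``"local-metric"``.
    nodata
        Sentinel for missing cells in integer rasters; float rasters use NaN.
    """

    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float
    n_rows: int
    n_cols: int
    crs_id: str = "local-metric"
    nodata: float = -1.0

    def __post_init__(self) -> None:
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have at least one cell")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_height,
            self.origin_x + self.n_cols * self.pixel_width,
            self.origin_y,
        )

    @property
    def pixel_area(self) -> float:
        """Cell area in squared CRS units (m² on metric grids)."""
        return self.pixel_width * self.pixel_height

    @property
    def pixel_area_km2(self) -> float:
        return self.pixel_area / 1e6

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_area / 1e4

    def x_centers(self) -> np.ndarray:
        """X coordinate of each column's pixel centres."""
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_width

    def y_centers(self) -> np.ndarray:
        """Y coordinate of each row's pixel centres (decreasing)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_height

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) meshgrids of all pixel-centre coordinates, shape (n_rows, n_cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def window_for_bounds(
        self, minx: float, miny: float, maxx: float, maxy: float
    ) -> tuple[int, int, int, int]:
        """Half-open (row0, row1, col0, col1) window of pixels whose centres
        may fall inside the given bounds, clipped to the grid."""
        col0 = int(np.floor((minx - self.origin_x) / self.pixel_width - 0.5))
        col1 = int(np.ceil((maxx - self.origin_x) / self.pixel_width + 0.5))
        row0 = int(np.floor((self.origin_y - maxy) / self.pixel_height - 0.5))
        row1 = int(np.ceil((self.origin_y - miny) / self.pixel_height + 0.5))
        return (
            max(row0, 0),
            min(row1, self.n_rows),
            max(col0, 0),
            min(col1, self.n_cols),
        )

    # -- comparison -------------------------------------------------------

    def same_grid(self, other: "GridTemplate") -> bool:
        """Bit-exact frame equality ignoring the nodata sentinel."""
        return (
            self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.pixel_width == other.pixel_width
            and self.pixel_height == other.pixel_height
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.crs_id == other.crs_id
        )

    def require_same_grid(self, other: "GridTemplate", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what} is not aligned to the shared grid template")

    def require_metric(self, what: str = "operation") -> None:
        if is_geographic(self.crs_id):
            raise ValueError(
                f"{what} requires a projected metric CRS; "
                f"got geographic CRS {self.crs_id!r} — project the data first"
            )

    def with_nodata(self, nodata: float) -> "GridTemplate":
        return replace(self, nodata=nodata)
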