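"""Core grid and raster containers shared by every other module.

A :class:`GridSpec` describes a regular geographic (WGS84 lon/lat) grid by its
north-west corner, cell size and shape.  Cells are *edge registered*: value
``[r, c]`` covers the half-open box

    [x_min + c*cell, x_min + (c+1)*cell)  x  (y_max - (r+1)*cell, y_max - r*cell]

so a point exactly on a shared edge belongs to the east/south-ward cell, and
point-in-cell lookup is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: default nodata sentinel when file metadata is silent (common GIS convention)
DEFAULT_NODATA = -9999.0

_EDGE_TOL = 1e-9


class GridAlignmentError(ValueError):
    """Two rasters that must share a GridSpec do not."""


class PointOutsideError(ValueError):
    """A queried point falls outside the raster extent."""


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid in WGS84 (EPSG:4326), square cells in degrees."""

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.x_min < -180 - _EDGE_TOL or self.x_max > 180 + _EDGE_TOL:
            raise ValueError("grid longitudes exceed [-180, 180]")
        if self.y_max > 90 + _EDGE_TOL or self.y_min < -90 - _EDGE_TOL:
            raise ValueError("grid latitudes exceed [-90, 90]")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        return (
            self.x_min + (col + 0.5) * self.cell_size,
            self.y_max - (row + 0.5) * self.cell_size,
        )

    def rowcol_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing (lon, lat) under the half-open edge registration.

        West and north edges are inclusive, east and south edges belong to the
        neighbouring cell.  Raises :class:`PointOutsideError` beyond the grid.
        """
        col = int(np.floor((lon - self.x_min) / self.cell_size + _EDGE_TOL))
        row = int(np.floor((self.y_max - lat) / self.cell_size + _EDGE_TOL))
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise PointOutsideError(
                f"point ({lon}, {lat}) outside raster extent "
                f"[{self.x_min}, {self.x_max}] x [{self.y_min}, {self.y_max}]"
            )
        return row, col

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_max - other.y_max) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def with_factor(self, factor: int) -> "GridSpec":
        """Grid coarsened by an integer block factor (shape must divide)."""
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError("grid shape not divisible by factor")
        return replace(
            self,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            cell_size=self.cell_size * factor,
        )


@dataclass
class Raster:
    """A georeferenced 2-D array, categorical (integer classes) or continuous."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    kind: str = "continuous"  # "categorical" | "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "categorical":
            if not np.issubdtype(self.values.dtype, np.integer):
                v = self.values
                if np.issubdtype(v.dtype, np.floating) and np.all(
                    np.isnan(v) | (v == np.floor(v))
                ):
                    filled = np.where(np.isnan(v), self.nodata, v)
                    self.values = filled.astype(np.int64)
                else:
                    raise ValueError("categorical raster requires integer values")
            valid = self.values != int(self.nodata)
            if np.any(self.values[valid] < 0):
                raise ValueError("categorical values must be non-negative")

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        if np.issubdtype(self.values.dtype, np.floating):
            return ~np.isnan(self.values) & (self.values != self.nodata)
        return self.values != self.nodata

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=~self.valid_mask)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata, self.kind)

    def check_aligned(self, other: "Raster") -> None:
        if not self.grid.approx_equal(other.grid):
            raise GridAlignmentError("rasters do not share a GridSpec")


def check_stack_aligned(rasters) -> GridSpec:
    """Assert all rasters share one grid; return it."""
    rasters = list(rasters)
    if not rasters:
        raise ValueError("empty raster stack")
    grid = rasters[0].grid
    for r in rasters[1:]:
        if not grid.approx_equal(r.grid):
            raise GridAlignmentError("raster stack is misaligned")
    return grid


def stack_valid_mask(rasters) -> np.ndarray:
    """Cells valid in *every* raster of the stack."""
    rasters = list(rasters)
    mask = rasters[0].valid_mask.copy()
    for r in rasters[1:]:
        mask &= r.valid_mask
    return mask
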