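"""Crop-by-zone cross-tabulation.

The fine categorical zone raster is coarsened to the crop grid by modal
(block-majority) aggregation, crop layers expressed as fraction-of-cell are
converted to hectares with exact spherical latitude-band cell areas, and
harvested area is summed per zone (optionally within a region mask) into a
:class:`ZoneAreaTable` of thousand-hectare totals and percentage shares —
the machine-readable form of a crop histogram.

Display masking (drop fractions below a minimum, cap at a percentile) is a
map-product convenience only and never feeds the tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GridSpec, Raster

log = logging.getLogger("agrozone")

#: authalic Earth radius, km
EARTH_RADIUS_KM = 6371.0088

KM2_TO_HA = 100.0


@dataclass
class CropLayer:
    """One crop's harvested area per cell."""

    crop: str
    raster: Raster
    units: str = "hectares_per_cell"  # or "fraction_of_cell"

    def __post_init__(self) -> None:
        if self.units not in ("hectares_per_cell", "fraction_of_cell"):
            raise ValueError(f"unknown crop units {self.units!r}")
        vals = self.raster.values[self.raster.valid_mask]
        if vals.size and vals.min() < 0:
            raise ValueError("harvested area must be >= 0")
        if self.units == "fraction_of_cell" and vals.size and vals.max() > 1 + 1e-6:
            raise ValueError("fraction-of-cell values must be <= 1")


@dataclass
class RegionMask:
    """1 inside the region, 0 outside, on the analysis grid."""

    label: str
    mask: Raster

    def __post_init__(self) -> None:
        vals = self.mask.values[self.mask.valid_mask]
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("region mask values must be 0 or 1")


@dataclass
class ZoneAreaTable:
    """Per-zone harvested area (1000 ha) and percentage share for one
    crop x region combination."""

    crop: str
    region: str
    rows: pd.DataFrame  # columns zone_id, zone_name, area_kha, share_pct

    @property
    def total_kha(self) -> float:
        return float(self.rows["area_kha"].sum())

    def share_of(self, zone_id: int) -> float:
        sel = self.rows.loc[self.rows["zone_id"] == zone_id, "share_pct"]
        return float(sel.iloc[0]) if len(sel) else 0.0


@dataclass(frozen=True)
class DisplayParams:
    min_fraction: float = 0.0001
    cap_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_fraction < 1:
            raise ValueError("require 0 <= min_fraction < 1")
        if not 0 < self.cap_percentile <= 100:
            raise ValueError("require 0 < cap_percentile <= 100")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def cell_area(grid: GridSpec, row: int) -> float:
    """Area in km2 of any cell in ``row`` on a spherical Earth.

    Latitude band formula: ``A = R^2 * dlam * (sin(phi_top) - sin(phi_bot))``
    with the authalic radius; valid for every column since cells in a row
    share edge latitudes.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} out of range")
    phi_top = np.radians(grid.y_max - row * grid.cell_size)
    phi_bot = np.radians(grid.y_max - (row + 1) * grid.cell_size)
    dlam = np.radians(grid.cell_size)
    return float(EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bot)))


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Vector of per-row cell areas (km2), length ``n_rows``."""
    rows = np.arange(grid.n_rows)
    phi_top = np.radians(grid.y_max - rows * grid.cell_size)
    phi_bot = np.radians(grid.y_max - (rows + 1) * grid.cell_size)
    dlam = np.radians(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bot))


# ---------------------------------------------------------------------------
# resolution matching
# ---------------------------------------------------------------------------


def pad_to_multiple(raster: Raster, factor: int) -> Raster:
    """Pad on the south/east with nodata so both dimensions divide ``factor``."""
    g = raster.grid
    pad_r = (-g.n_rows) % factor
    pad_c = (-g.n_cols) % factor
    if pad_r == 0 and pad_c == 0:
        return raster.copy()
    fill = int(raster.nodata) if raster.kind == "categorical" else raster.nodata
    vals = np.pad(raster.values, ((0, pad_r), (0, pad_c)), constant_values=fill)
    grid = GridSpec(g.n_rows + pad_r, g.n_cols + pad_c, g.x_min, g.y_max, g.cell_size)
    return Raster(grid, vals, nodata=raster.nodata, kind=raster.kind)


def modal_aggregate(raster: Raster, factor: int) -> Raster:
    """Coarsen a categorical raster by block majority.

    Each output cell takes the most frequent non-nodata category of its
    ``factor x factor`` block, ties broken by the smallest category id;
    all-nodata blocks stay nodata.  Dimensions must divide ``factor``
    (use :func:`pad_to_multiple` first).
    """
    if raster.kind != "categorical":
        raise ValueError("modal aggregation applies to categorical rasters")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    g = raster.grid
    if g.n_rows % factor or g.n_cols % factor:
        raise ValueError(
            "raster shape not divisible by factor; pad_to_multiple or crop first"
        )
    if factor == 1:
        return raster.copy()
    nr, nc = g.n_rows // factor, g.n_cols // factor
    nodata = int(raster.nodata)
    blocks = (
        raster.values.reshape(nr, factor, nc, factor)
        .transpose(0, 2, 1, 3)
        .reshape(nr, nc, factor * factor)
    )
    out = np.full((nr, nc), nodata, dtype=np.int64)
    for i in range(nr):
        for j in range(nc):
            b = blocks[i, j]
            b = b[b != nodata]
            if b.size == 0:
                continue
            counts = np.bincount(b)
            out[i, j] = int(np.argmax(counts))  # argmax -> smallest id on ties
    return Raster(g.with_factor(factor), out, nodata=nodata, kind="categorical")


# ---------------------------------------------------------------------------
# unit conversion and zonal sums
# ---------------------------------------------------------------------------


def to_hectares(layer: CropLayer) -> CropLayer:
    """Convert a fraction-of-cell layer to hectares per cell (identity if
    already in hectares)."""
    if layer.units == "hectares_per_cell":
        return CropLayer(layer.crop, layer.raster.copy(), "hectares_per_cell")
    areas_ha = cell_areas(layer.raster.grid) * KM2_TO_HA
    vals = layer.raster.values.astype(np.float64)
    out = np.where(layer.raster.valid_mask, vals * areas_ha[:, None], layer.raster.nodata)
    return CropLayer(
        layer.crop,
        Raster(layer.raster.grid, out, nodata=layer.raster.nodata, kind="continuous"),
        "hectares_per_cell",
    )


def zonal_area(
    layer: CropLayer,
    zones: Raster,
    legend,
    region: RegionMask | None = None,
    region_label: str | None = None,
) -> ZoneAreaTable:
    """Sum harvested hectares per zone into a :class:`ZoneAreaTable`.

    Every non-nodata crop cell contributes — no display threshold is applied
    to totals.  Zones with zero area are omitted.  An empty intersection
    yields a zero-row table with a warning.
    """
    layer = to_hectares(layer)
    layer.raster.check_aligned(zones)
    mask = layer.raster.valid_mask & zones.valid_mask
    label = region_label or ("global" if region is None else region.label)
    if region is not None:
        layer.raster.check_aligned(region.mask)
        mask &= region.mask.valid_mask & (region.mask.values == 1)

    zone_ids = zones.values[mask].astype(np.int64)
    hectares = layer.raster.values[mask].astype(np.float64)
    cols = ["zone_id", "zone_name", "area_kha", "share_pct"]
    if zone_ids.size == 0 or hectares.sum() == 0:
        warnings.warn(f"empty crop/zone intersection for {layer.crop} in {label}")
        return ZoneAreaTable(layer.crop, label, pd.DataFrame(columns=cols))
    sums = np.bincount(zone_ids, weights=hectares)
    present = np.nonzero(sums > 0)[0]
    area_kha = sums[present] / 1000.0
    total = area_kha.sum()
    rows = pd.DataFrame(
        {
            "zone_id": present.astype(int),
            "zone_name": [legend.name_of(int(z)) for z in present],
            "area_kha": area_kha,
            "share_pct": 100.0 * area_kha / total,
        }
    )
    return ZoneAreaTable(layer.crop, label, rows)


def mask_for_display(layer: CropLayer, params: DisplayParams = DisplayParams()) -> Raster:
    """Map-display raster: drop tiny fractions, cap at a high percentile.

    Requires fraction-of-cell units.  Cells below ``min_fraction`` become
    nodata; survivors are capped at the ``cap_percentile``-th percentile of
    the retained values (linear interpolation between order statistics,
    numpy's default "type 7" rule).  Never used for area tables.
    """
    if layer.units != "fraction_of_cell":
        raise ValueError("display masking expects fraction_of_cell units")
    r = layer.raster
    keep = r.valid_mask & (r.values >= params.min_fraction)
    out = np.full(r.grid.shape, r.nodata, dtype=np.float64)
    if not keep.any():
        warnings.warn(f"no cell of {layer.crop} survives the display threshold")
        return Raster(r.grid, out, nodata=r.nodata, kind="continuous")
    retained = r.values[keep].astype(np.float64)
    cap = np.percentile(retained, params.cap_percentile)
    out[keep] = np.minimum(retained, cap)
    return Raster(r.grid, out, nodata=r.nodata, kind="continuous")


def crop_zone_matrix(
    layers: list[CropLayer],
    zones: Raster,
    legend,
    regions: list[RegionMask] | None = None,
) -> list[ZoneAreaTable]:
    """One :class:`ZoneAreaTable` per crop x (global + each region)."""
    tables = []
    for layer in layers:
        tables.append(zonal_area(layer, zones, legend))
        for region in regions or []:
            tables.append(zonal_area(layer, zones, legend, region=region))
    return tables


def tables_to_frame(tables: list[ZoneAreaTable]) -> pd.DataFrame:
    """Long-format CSV export: crop, region, zone_id, zone_name, area_kha,
    share_pct."""
    frames = []
    for t in tables:
        df = t.rows.copy()
        df.insert(0, "crop", t.crop)
        df.insert(1, "region", t.region)
        frames.append(df)
    cols = ["crop", "region", "zone_id", "zone_name", "area_kha", "share_pct"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
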