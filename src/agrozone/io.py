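"""File formats and tile export.

Supported formats: single-band GeoTIFF and ESRI ASCII grid for rasters (both
restricted to geographic WGS84), CSV for tables and site lists, GeoJSON for
regions, PNG for slippy-map tiles, YAML/JSON for configuration.

GeoTIFF georeferencing is carried by the standard tags: ModelPixelScale
(33550), ModelTiepoint (33922), the GeoKey directory (34735, checked for a
geographic model) and GDAL's nodata tag (42113).
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .core import DEFAULT_NODATA, GridSpec, Raster

log = logging.getLogger("agrozone")

# Web Mercator latitude limit: atan(sinh(pi)) in degrees
MERCATOR_LAT_MAX = 85.05112877980659

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey directory: version header + (GTModelType=geographic,
# GTRasterType=PixelIsArea, GeographicType=WGS84)
_GEOKEYS_WGS84 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the CLI."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


def load_config(path: str | os.PathLike) -> dict:
    """Read a YAML or JSON config file into a flat dict of CLI defaults."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


# ---------------------------------------------------------------------------
# raster read/write
# ---------------------------------------------------------------------------


def read_raster(path: str | os.PathLike, kind: str = "continuous") -> Raster:
    """Read a single-band GeoTIFF or ESRI ASCII grid as a :class:`Raster`.

    The file must be in geographic (lon/lat) WGS84 coordinates; projected
    rasters are rejected rather than silently reinterpreted.  Nodata defaults
    to -9999 when the file carries no metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".asc", ".txt"):
        return _read_ascii(path, kind)
    return _read_geotiff(path, kind)


def write_raster(raster: Raster, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a raster as GeoTIFF or ESRI ASCII (inferred from suffix if needed)."""
    path = Path(path)
    if format is None:
        format = "ascii" if path.suffix.lower() in (".asc", ".txt") else "geotiff"
    if format == "ascii":
        _write_ascii(raster, path)
    elif format == "geotiff":
        _write_geotiff(raster, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")


def _read_ascii(path: Path, kind: str) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_min, y_min = header["xllcorner"], header["yllcorner"]
    else:  # center registration
        x_min = header["xllcenter"] - cell / 2
        y_min = header["yllcenter"] - cell / 2
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    grid = GridSpec(n_rows, n_cols, x_min, y_min + n_rows * cell, cell)
    if kind == "categorical":
        values = np.rint(values).astype(np.int64)
        nodata = int(nodata)
    return Raster(grid, values, nodata=nodata, kind=kind)


def _write_ascii(raster: Raster, path: Path) -> None:
    g = raster.grid
    fmt = "%d" if raster.kind == "categorical" else "%.10g"
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_min:.10g}\n")
        fh.write(f"yllcorner {g.y_min:.10g}\n")
        fh.write(f"cellsize {g.cell_size:.10g}\n")
        fh.write(f"NODATA_value {raster.nodata:.10g}\n")
        np.savetxt(fh, raster.values, fmt=fmt)


def _read_geotiff(path: Path, kind: str) -> Raster:
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: multi-band GeoTIFF not supported")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multi-band GeoTIFF not supported")
        geokeys = page.tags.get(_TAG_GEOKEYS)
        if geokeys is not None:
            model_type = _geokey_value(geokeys.value, 1024)
            if model_type is not None and model_type != 2:
                raise ValueError(f"{path}: non-geographic CRS (GTModelType={model_type})")
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        tie = tie_tag.value
        # tiepoint maps raster (i, j, k) -> model (x, y, z)
        x_min = float(tie[3]) - float(tie[0]) * sx
        y_max = float(tie[4]) + float(tie[1]) * sy
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells not supported")
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else DEFAULT_NODATA
        values = page.asarray()
    grid = GridSpec(values.shape[0], values.shape[1], x_min, y_max, sx)
    if kind == "categorical":
        values = np.rint(values).astype(np.int64)
        nodata = int(nodata)
    else:
        values = values.astype(np.float64)
    return Raster(grid, values, nodata=nodata, kind=kind)


def _geokey_value(directory, key_id: int):
    d = np.asarray(directory).ravel()
    for i in range(4, len(d) - 3, 4):
        if d[i] == key_id and d[i + 1] == 0:
            return int(d[i + 3])
    return None


def _write_geotiff(raster: Raster, path: Path) -> None:
    g = raster.grid
    data = (
        raster.values.astype(np.int32)
        if raster.kind == "categorical"
        else raster.values.astype(np.float64)
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_min, g.y_max, 0.0)),
        (_TAG_GEOKEYS, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
        (_TAG_GDAL_NODATA, "s", 0, f"{raster.nodata:.10g}"),
    ]
    tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)


# ---------------------------------------------------------------------------
# XYZ tile export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TileParams:
    """Zoom range and pixel size of the slippy-map tile pyramid."""

    zoom_min: int = 0
    zoom_max: int = 10
    tile_size: int = 256

    def __post_init__(self) -> None:
        if not (0 <= self.zoom_min <= self.zoom_max <= 12):
            raise ValueError("require 0 <= zoom_min <= zoom_max <= 12")


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def export_xyz_tiles(raster: Raster, legend, params: TileParams, out_dir) -> list[Path]:
    """Render a categorical raster into a z/x/y.png Web Mercator tile tree.

    Each tile pixel takes the legend color of the category at its geographic
    location (nearest neighbour); pixels outside the raster or on nodata are
    fully transparent.  Returns the list of tile paths written.
    """
    if raster.kind != "categorical":
        raise ValueError("tiles require a categorical raster")
    out_dir = Path(out_dir)
    present = np.unique(raster.values[raster.valid_mask])
    known = {e.zone_id for e in legend.entries}
    missing = [int(c) for c in present if int(c) not in known]
    if missing:
        raise KeyError(f"category ids missing from legend: {missing}")

    max_id = int(present.max(initial=0))
    lut = np.zeros((max_id + 2, 4), dtype=np.uint8)  # last row = transparent
    for e in legend.entries:
        if e.zone_id <= max_id:
            lut[e.zone_id] = (*_hex_to_rgb(e.color), 255)

    g = raster.grid
    ts = params.tile_size
    written: list[Path] = []
    lat_top = min(g.y_max, MERCATOR_LAT_MAX)
    lat_bot = max(g.y_min, -MERCATOR_LAT_MAX)
    for z in range(params.zoom_min, params.zoom_max + 1):
        n = 2**z
        x_lo = max(0, int(math.floor((g.x_min + 180) / 360 * n)))
        x_hi = min(n - 1, int(math.floor((g.x_max + 180) / 360 * n - 1e-9)))
        y_lo = max(0, _lat_to_ytile(lat_top, n))
        y_hi = min(n - 1, _lat_to_ytile(lat_bot, n))
        for xt in range(x_lo, x_hi + 1):
            for yt in range(y_lo, y_hi + 1):
                rgba = _render_tile(raster, lut, xt, yt, z, ts)
                if rgba is None:
                    continue
                path = out_dir / str(z) / str(xt) / f"{yt}.png"
                path.parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(rgba, "RGBA").save(path)
                written.append(path)
    log.info("wrote %d tiles under %s", len(written), out_dir)
    return written


def _lat_to_ytile(lat: float, n: int) -> int:
    lat = min(max(lat, -MERCATOR_LAT_MAX), MERCATOR_LAT_MAX)
    phi = math.radians(lat)
    y = (1 - math.asinh(math.tan(phi)) / math.pi) / 2
    return min(n - 1, max(0, int(y * n)))


def _render_tile(raster: Raster, lut: np.ndarray, xt: int, yt: int, z: int, ts: int):
    n_px = 2**z * ts
    px = xt * ts + np.arange(ts) + 0.5
    py = yt * ts + np.arange(ts) + 0.5
    lon = px / n_px * 360.0 - 180.0
    lat = np.degrees(np.arctan(np.sinh(math.pi * (1 - 2 * py / n_px))))

    g = raster.grid
    col = np.floor((lon - g.x_min) / g.cell_size).astype(np.int64)
    row = np.floor((g.y_max - lat) / g.cell_size).astype(np.int64)
    ok_col = (col >= 0) & (col < g.n_cols)
    ok_row = (row >= 0) & (row < g.n_rows)
    if not ok_col.any() or not ok_row.any():
        return None
    inside = ok_row[:, None] & ok_col[None, :]
    rows = np.clip(row, 0, g.n_rows - 1)
    cols = np.clip(col, 0, g.n_cols - 1)
    cats = raster.values[np.ix_(rows, cols)]
    valid = inside & (cats != raster.nodata)
    idx = np.where(valid, cats, lut.shape[0] - 1)
    return lut[idx]


# ---------------------------------------------------------------------------
# tables, sites, regions
# ---------------------------------------------------------------------------


def read_sites(path: str | os.PathLike) -> list:
    """Read a site list CSV with columns name, lon, lat."""
    from .lookup import Site

    df = pd.read_csv(path)
    return [Site(str(r["name"]), float(r["lon"]), float(r["lat"])) for _, r in df.iterrows()]


def write_sites(sites, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [{"name": s.name, "lon": s.lon, "lat": s.lat} for s in sites]
    ).to_csv(path, index=False)


def read_region_geojson(path: str | os.PathLike, grid: GridSpec, label: str | None = None):
    """Rasterize a GeoJSON (multi)polygon onto ``grid`` by cell-center test."""
    import shapely
    from shapely.geometry import shape

    from .crosstab import RegionMask

    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        feats = gj["features"]
        geoms = [shape(f["geometry"]) for f in feats]
        geom = shapely.union_all(geoms)
        if label is None:
            label = feats[0].get("properties", {}).get("name", Path(path).stem)
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
        if label is None:
            label = gj.get("properties", {}).get("name", Path(path).stem)
    else:
        geom = shape(gj)
        label = label or Path(path).stem
    lon, lat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    inside = shapely.contains_xy(geom, lon.ravel(), lat.ravel()).reshape(grid.shape)
    mask = Raster(grid, inside.astype(np.int64), nodata=-9999, kind="categorical")
    return RegionMask(label=str(label), mask=mask)


def write_region_geojson(bounds: tuple[float, float, float, float], label: str,
                         path: str | os.PathLike) -> None:
    """Write a rectangular region (west, south, east, north) as GeoJSON."""
    w, s, e, n = bounds
    gj = {
        "type": "Feature",
        "properties": {"name": label},
        "geometry": {
            "type": "Polygon",
            "coordinates": [[[w, s], [e, s], [e, n], [w, n], [w, s]]],
        },
    }
    Path(path).write_text(json.dumps(gj))
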