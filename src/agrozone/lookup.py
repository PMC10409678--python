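"""Point-to-zone lookup and trial-site coverage reports.

``zone_at`` answers "which agroclimatic zone is this coordinate in";
``coverage_report`` compares the zones of a set of confined-field-trial
(CFT) sites against a crop's zone distribution and lists the major
production zones no site covers — the zones where a new trial would add
the most information for an environmental risk assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PointOutsideError, Raster
from .crosstab import ZoneAreaTable

log = logging.getLogger("agrozone")


@dataclass(frozen=True)
class Site:
    name: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180 <= self.lon <= 180:
            raise ValueError(f"site {self.name}: longitude {self.lon} out of range")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"site {self.name}: latitude {self.lat} out of range")


@dataclass
class CoverageReport:
    crop: str
    region: str
    sites: list[tuple[Site, int | None]]
    covered_zones: set[int]
    covered_share_pct: float
    uncovered_major_zones: list[tuple[int, float]]  # (zone_id, share_pct), desc

    def to_dict(self) -> dict:
        return {
            "crop": self.crop,
            "region": self.region,
            "sites": [
                {"name": s.name, "lon": s.lon, "lat": s.lat, "zone_id": z}
                for s, z in self.sites
            ],
            "covered_zones": sorted(self.covered_zones),
            "covered_share_pct": self.covered_share_pct,
            "uncovered_major_zones": [
                {"zone_id": z, "share_pct": p} for z, p in self.uncovered_major_zones
            ],
        }


def zone_at(site: Site, zones: Raster, legend) -> tuple[int, str] | None:
    """Zone id and name at a site, or ``None`` on a nodata cell.

    The containing cell follows the half-open registration (west/north edges
    inclusive); a point beyond the raster extent raises
    :class:`PointOutsideError`.
    """
    row, col = zones.grid.rowcol_of(site.lon, site.lat)
    zid = int(zones.values[row, col])
    if zid == int(zones.nodata):
        return None
    return zid, legend.name_of(zid)


def sites_report(sites: list[Site], zones: Raster, legend) -> pd.DataFrame:
    """Per-site lookup table in input order.

    Columns: name, lon, lat, zone_id, zone_name, error.  Sites on nodata
    get empty zone fields; out-of-extent sites get an error message instead
    of aborting the report.
    """
    if not sites:
        raise ValueError("empty site list")
    rows = []
    for s in sites:
        row = {"name": s.name, "lon": s.lon, "lat": s.lat,
               "zone_id": pd.NA, "zone_name": "", "error": ""}
        try:
            hit = zone_at(s, zones, legend)
        except PointOutsideError as exc:
            row["error"] = str(exc)
        else:
            if hit is not None:
                row["zone_id"], row["zone_name"] = hit
        rows.append(row)
    df = pd.DataFrame(rows)
    df["zone_id"] = df["zone_id"].astype("Int64")
    return df


def coverage_report(
    sites: list[Site],
    crop_table: ZoneAreaTable,
    zones: Raster,
    legend,
    major_threshold_pct: float = 5.0,
) -> CoverageReport:
    """Compare CFT site zones against a crop's zone distribution.

    ``covered_share_pct`` is the summed production share of the zones with
    at least one resolvable site; ``uncovered_major_zones`` are table zones
    at or above ``major_threshold_pct`` with no site, largest first — the
    recommended placements for new trials.
    """
    if crop_table.rows.empty:
        raise ValueError("coverage needs a non-empty crop zone table")
    resolved: list[tuple[Site, int | None]] = []
    for s in sites:
        try:
            hit = zone_at(s, zones, legend)
        except PointOutsideError:
            hit = None
        resolved.append((s, hit[0] if hit is not None else None))
    covered = {z for _, z in resolved if z is not None}
    if sites and not covered:
        log.warning("no site resolved to a zone; covered share is 0")
    share = float(
        crop_table.rows.loc[crop_table.rows["zone_id"].isin(covered), "share_pct"].sum()
    )
    uncovered = crop_table.rows.loc[
        ~crop_table.rows["zone_id"].isin(covered)
        & (crop_table.rows["share_pct"] >= major_threshold_pct)
    ].sort_values("share_pct", ascending=False)
    return CoverageReport(
        crop=crop_table.crop,
        region=crop_table.region,
        sites=resolved,
        covered_zones=covered,
        covered_share_pct=share,
        uncovered_major_zones=[
            (int(r.zone_id), float(r.share_pct)) for r in uncovered.itertuples()
        ],
    )
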