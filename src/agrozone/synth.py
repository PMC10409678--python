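"""Synthetic climate, crop, region and site generators with known ground
truth.

These stand in for the large hosted datasets a real deployment would use
(global climate normals, per-crop harvested-area grids) so the whole
pipeline is testable offline.  The climate generator produces the gross
structure the stratification relies on — temperature falling from equator
to pole, seasonal amplitude growing with latitude, a west-to-east moisture
gradient, PET tied to temperature — not realistic weather statistics.

``worked_fixture`` returns a fully hand-computed 6x6 example whose expected
cross-tabulation tables, coverage report and modal-aggregation matrix are
committed as literal data, so any regression in the pipeline is caught
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GridSpec, Raster
from .crosstab import CropLayer, RegionMask
from .lookup import Site
from .stratify import ClimateStack, StratumMap, ZoneLegend, LegendEntry

NODATA = -9999.0


@dataclass(frozen=True)
class SynthClimateParams:
    """Controls for the synthetic monthly climate.

    Defaults span the full observed range of the emulated quantities: sea
    level tropical means near 28 degC down to polar -12 degC, seasonal
    amplitude up to 18 degC at the poles, humid-to-arid precipitation from
    220 to 10 mm/month, and a 130 mm/month PET scale.
    """

    grid: GridSpec
    t_equator: float = 28.0
    t_pole: float = -12.0
    seasonal_amp_max: float = 18.0
    wet_west: float = 220.0
    dry_east: float = 10.0
    pet_base: float = 130.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SynthCropParams:
    """Zone-affinity crop generator: expected per-zone hectare shares equal
    ``zone_affinity``; each cell of a zone is planted independently with
    probability ``planted_cell_fraction``."""

    zone_affinity: dict[int, float]
    total_area: float = 1e6  # hectares
    planted_cell_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(self.zone_affinity.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("zone affinities must sum to 1")
        if any(v < 0 for v in self.zone_affinity.values()):
            raise ValueError("zone affinities must be >= 0")
        if self.total_area <= 0:
            raise ValueError("total_area must be > 0")


def _pet_factor(tmean: np.ndarray) -> np.ndarray:
    # monotone increasing in temperature, zero below -5 degC
    return np.clip((tmean + 5.0) / 25.0, 0.0, None)


def gen_climate(params: SynthClimateParams, n_bands: int | None = None) -> ClimateStack:
    """Synthesize 12 months of mean temperature, precipitation and PET.

    Continuous mode: temperature follows a linear equator-to-pole gradient
    with a hemisphere-phased seasonal cosine whose amplitude grows with
    ``|latitude|``; precipitation declines linearly west to east; PET is
    ``pet_base`` scaled by a monotone function of temperature (zero below
    -5 degC).  Gaussian noise of ``noise_sd`` is added to temperature and
    precipitation.

    Banded mode (``n_bands``): the latitudinal gradients are discretized
    into ``n_bands`` equal-height bands of constant climate — well-separated
    planted regimes for clustering-recovery experiments;
    :func:`band_labels` returns the matching ground truth.
    """
    g = params.grid
    rng = np.random.default_rng(params.seed)
    lat = g.lat_centers()[:, None] * np.ones((1, g.n_cols))
    lon_frac = ((g.lon_centers() - g.x_min) / (g.n_cols * g.cell_size))[None, :] * np.ones(
        (g.n_rows, 1)
    )
    if n_bands is None:
        lat_frac = np.abs(lat) / 90.0
        moisture_frac = lon_frac
    else:
        band = _band_index(g, n_bands)
        lat_frac = (band + 0.5) / n_bands
        moisture_frac = lat_frac  # band-constant moisture keeps regimes compact

    t_annual = params.t_equator + (params.t_pole - params.t_equator) * lat_frac
    amp = params.seasonal_amp_max * lat_frac
    peak_month = np.where(lat >= 0, 6.0, 0.0)  # July north, January south

    tmean, precip, pet = [], [], []
    for m in range(12):
        season = np.cos(2 * np.pi * (m - peak_month) / 12.0)
        t_m = t_annual + amp * season + rng.normal(0, params.noise_sd, g.shape)
        p_m = (
            params.wet_west + (params.dry_east - params.wet_west) * moisture_frac
            + rng.normal(0, params.noise_sd, g.shape)
        )
        p_m = np.clip(p_m, 0.0, None)
        pet_m = np.clip(params.pet_base * _pet_factor(t_m), 0.0, None)
        tmean.append(Raster(g, t_m, nodata=NODATA, kind="continuous"))
        precip.append(Raster(g, p_m, nodata=NODATA, kind="continuous"))
        pet.append(Raster(g, pet_m, nodata=NODATA, kind="continuous"))
    return ClimateStack(tmean=tmean, precip=precip, pet=pet)


def _band_index(grid: GridSpec, n_bands: int) -> np.ndarray:
    lat = grid.lat_centers()[:, None] * np.ones((1, grid.n_cols))
    frac = (grid.y_max - lat) / (grid.n_rows * grid.cell_size)
    return np.minimum((frac * n_bands).astype(np.int64), n_bands - 1)


def band_labels(grid: GridSpec, n_bands: int) -> np.ndarray:
    """Planted regime label (0..n_bands-1) per cell for banded climate."""
    return _band_index(grid, n_bands)


def gen_crop(
    zones: StratumMap, params: SynthCropParams, crop: str = "synthcrop"
) -> tuple[CropLayer, dict[int, float]]:
    """Crop layer whose expected per-zone hectare share equals the affinity.

    Within each zone, cells are planted independently with probability
    ``planted_cell_fraction`` and every planted cell of zone *z* carries
    ``w_z * total_area / (n_cells_z * p)`` hectares, so the zone total is
    binomial around ``w_z * total_area``.  Returns the layer (hectares per
    cell) and the realized per-zone hectare totals as ground truth.
    """
    zr = zones.zone_raster() if zones.stratum_to_zone else zones.strata
    rng = np.random.default_rng(params.seed)
    vals = np.where(zr.valid_mask, 0.0, NODATA)
    realized: dict[int, float] = {}
    p = params.planted_cell_fraction
    for z, w in sorted(params.zone_affinity.items()):
        cells = np.argwhere(zr.values == z)
        if len(cells) == 0:
            raise ValueError(f"zone {z} has positive affinity but no cells")
        if w == 0:
            realized[z] = 0.0
            continue
        planted = rng.random(len(cells)) < p
        per_cell = w * params.total_area / (len(cells) * p)
        rr, cc = cells[planted].T if planted.any() else (np.array([], int), np.array([], int))
        vals[rr, cc] = per_cell
        realized[z] = float(planted.sum() * per_cell)
    layer = CropLayer(crop, Raster(zr.grid, vals, nodata=NODATA, kind="continuous"),
                      "hectares_per_cell")
    return layer, realized


def gen_region(
    grid: GridSpec, bounds: tuple[float, float, float, float], label: str
) -> RegionMask:
    """Rectangular region mask: cells whose center lies in (west, south,
    east, north)."""
    w, s, e, n = bounds
    lon = grid.lon_centers()[None, :]
    lat = grid.lat_centers()[:, None]
    inside = (lon >= w) & (lon < e) & (lat > s) & (lat <= n)
    if not inside.any():
        raise ValueError(f"region {label!r} does not intersect the grid")
    mask = inside * np.ones(grid.shape, dtype=np.int64)
    return RegionMask(label=label, mask=Raster(grid, mask, nodata=-9999, kind="categorical"))


def gen_sites(
    zones: StratumMap, wanted_zone_ids: list[int], n: int, seed: int = 0
) -> tuple[list[Site], list[int]]:
    """``n`` sites at cell centers of the wanted zones (round-robin over
    zones, uniform over each zone's cells).  Returns the sites and the
    intended zone of each."""
    zr = zones.zone_raster() if zones.stratum_to_zone else zones.strata
    rng = np.random.default_rng(seed)
    cells_by_zone = {}
    for z in wanted_zone_ids:
        cells = np.argwhere(zr.values == z)
        if len(cells) == 0:
            raise ValueError(f"wanted zone {z} absent from the raster")
        cells_by_zone[z] = cells
    sites, intended = [], []
    for i in range(n):
        z = wanted_zone_ids[i % len(wanted_zone_ids)]
        r, c = cells_by_zone[z][rng.integers(len(cells_by_zone[z]))]
        lon, lat = zr.grid.cell_center(int(r), int(c))
        sites.append(Site(f"site-{i + 1}", lon, lat))
        intended.append(z)
    return sites, intended


# ---------------------------------------------------------------------------
# hand-computed worked fixture
# ---------------------------------------------------------------------------


@dataclass
class WorkedFixture:
    grid: GridSpec
    strata: StratumMap
    legend: ZoneLegend
    crop_a: CropLayer
    crop_b: CropLayer
    region: RegionMask
    sites: list[Site]
    expected: dict = field(default_factory=dict)


def worked_fixture() -> WorkedFixture:
    """A 6x6, 3-zone, 2-crop, 1-region, 4-site example, solved by hand.

    Strata raster (strata are zones, identity mapping)::

        1 1 1 1 2 2
        1 1 1 2 2 2
        1 1 2 2 2 2
        1 2 2 2 3 3
        2 2 2 3 3 3
        2 2 3 3 3 3

    Crop A hectares: 400 at (0,0) and 200 at (1,1) in zone 1; 200 at (2,3)
    and 100 at (1,5) in zone 2; 100 at (5,4) in zone 3.  Zone totals
    600/300/100 ha -> global shares 60/30/10 %.  The "west" region covers
    columns 0..3 (lon < 4): it keeps 600 ha of zone 1 and 200 ha of zone 2
    -> regional shares 75/25 %.  Crop B: 250 ha at (4,0) (zone 2) and 250
    ha at (5,2) (zone 3) -> 50/50 %.

    Sites sit at the centers of (0,0), (0,1) (zone 1) and (4,4), (5,5)
    (zone 3): covered crop-A share 60 + 10 = 70 %, the single uncovered
    major zone is zone 2 at 30 %.

    Modal aggregation of the strata at factor 2 (ties -> smallest id, e.g.
    the 2/2/3/3 block) gives::

        1 1 2
        1 2 2
        2 3 3
    """
    grid = GridSpec(n_rows=6, n_cols=6, x_min=0.0, y_max=6.0, cell_size=1.0)
    strata_vals = np.array(
        [
            [1, 1, 1, 1, 2, 2],
            [1, 1, 1, 2, 2, 2],
            [1, 1, 2, 2, 2, 2],
            [1, 2, 2, 2, 3, 3],
            [2, 2, 2, 3, 3, 3],
            [2, 2, 3, 3, 3, 3],
        ]
    )
    strata_raster = Raster(grid, strata_vals, nodata=-9999, kind="categorical")
    centroids = pd.DataFrame(
        {
            "gdd": [1200.0, 3600.0, 6200.0],
            "aridity": [0.9, 0.5, 0.25],
            "temp_seasonality": [9.0, 6.0, 2.0],
            "pet_seasonality": [55.0, 35.0, 12.0],
            "n_cells": [10, 17, 9],
        },
        index=pd.Index([1, 2, 3], name="stratum_id"),
    )
    strata = StratumMap(
        strata=strata_raster, centroids=centroids, stratum_to_zone={1: 1, 2: 2, 3: 3}
    )
    legend = ZoneLegend(
        [
            LegendEntry(1, "Cool and Mesic", "#1f77b4"),
            LegendEntry(2, "Warm and Dry", "#ff7f0e"),
            LegendEntry(3, "Hot and Moist", "#2ca02c"),
        ]
    )

    a = np.zeros((6, 6))
    a[0, 0], a[1, 1] = 400.0, 200.0  # zone 1
    a[2, 3], a[1, 5] = 200.0, 100.0  # zone 2
    a[5, 4] = 100.0  # zone 3
    crop_a = CropLayer("crop_a", Raster(grid, a, nodata=NODATA), "hectares_per_cell")

    b = np.zeros((6, 6))
    b[4, 0] = 250.0  # zone 2
    b[5, 2] = 250.0  # zone 3
    crop_b = CropLayer("crop_b", Raster(grid, b, nodata=NODATA), "hectares_per_cell")

    region = gen_region(grid, (0.0, 0.0, 4.0, 6.0), "west")
    sites = [
        Site("s1", 0.5, 5.5),
        Site("s2", 1.5, 5.5),
        Site("s3", 4.5, 1.5),
        Site("s4", 5.5, 0.5),
    ]

    expected = {
        "crop_a_global": pd.DataFrame(
            {
                "zone_id": [1, 2, 3],
                "zone_name": ["Cool and Mesic", "Warm and Dry", "Hot and Moist"],
                "area_kha": [0.6, 0.3, 0.1],
                "share_pct": [60.0, 30.0, 10.0],
            }
        ),
        "crop_a_west": pd.DataFrame(
            {
                "zone_id": [1, 2],
                "zone_name": ["Cool and Mesic", "Warm and Dry"],
                "area_kha": [0.6, 0.2],
                "share_pct": [75.0, 25.0],
            }
        ),
        "crop_b_global": pd.DataFrame(
            {
                "zone_id": [2, 3],
                "zone_name": ["Warm and Dry", "Hot and Moist"],
                "area_kha": [0.25, 0.25],
                "share_pct": [50.0, 50.0],
            }
        ),
        "modal_factor2": np.array([[1, 1, 2], [1, 2, 2], [2, 3, 3]]),
        "site_zones": [1, 1, 3, 3],
        "coverage": {
            "covered_zones": {1, 3},
            "covered_share_pct": 70.0,
            "uncovered_major_zones": [(2, 30.0)],
        },
    }
    return WorkedFixture(
        grid=grid,
        strata=strata,
        legend=legend,
        crop_a=crop_a,
        crop_b=crop_b,
        region=region,
        sites=sites,
        expected=expected,
    )
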