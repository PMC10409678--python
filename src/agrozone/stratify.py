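"""Agroclimatic stratification.

Four variables summarise a 12-month climate normal per cell:

* GDD  — growing degree days, sum over months of ``max(0, T - T_base) * days``
  (degC * day, base 0 degC by default);
* AI   — aridity index, annual precipitation / annual potential
  evapotranspiration (dimensionless);
* temperature seasonality — population SD of the 12 monthly means (degC);
* PET seasonality — coefficient of variation of monthly PET (percent).

Cells are z-scored per variable and clustered with k-means (Lloyd, fixed
seed) into S strata; stratum centroids are then grouped with Ward-linkage
agglomerative clustering into Z named zones.  Stratum and zone ids are
relabelled so they increase with centroid GDD (ties broken by aridity),
which makes label 1 the coldest unit.  This is a transparent, reproducible
stand-in for published global stratifications built from the same four
variables; it makes no attempt to replicate any published zone map.
"""

from __future__ import annotations

import colorsys
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .core import GridSpec, Raster, check_stack_aligned, stack_valid_mask

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

VARIABLE_NAMES = ("gdd", "aridity", "temp_seasonality", "pet_seasonality")

NODATA = -9999.0


@dataclass
class ClimateStack:
    """36 aligned monthly rasters: mean temperature, precipitation, PET."""

    tmean: list  # 12 continuous Rasters, degC
    precip: list  # 12 continuous Rasters, mm/month
    pet: list  # 12 continuous Rasters, mm/month

    def __post_init__(self) -> None:
        if not (len(self.tmean) == len(self.precip) == len(self.pet) == 12):
            raise ValueError("a climate stack needs 12 rasters per variable")
        self.grid = check_stack_aligned(self.tmean + self.precip + self.pet)

    @property
    def valid_mask(self) -> np.ndarray:
        return stack_valid_mask(self.tmean + self.precip + self.pet)


@dataclass
class ClimateVariables:
    """The four stratification variables on a common grid and nodata mask."""

    gdd: Raster
    aridity: Raster
    temp_seasonality: Raster
    pet_seasonality: Raster

    def __post_init__(self) -> None:
        check_stack_aligned(self.as_list())
        masks = [r.valid_mask for r in self.as_list()]
        if not all(np.array_equal(masks[0], m) for m in masks[1:]):
            raise ValueError("variable layers must share one nodata mask")

    def as_list(self) -> list:
        return [self.gdd, self.aridity, self.temp_seasonality, self.pet_seasonality]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.gdd.valid_mask


@dataclass(frozen=True)
class StratifyParams:
    n_strata: int = 125
    n_zones: int = 18
    t_base: float = 0.0
    seed: int = 0
    n_init: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.n_zones <= self.n_strata:
            raise ValueError("require 1 <= n_zones <= n_strata")


@dataclass
class StratumMap:
    """Stratum raster (ids 1..S), stratum->zone mapping and centroid table.

    ``centroids`` is indexed by stratum id with the four variables in
    original units plus ``n_cells``.
    """

    strata: Raster
    centroids: pd.DataFrame
    stratum_to_zone: dict[int, int] = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return len(self.centroids)

    def zone_raster(self) -> Raster:
        """Categorical raster of zone ids obtained through the mapping."""
        if not self.stratum_to_zone:
            raise ValueError("stratum_to_zone mapping is empty; run group_zones")
        max_id = int(self.strata.values.max())
        lut = np.full(max_id + 1, int(self.strata.nodata), dtype=np.int64)
        for s, z in self.stratum_to_zone.items():
            lut[s] = z
        vals = self.strata.values
        out = np.where(vals == self.strata.nodata, int(self.strata.nodata), lut[np.clip(vals, 0, max_id)])
        return Raster(self.strata.grid, out, nodata=self.strata.nodata, kind="categorical")

    def mapping_frame(self) -> pd.DataFrame:
        df = self.centroids.copy()
        df.insert(0, "stratum_id", df.index)
        df.insert(1, "zone_id", [self.stratum_to_zone.get(s, 0) for s in df.index])
        return df.reset_index(drop=True)


@dataclass(frozen=True)
class LegendEntry:
    zone_id: int
    name: str
    color: str  # "#RRGGBB"


@dataclass
class ZoneLegend:
    entries: list[LegendEntry]

    def __post_init__(self) -> None:
        ids = [e.zone_id for e in self.entries]
        names = [e.name for e in self.entries]
        colors = [e.color for e in self.entries]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("zone ids must be contiguous from 1")
        if len(set(names)) != len(names):
            raise ValueError("zone names must be unique")
        if len(set(colors)) != len(colors):
            raise ValueError("zone colors must be unique")

    def name_of(self, zone_id: int) -> str:
        return self.entries[zone_id - 1].name

    def color_of(self, zone_id: int) -> str:
        return self.entries[zone_id - 1].color

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            [{"zone_id": e.zone_id, "name": e.name, "color": e.color} for e in self.entries]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ZoneLegend":
        df = pd.read_csv(path)
        return cls([LegendEntry(int(r.zone_id), str(r.name), str(r.color)) for r in df.itertuples()])


# ---------------------------------------------------------------------------
# the four climate variables
# ---------------------------------------------------------------------------


def _monthly_cube(rasters, mask: np.ndarray) -> np.ndarray:
    """(12, n_valid) array of the stack restricted to ``mask``."""
    return np.stack([r.values[mask].astype(np.float64) for r in rasters])


def _as_raster(grid: GridSpec, mask: np.ndarray, vals: np.ndarray) -> Raster:
    out = np.full(grid.shape, NODATA)
    out[mask] = vals
    return Raster(grid, out, nodata=NODATA, kind="continuous")


def compute_gdd(tmean: list, t_base: float = 0.0) -> Raster:
    """Growing degree days (degC*day) from 12 monthly mean temperatures.

    Monthly approximation on a 365-day year: each month contributes
    ``max(0, T_m - t_base)`` times its calendar length.
    """
    grid = check_stack_aligned(tmean)
    mask = stack_valid_mask(tmean)
    cube = _monthly_cube(tmean, mask)
    gdd = (np.maximum(cube - t_base, 0.0) * DAYS_IN_MONTH[:, None]).sum(axis=0)
    return _as_raster(grid, mask, gdd)


def compute_aridity(precip: list, pet: list) -> Raster:
    """Aridity index: annual precipitation over annual PET (dimensionless).

    Cells with zero annual PET have an undefined index and become nodata.
    """
    grid = check_stack_aligned(list(precip) + list(pet))
    mask = stack_valid_mask(list(precip) + list(pet))
    p_sum = _monthly_cube(precip, mask).sum(axis=0)
    pet_sum = _monthly_cube(pet, mask).sum(axis=0)
    ai = np.full(p_sum.shape, NODATA)
    ok = pet_sum > 0
    ai[ok] = p_sum[ok] / pet_sum[ok]
    return _as_raster(grid, mask, ai)


def compute_temp_seasonality(tmean: list) -> Raster:
    """Temperature seasonality: population SD of 12 monthly means (degC)."""
    grid = check_stack_aligned(tmean)
    mask = stack_valid_mask(tmean)
    cube = _monthly_cube(tmean, mask)
    return _as_raster(grid, mask, cube.std(axis=0, ddof=0))


def compute_pet_seasonality(pet: list) -> Raster:
    """PET seasonality: coefficient of variation of monthly PET, percent.

    Cells with zero mean PET are nodata (CV undefined).
    """
    grid = check_stack_aligned(pet)
    mask = stack_valid_mask(pet)
    cube = _monthly_cube(pet, mask)
    mean = cube.mean(axis=0)
    cv = np.full(mean.shape, NODATA)
    ok = mean > 0
    cv[ok] = 100.0 * cube.std(axis=0, ddof=0)[ok] / mean[ok]
    return _as_raster(grid, mask, cv)


def compute_variables(stack: ClimateStack, t_base: float = 0.0) -> ClimateVariables:
    """All four variables with a single, intersected nodata mask."""
    layers = {
        "gdd": compute_gdd(stack.tmean, t_base),
        "aridity": compute_aridity(stack.precip, stack.pet),
        "temp_seasonality": compute_temp_seasonality(stack.tmean),
        "pet_seasonality": compute_pet_seasonality(stack.pet),
    }
    mask = np.logical_and.reduce([r.valid_mask for r in layers.values()])
    unified = {}
    for name, r in layers.items():
        vals = np.full(r.grid.shape, NODATA)
        vals[mask] = r.values[mask]
        unified[name] = Raster(r.grid, vals, nodata=NODATA, kind="continuous")
    return ClimateVariables(**unified)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate input: a variable is constant over valid cells")
    return (x - x.mean(axis=0)) / sd


def cluster_strata(variables: ClimateVariables, params: StratifyParams) -> StratumMap:
    """Partition valid cells into ``n_strata`` strata by k-means.

    Each variable is z-scored over valid cells before clustering so the
    partition is invariant to affine rescaling of any one variable.  Stratum
    ids 1..S are assigned in ascending order of centroid GDD in original
    units (ties: ascending aridity); centroids report the per-stratum means
    of the four variables in original units.
    """
    mask = variables.valid_mask
    X = np.column_stack([r.values[mask] for r in variables.as_list()])
    S = params.n_strata
    if X.shape[0] < S:
        raise ValueError(f"only {X.shape[0]} valid cells for {S} strata")
    Z = _zscore(X)
    km = KMeans(
        n_clusters=S,
        n_init=params.n_init,
        random_state=params.seed,
        algorithm="lloyd",
    ).fit(Z)
    labels = km.labels_

    means = np.vstack([X[labels == k].mean(axis=0) for k in range(S)])
    counts = np.bincount(labels, minlength=S)
    # relabel: ascending GDD, ties ascending aridity -> ids 1..S
    order = np.lexsort((means[:, 1], means[:, 0]))
    new_id = np.empty(S, dtype=np.int64)
    new_id[order] = np.arange(1, S + 1)

    strata_vals = np.full(variables.gdd.grid.shape, -9999, dtype=np.int64)
    strata_vals[mask] = new_id[labels]
    strata = Raster(variables.gdd.grid, strata_vals, nodata=-9999, kind="categorical")
    centroids = pd.DataFrame(
        means[order], columns=list(VARIABLE_NAMES), index=pd.Index(np.arange(1, S + 1), name="stratum_id")
    )
    centroids["n_cells"] = counts[order]
    return StratumMap(strata=strata, centroids=centroids)


def group_zones(strata: StratumMap, params: StratifyParams) -> StratumMap:
    """Group stratum centroids into ``n_zones`` zones by Ward clustering.

    Centroids are z-scored across strata; zones are relabelled 1..Z in
    ascending order of the zone mean of centroid GDD (original units).
    The mapping is total and surjective onto 1..Z.
    """
    S, Z = strata.n_strata, params.n_zones
    if Z > S:
        raise ValueError("n_zones may not exceed n_strata")
    C = strata.centroids[list(VARIABLE_NAMES)].to_numpy(dtype=np.float64)
    if Z == S:
        labels = np.arange(1, S + 1)
    elif Z == 1:
        labels = np.ones(S, dtype=np.int64)
    else:
        Czs = (C - C.mean(axis=0)) / np.where(C.std(axis=0, ddof=0) == 0, 1, C.std(axis=0, ddof=0))
        link = linkage(Czs, method="ward")
        labels = fcluster(link, t=Z, criterion="maxclust")
    # relabel by zone-mean GDD ascending
    gdd = C[:, 0]
    zone_means = {z: gdd[labels == z].mean() for z in np.unique(labels)}
    order = sorted(zone_means, key=lambda z: zone_means[z])
    remap = {old: new for new, old in enumerate(order, start=1)}
    mapping = {
        int(sid): remap[int(lab)]
        for sid, lab in zip(strata.centroids.index, labels)
    }
    return StratumMap(strata=strata.strata, centroids=strata.centroids, stratum_to_zone=mapping)


# ---------------------------------------------------------------------------
# legend
# ---------------------------------------------------------------------------

#: fixed base palette (colour-brewer-style qualitative hues); zones past its
#: length fall back to evenly spaced HSV hues, still deterministic.
BASE_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#c7c7c7",
    "#dbdb8d", "#9edae5", "#393b79", "#637939", "#8c6d31", "#843c39",
)


def make_legend(n_zones: int, names: list[str] | None = None) -> ZoneLegend:
    """Deterministic legend for ``n_zones`` zones with unique colors."""
    if names is not None:
        if len(names) != n_zones:
            raise ValueError("names length must equal n_zones")
        if len(set(names)) != n_zones:
            raise ValueError("duplicate zone names")
    else:
        names = [f"Zone {k}" for k in range(1, n_zones + 1)]
    colors = []
    for k in range(n_zones):
        if k < len(BASE_PALETTE):
            colors.append(BASE_PALETTE[k])
        else:
            r, g, b = colorsys.hsv_to_rgb((k * 0.61803398875) % 1.0, 0.65, 0.85)
            colors.append(f"#{int(r*255):02x}{int(g*255):02x}{int(b*255):02x}")
    return ZoneLegend(
        [LegendEntry(k + 1, names[k], colors[k]) for k in range(n_zones)]
    )
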