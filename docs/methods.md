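# Methods

## Stratification model

A cell's agroclimate is summarised by four annual variables computed from
12-month climate normals (mean temperature °C, precipitation mm/month,
potential evapotranspiration mm/month):

| variable | definition | units | notes |
|---|---|---|---|
| GDD | Σₘ max(0, Tₘ − T_base)·dₘ, dₘ = calendar month lengths (non-leap) | °C·day | T_base defaults to 0 °C, the convention of the global stratification literature this follows; configurable |
| aridity index | Σₘ Pₘ / Σₘ PETₘ | — | cells with zero annual PET are undefined → nodata |
| temperature seasonality | population SD (divisor 12) of the monthly means | °C | plain SD, *not* the ×100 bioclim scaling — documented so users comparing against bioclim variables can rescale |
| PET seasonality | 100·SD/mean of monthly PET | % | zero-mean cells → nodata |

A cell is valid only where all 36 input layers carry data *and* both
ratios are defined; the four variable layers share that single mask.

Clustering is deliberately simple and fully reproducible: each variable is
z-scored over valid cells (so the partition is invariant to affine
rescaling of any variable — units cannot matter), then Lloyd k-means with
a fixed seed and `n_init` restarts (default 10) assigns every valid cell
to one of *S* strata (default 125). Stratum centroids, reported as
per-stratum means in original units, are z-scored across strata and
grouped by Ward-linkage agglomerative clustering into *Z* zones (default
18). Published global stratifications built on these same four variables
used proprietary clustering pipelines; this package makes no attempt to
reproduce any published zone map — the counts are defaults, not a claim of
equivalence.

Labelling convention: stratum ids 1..S ascend with centroid GDD, ties
broken by ascending aridity (the two variables that dominate zone
interpretation); zone ids 1..Z ascend with the unweighted mean GDD of
their member strata. Label 1 is therefore always the coldest unit, which
makes runs comparable across parameter choices.

## Cross-tabulation

Resolution matching goes one way only: the *fine categorical* raster is
coarsened to the crop grid by modal aggregation (most frequent non-nodata
category per block, ties to the smallest id, all-nodata blocks stay
nodata). Grids must nest by an integer factor; `pad_to_multiple` pads with
nodata, and non-nested grids are an error rather than a silent resample,
because interpolating a categorical map or warping an area density hides
area errors.

Cell areas use the spherical latitude-band formula
A = R²·Δλ·(sin φ_top − sin φ_bot) with the authalic radius
R = 6371.0088 km. The error against an ellipsoidal Earth is below 0.3 %,
and the closed form gives two exact testable identities: north/south
symmetry and telescoping of the global sum to 4πR².

Zonal tables sum *all* non-nodata hectares — the display conveniences
(dropping fractions below 10⁻⁴ of a cell, roughly 1 ha at the equator on a
5-arcmin grid, and capping at the 90th percentile) apply only to map
products and are asserted never to change a table. The percentile is
numpy's default linear interpolation between order statistics ("type 7").
Zones with zero area are omitted from tables; shares are percentages of
the table total.

## Site coverage

Point-in-cell lookup uses edge registration with half-open cells: west and
north edges inclusive, so a point on a shared edge belongs to the
east/south-ward cell, and every in-bounds point resolves to exactly one
cell. Coverage of a set of trial sites is the summed production share of
the zones their cells fall in; "major uncovered zones" are table zones at
or above a threshold share (default 5 % — the narrative notion of a major
production zone has no canonical cutoff, so it is a parameter) with no
site, sorted by share. Site lookups should use the finest zone raster
available, not the modally aggregated one.

## Synthetic data

The climate generator produces the monotone structure the stratification
needs and nothing more: a linear equator-to-pole temperature gradient
(28 °C to −12 °C by default), a seasonal cosine whose amplitude grows with
|latitude| (up to 18 °C) and peaks in July north of the equator and
January south of it, a west-to-east precipitation decline (220 to
10 mm/month), and PET tied to temperature through a monotone ramp that is
zero below −5 °C (so aridity and GDD co-vary the way real agroclimate
does, which is what makes clustering recovery a meaningful test).
Gaussian noise (default SD 1 °C / 1 mm) is added to temperature and
precipitation; all generators are deterministic under a fixed seed.

In *banded* mode the latitudinal gradients are discretized into equal
bands of constant climate — planted regimes for recovery experiments. The
hemisphere phasing means monthly fields differ across the equator within a
band while the annual variables are near-constant (calendar month lengths
break exact symmetry in GDD by well under a percent of the between-band
separation).

The crop generator plants each cell of zone *z* independently with
probability *p* (default 0.3) and gives every planted cell
w_z·total/(n_z·p) hectares, so the expected zone share equals the affinity
w_z and the realized share fluctuates binomially — with ≥10⁴ planted cells
the sampling error is well inside ±2 percentage points. The realized
per-zone totals are emitted as ground truth.

What passing these tests does *not* show: the generators have no spatial
autocorrelation beyond the gradients, no orography, coastlines or missing
data patterns, and the crop layers have no spatial clumping within zones.
Recovery results on them demonstrate correctness of the computations, not
performance of the stratification on real climate data.

## Worked fixture

A 6×6, 3-zone, 2-crop, 1-region, 4-site example is committed with all
expected tables, the coverage report and the factor-2 modal aggregation
matrix hard-coded from manual arithmetic (the derivations are in the
fixture docstring), so regressions are caught against literal data rather
than recomputed values. Comparisons run at 10⁻¹² relative tolerance: the
expectations are exact decimals, but percentage shares divide by a total
accumulated in floating point, which perturbs the last bit or two.

## Numerical and format choices

* GeoTIFFs are written and read through tifffile with the standard
  georeferencing tags (ModelPixelScale, ModelTiepoint, GeoKey directory,
  GDAL nodata); only single-band geographic WGS84 rasters are accepted,
  and projected inputs raise instead of being reinterpreted. Nodata
  defaults to −9999 when metadata is silent.
* Tiles follow the slippy-map scheme: Web Mercator z/x/y.png, 256 px
  default, nearest-neighbour colour lookup, transparent outside
  data, latitudes clipped at ±85.051129°. The tile projection and size
  are web-mapping conventions, chosen here as the de-facto standard.
* Categorical round-trips are bit-exact (int32 in GeoTIFF); continuous
  ASCII round-trips are good to 10⁻⁶ relative (`%.10g` formatting).
* Crop-statistics group rows are an explicit boolean column, not name
  parsing; selection ties break alphabetically; the combined-share
  denominator counts individual (non-group) crops only.

## Problem sizes

The test-suite and acceptance runs use grids from 6×6 (hand-checked) to
180×360 (1° global) cells, 3-regime recovery over 5 seeds at 36×72, and
affinity recovery with ~10⁴ planted cells; these sizes already put every
statistical check deep inside its tolerance, and the pipeline is linear in
cell count for larger inputs.

## Known limitations

* No raster reprojection or warping; inputs must share (or integer-nest
  into) one geographic grid.
* PET is an input, not modelled (no Thornthwaite/Hargreaves); yield and
  net-primary-production layers are out of scope.
* Region polygons are rasterized by cell-center membership — cells
  straddling a boundary are wholly in or out.
* Geocoding by place name is out of scope; sites are coordinates.
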