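# agrozone

Agroclimatic zonation and crop cross-tabulation for planning and assessing
confined field trials (CFTs) of genetically engineered crops.

Regulatory environmental risk assessments often require field-trial data
from the country where cultivation is intended, even when equivalent trials
were already run elsewhere under the same agroclimate. The scientific basis
for *data transportability* — reusing those remote trials — is that the
main environmental difference between well-managed CFT locations is
agroclimate. `agrozone` provides the computational pieces needed to make
that argument quantitative:

* **stratify** — derive four agroclimatic variables from monthly climate
  normals and cluster them into strata grouped into named zones:
  growing degree days GDD = Σₘ max(0, Tₘ − T_base)·dₘ, aridity index
  AI = Σₘ Pₘ / Σₘ PETₘ, temperature seasonality (population SD of monthly
  means, °C) and PET seasonality (CV, %). Cells are z-scored and
  partitioned by k-means into *S* strata; stratum centroids are grouped by
  Ward-linkage clustering into *Z* zones, labelled in order of increasing
  GDD.
* **crosstab** — coarsen the categorical zone raster to a crop grid by
  modal (block-majority) aggregation, convert fraction-of-cell harvested
  area to hectares with exact spherical cell areas
  A = R²·Δλ·(sin φ_top − sin φ_bot), and sum hectares per zone into tables
  of thousand-hectare totals and percentage shares, globally or per region.
* **lookup** — resolve coordinates to zones and report which share of a
  crop's production the zones of a set of CFT sites cover, plus the major
  uncovered zones where a new trial would add the most information.
* **cropselect** — pick the top-*k* individual crops per metric (harvested
  area, production value, food supply) and merge the lists.
* **synth** — synthetic climate/crop/region/site generators with known
  ground truth, so the whole pipeline is testable without external data.

Intended users: risk assessors, trial planners and tool builders who need
reproducible zone statistics rather than an interactive map.

## Worked example

The library ships a hand-computed 6×6 example (three zones, two crops,
one region, four trial sites):

```python
import agrozone as az

fx = az.worked_fixture()
zones = fx.strata.zone_raster()
table = az.zonal_area(fx.crop_a, zones, fx.legend)
print(table.rows)
report = az.coverage_report(fx.sites, table, zones, fx.legend)
print(report.covered_share_pct, report.uncovered_major_zones)
```

prints

```
   zone_id       zone_name  area_kha  share_pct
0        1  Cool and Mesic       0.6       60.0
1        2    Warm and Dry       0.3       30.0
2        3   Hot and Moist       0.1       10.0
70.00000000000001 [(2, 30.000000000000004)]
```

Crop A has 600/300/100 ha in zones 1/2/3 (60/30/10 % of its harvested
area). The four sites sit in zones 1 and 3, so existing trials cover 70 %
of production; the one major uncovered zone is zone 2 with a 30 % share —
the recommended placement for a new trial.

The same pipeline is available from the shell:

```sh
agrozone --seed 5 simulate --preset three-band --grid 360x180 --out-dir sim/
agrozone crosstab --zones sim/strata.tif --mapping sim/mapping.csv \
    --legend sim/legend.csv --crop demo=sim/crop_synthcrop.tif --out table.csv
agrozone coverage --table table.csv --crop demo --sites sim/sites.csv \
    --zones sim/strata.tif --mapping sim/mapping.csv --legend sim/legend.csv \
    --out coverage.json
```

Other subcommands: `stratify`, `histogram`, `lookup`, `select-crops`,
`tiles` (z/x/y.png Web Mercator pyramid).

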