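import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.integrate import dblquad

import agrozone as az
from agrozone.crosstab import EARTH_RADIUS_KM


def _cat(grid, vals, nodata=-9999):
    return az.Raster(grid, np.asarray(vals, dtype=np.int64), nodata=nodata, kind="categorical")


def _crop_ha(grid, vals, name="c"):
    return az.CropLayer(name, az.Raster(grid, np.asarray(vals, float), nodata=-9999.0),
                        "hectares_per_cell")


def brute_force_modal(values, nodata, factor):
    nr, nc = values.shape[0] // factor, values.shape[1] // factor
    out = np.full((nr, nc), nodata, dtype=np.int64)
    for i in range(nr):
        for j in range(nc):
            block = values[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            cats = block[block != nodata]
            if cats.size == 0:
                continue
            uniq, counts = np.unique(cats, return_counts=True)
            out[i, j] = uniq[np.argmax(counts == counts.max())]  # smallest id on ties
    return out


class TestCellArea:
    def test_hemispheric_symmetry(self):
        grid = az.GridSpec(18, 36, -180.0, 90.0, 10.0)
        for row in range(9):
            assert az.cell_area(grid, row) == pytest.approx(
                az.cell_area(grid, 17 - row), rel=1e-12
            )

    def test_global_sum_is_sphere_area(self):
        grid = az.GridSpec(36, 72, -180.0, 90.0, 5.0)
        total = sum(az.cell_area(grid, r) * grid.n_cols for r in range(grid.n_rows))
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_KM**2, rel=1e-12)

    def test_quadrature_oracle_equatorial_5_arcmin_cell(self):
        cell = 5.0 / 60.0
        grid = az.GridSpec(int(round(180 / cell)), int(round(360 / cell)), -180.0, 90.0, cell)
        row = grid.n_rows // 2 - 1  # touches the equator from the north
        expected, _ = dblquad(
            lambda phi, lam: EARTH_RADIUS_KM**2 * np.cos(phi),
            0.0, np.radians(cell),
            0.0, np.radians(cell),
        )
        assert az.cell_area(grid, row) == pytest.approx(expected, rel=1e-6)

    def test_row_out_of_range(self, small_grid):
        with pytest.raises(IndexError):
            az.cell_area(small_grid, 4)

    def test_vector_matches_scalar(self, small_grid):
        vec = az.cell_areas(small_grid)
        assert vec.tolist() == [az.cell_area(small_grid, r) for r in range(4)]


class TestModalAggregate:
    @pytest.mark.parametrize(
        "block, expected",
        [
            ([[3, 3], [3, 3]], 3),  # uniform
            ([[1, 2], [2, 2]], 2),  # clear majority
            ([[1, 1], [2, 2]], 1),  # tie -> smallest id
            ([[-9999, -9999], [-9999, 7]], 7),  # nodata ignored
            ([[-9999, -9999], [-9999, -9999]], -9999),  # all nodata stays nodata
        ],
    )
    def test_single_block(self, block, expected):
        grid = az.GridSpec(2, 2, 0.0, 2.0, 1.0)
        out = az.modal_aggregate(_cat(grid, block), 2)
        assert out.values[0, 0] == expected
        assert out.grid.cell_size == 2.0 and out.grid.shape == (1, 1)

    def test_non_divisible_shape_rejected(self):
        grid = az.GridSpec(3, 3, 0.0, 3.0, 1.0)
        with pytest.raises(ValueError, match="divisible"):
            az.modal_aggregate(_cat(grid, np.ones((3, 3))), 2)

    def test_pad_to_multiple_then_aggregate(self):
        grid = az.GridSpec(3, 3, 0.0, 3.0, 1.0)
        padded = az.pad_to_multiple(_cat(grid, np.ones((3, 3))), 2)
        assert padded.grid.shape == (4, 4)
        assert (padded.values == -9999).sum() == 7
        out = az.modal_aggregate(padded, 2)
        assert np.array_equal(out.values, [[1, 1], [1, 1]])

    def test_factor_10_brute_force_oracle(self, rng):
        grid = az.GridSpec(100, 100, 0.0, 50.0, 0.5)
        vals = rng.integers(0, 5, size=(100, 100))
        vals[rng.random((100, 100)) < 0.2] = -9999
        r = _cat(grid, vals)
        out = az.modal_aggregate(r, 10)
        assert np.array_equal(out.values, brute_force_modal(vals, -9999, 10))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        data=hst.integers(0, 2**31 - 1),
        factor=hst.sampled_from([1, 2, 3, 5]),
        n_cats=hst.integers(1, 6),
    )
    def test_property_equals_brute_force(self, data, factor, n_cats):
        rng = np.random.default_rng(data)
        shape = (factor * rng.integers(1, 5), factor * rng.integers(1, 5))
        vals = rng.integers(0, n_cats, size=shape)
        vals[rng.random(shape) < 0.3] = -9999
        grid = az.GridSpec(shape[0], shape[1], 0.0, float(shape[0]) * 0.1, 0.1)
        out = az.modal_aggregate(_cat(grid, vals), factor)
        assert np.array_equal(out.values, brute_force_modal(vals, -9999, int(factor)))


class TestToHectares:
    def test_zero_fraction_is_zero(self, small_grid):
        layer = az.CropLayer(
            "c", az.Raster(small_grid, np.zeros(small_grid.shape), nodata=-9999.0),
            "fraction_of_cell",
        )
        assert np.all(az.to_hectares(layer).raster.values == 0)

    def test_full_cell_fraction_gives_cell_area(self, small_grid):
        vals = np.zeros(small_grid.shape)
        vals[2, 1] = 1.0
        layer = az.CropLayer("c", az.Raster(small_grid, vals, nodata=-9999.0), "fraction_of_cell")
        out = az.to_hectares(layer)
        assert out.raster.values[2, 1] == pytest.approx(az.cell_area(small_grid, 2) * 100)

    def test_min_display_fraction_is_about_one_hectare_at_equator(self):
        # 0.0001 of an equatorial 5-arcmin cell is around 1 ha
        cell = 5.0 / 60.0
        grid = az.GridSpec(2, 2, 0.0, cell, cell)  # rows straddle the equator
        vals = np.full(grid.shape, 1e-4)
        layer = az.CropLayer("c", az.Raster(grid, vals, nodata=-9999.0), "fraction_of_cell")
        ha = az.to_hectares(layer).raster.values[0, 0]
        assert ha == pytest.approx(1.0, rel=0.2)

    def test_hectares_layer_is_identity(self, small_grid, rng):
        layer = _crop_ha(small_grid, rng.random(small_grid.shape))
        out = az.to_hectares(layer)
        assert np.array_equal(out.raster.values, layer.raster.values)

    def test_fraction_above_one_rejected(self, small_grid):
        with pytest.raises(ValueError):
            az.CropLayer(
                "c", az.Raster(small_grid, np.full(small_grid.shape, 1.5), nodata=-9999.0),
                "fraction_of_cell",
            )


class TestZonalArea:
    def test_single_zone_totals(self, small_grid):
        vals = np.zeros(small_grid.shape)
        vals[0, 0], vals[3, 5] = 1000.0, 234.0
        t = az.zonal_area(_crop_ha(small_grid, vals), _cat(small_grid, np.ones(small_grid.shape)),
                          az.make_legend(1))
        assert len(t.rows) == 1
        assert t.rows.area_kha.iloc[0] == pytest.approx(1.234)
        assert t.rows.share_pct.iloc[0] == pytest.approx(100.0)

    def test_two_equal_zones_split_evenly(self, small_grid):
        zones = np.ones(small_grid.shape, dtype=int)
        zones[:, 3:] = 2
        vals = np.zeros(small_grid.shape)
        vals[0, 0] = 500.0
        vals[0, 4] = 500.0
        t = az.zonal_area(_crop_ha(small_grid, vals), _cat(small_grid, zones), az.make_legend(2))
        assert t.rows.share_pct.tolist() == pytest.approx([50.0, 50.0])

    def test_brute_force_oracle(self, rng):
        grid = az.GridSpec(20, 20, 0.0, 20.0, 1.0)
        zones = rng.integers(1, 5, size=(20, 20))
        vals = rng.random((20, 20)) * 100
        vals[rng.random((20, 20)) < 0.1] = -9999.0
        t = az.zonal_area(_crop_ha(grid, vals), _cat(grid, zones), az.make_legend(4))
        for zid in range(1, 5):
            total = 0.0
            for i in range(20):
                for j in range(20):
                    if zones[i, j] == zid and vals[i, j] != -9999.0:
                        total += vals[i, j]
            assert t.share_of(zid) == pytest.approx(
                100 * total / vals[vals != -9999.0].sum(), rel=1e-12
            )

    def test_conservation(self, rng):
        grid = az.GridSpec(15, 15, 0.0, 15.0, 1.0)
        zones = rng.integers(1, 4, size=(15, 15))
        vals = rng.random((15, 15)) * 50
        t = az.zonal_area(_crop_ha(grid, vals), _cat(grid, zones), az.make_legend(3))
        assert t.total_kha * 1000 == pytest.approx(vals.sum(), rel=1e-12)

    def test_region_additivity(self, rng):
        grid = az.GridSpec(10, 10, 0.0, 10.0, 1.0)
        zones = _cat(grid, rng.integers(1, 4, size=(10, 10)))
        layer = _crop_ha(grid, rng.random((10, 10)) * 10)
        legend = az.make_legend(3)
        west = az.gen_region(grid, (0.0, 0.0, 5.0, 10.0), "west")
        east = az.gen_region(grid, (5.0, 0.0, 10.0, 10.0), "east")
        g = az.zonal_area(layer, zones, legend)
        w = az.zonal_area(layer, zones, legend, region=west)
        e = az.zonal_area(layer, zones, legend, region=east)
        for zid in range(1, 4):
            parts = sum(
                float(t.rows.loc[t.rows.zone_id == zid, "area_kha"].sum()) for t in (w, e)
            )
            assert parts == pytest.approx(
                float(g.rows.loc[g.rows.zone_id == zid, "area_kha"].sum()), rel=1e-12
            )

    def test_empty_intersection_warns(self, small_grid):
        zones = _cat(small_grid, np.ones(small_grid.shape))
        layer = _crop_ha(small_grid, np.zeros(small_grid.shape))
        with pytest.warns(UserWarning):
            t = az.zonal_area(layer, zones, az.make_legend(1))
        assert t.rows.empty

    def test_grid_mismatch_rejected(self, small_grid):
        other = az.GridSpec(4, 6, 0.0, 40.0, 9.0)
        zones = _cat(other, np.ones(other.shape))
        with pytest.raises(Exception):
            az.zonal_area(_crop_ha(small_grid, np.ones(small_grid.shape)), zones, az.make_legend(1))


class TestDisplayMask:
    def _fraction_layer(self, grid, vals):
        return az.CropLayer("c", az.Raster(grid, np.asarray(vals, float), nodata=-9999.0),
                            "fraction_of_cell")

    def test_all_below_threshold_warns_all_nodata(self, small_grid):
        layer = self._fraction_layer(small_grid, np.full(small_grid.shape, 1e-5))
        with pytest.warns(UserWarning):
            out = az.mask_for_display(layer)
        assert not out.valid_mask.any()

    def test_percentile_cap(self):
        grid = az.GridSpec(2, 5, 0.0, 2.0, 1.0)
        vals = np.full((2, 5), 0.001)
        vals[0, 0] = 0.5
        out = az.mask_for_display(self._fraction_layer(grid, vals),
                                  az.DisplayParams(min_fraction=0.0001, cap_percentile=90))
        retained = np.sort(np.r_[np.full(9, 0.001), 0.5])
        expected_cap = np.percentile(retained, 90)  # type-7 linear interpolation
        assert out.values[0, 0] == pytest.approx(expected_cap)
        assert expected_cap == pytest.approx(0.001 + 0.1 * (0.5 - 0.001))

    def test_identity_params(self, small_grid, rng):
        vals = rng.random(small_grid.shape) * 0.9
        layer = self._fraction_layer(small_grid, vals)
        out = az.mask_for_display(layer, az.DisplayParams(min_fraction=0.0, cap_percentile=100))
        np.testing.assert_allclose(out.values, vals)

    def test_masking_never_changes_tables(self, rng):
        grid = az.GridSpec(12, 12, 0.0, 12.0, 1.0)
        zones = _cat(grid, rng.integers(1, 4, size=(12, 12)))
        vals = rng.random((12, 12)) * 0.002  # many below the display floor
        layer = self._fraction_layer(grid, vals)
        legend = az.make_legend(3)
        before = az.zonal_area(layer, zones, legend)
        az.mask_for_display(layer)
        after = az.zonal_area(layer, zones, legend)
        pd.testing.assert_frame_equal(before.rows, after.rows)


class TestCropZoneMatrix:
    def test_full_grid_region_equals_global(self, rng):
        grid = az.GridSpec(8, 8, 0.0, 8.0, 1.0)
        zones = _cat(grid, rng.integers(1, 3, size=(8, 8)))
        layer = _crop_ha(grid, rng.random((8, 8)) * 5)
        whole = az.gen_region(grid, (0.0, 0.0, 8.0, 8.0), "all")
        tables = az.crop_zone_matrix([layer], zones, az.make_legend(2), [whole])
        assert [t.region for t in tables] == ["global", "all"]
        pd.testing.assert_frame_equal(tables[0].rows, tables[1].rows)

    def test_disjoint_crops_land_in_own_zone(self, small_grid):
        zones = np.ones(small_grid.shape, dtype=int)
        zones[:, 3:] = 2
        a = np.zeros(small_grid.shape)
        a[0, 0] = 100.0
        b = np.zeros(small_grid.shape)
        b[0, 5] = 100.0
        tables = az.crop_zone_matrix(
            [_crop_ha(small_grid, a, "a"), _crop_ha(small_grid, b, "b")],
            _cat(small_grid, zones), az.make_legend(2),
        )
        assert tables[0].share_of(1) == pytest.approx(100.0)
        assert tables[1].share_of(2) == pytest.approx(100.0)

    def test_csv_frame_columns(self, small_grid, rng):
        zones = _cat(small_grid, np.ones(small_grid.shape))
        layer = _crop_ha(small_grid, rng.random(small_grid.shape))
        df = az.tables_to_frame(az.crop_zone_matrix([layer], zones, az.make_legend(1)))
        assert df.columns.tolist() == [
            "crop", "region", "zone_id", "zone_name", "area_kha", "share_pct",
        ]
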