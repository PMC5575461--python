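"""Speciation-rate mapping: thinning, rate joins, IDW, regional summaries,
and raster I/O."""
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box as shapely_box

from andesdiv.ratemap import (
    RateRaster,
    attach_tip_rates,
    idw_interpolate,
    read_raster,
    summarize_regions,
    thin_occurrences,
    write_raster,
)


def occ_df(rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


class TestThinning:
    def test_single_cell_keeps_one(self):
        occ = occ_df([("s", -70.1 - 0.01 * i, 2.1) for i in range(5)])
        assert len(thin_occurrences(occ, cell=0.5, seed=0)) == 1

    def test_three_cells_keep_three(self):
        occ = occ_df([("s", -70.1, 2.1), ("s", -70.7, 2.1), ("s", -70.1, 3.3)])
        assert len(thin_occurrences(occ, cell=0.5, seed=0)) == 3

    def test_half_open_boundary_convention(self):
        # lon exactly 0.5 belongs to the cell starting at 0.5
        occ = occ_df([("s", 0.499999, 0.1), ("s", 0.5, 0.1)])
        assert len(thin_occurrences(occ, cell=0.5, seed=0)) == 2

    def test_seed_changes_selection_never_count(self):
        rng = np.random.default_rng(0)
        occ = occ_df([
            ("s", float(lon), float(lat))
            for lon, lat in rng.uniform(-5, 5, size=(300, 2))
        ])
        counts = set()
        picks = set()
        for seed in range(5):
            thinned = thin_occurrences(occ, cell=0.5, seed=seed)
            counts.add(len(thinned))
            picks.add(tuple(sorted(zip(thinned.lon, thinned.lat))))
        assert len(counts) == 1
        assert len(picks) > 1

    @given(st.lists(
        st.tuples(st.floats(-179, 179, allow_nan=False),
                  st.floats(-89, 89, allow_nan=False)),
        min_size=1, max_size=60,
    ))
    def test_count_equals_occupied_cells(self, pts):
        occ = occ_df([("s", lon, lat) for lon, lat in pts])
        cells = {(np.floor(lon / 0.5), np.floor(lat / 0.5)) for lon, lat in pts}
        assert len(thin_occurrences(occ, cell=0.5, seed=3)) == len(cells)


class TestAttachRates:
    def test_exact_join(self):
        occ = occ_df([("a", 0, 0)] * 6 + [("b", 1, 1)] * 4)
        rated = attach_tip_rates(occ, {"a": 0.1, "b": 0.3})
        assert (rated.loc[rated.species == "a", "rate"] == 0.1).all()
        assert (rated.loc[rated.species == "b", "rate"] == 0.3).all()

    def test_strict_mode_names_missing_species(self):
        with pytest.raises(KeyError, match="ghost"):
            attach_tip_rates(occ_df([("ghost", 0, 0)]), {"a": 0.1})

    def test_lenient_mode_drops_and_warns(self):
        occ = occ_df([("a", 0, 0), ("ghost", 1, 1), ("ghost", 2, 2)])
        with pytest.warns(UserWarning, match="dropped 2 records"):
            rated = attach_tip_rates(occ, {"a": 0.1}, strict=False)
        assert len(rated) == 1


class TestIDW:
    def test_single_point_constant_field(self):
        pts = pd.DataFrame({"species": ["s"], "lon": [0.2], "lat": [0.2],
                            "rate": [0.2]})
        raster = idw_interpolate(pts, cell=0.5)
        vals = raster.values[np.isfinite(raster.values)]
        np.testing.assert_allclose(vals, 0.2)

    def test_equidistant_midpoint_average(self):
        # two points symmetric about a cell centre on the same parallel
        pts = pd.DataFrame({
            "species": ["a", "b"],
            "lon": [0.25 - 0.6, 0.25 + 0.6],
            "lat": [0.25, 0.25],
            "rate": [0.1, 0.3],
        })
        raster = idw_interpolate(pts, cell=0.5,
                                 mask=shapely_box(-1.0, 0.0, 1.5, 0.5))
        lon_idx = np.argmin(np.abs(raster.lon_centers() - 0.25))
        lat_idx = np.argmin(np.abs(raster.lat_centers() - 0.25))
        assert raster.values[lat_idx, lon_idx] == pytest.approx(0.2, abs=1e-12)

    def test_cell_centre_on_point_takes_exact_rate(self):
        pts = pd.DataFrame({
            "species": ["a", "b", "c"],
            "lon": [0.25, 1.5, -0.7],
            "lat": [0.25, 0.4, 0.2],
            "rate": [0.42, 0.1, 0.9],
        })
        raster = idw_interpolate(pts, cell=0.5)
        lon_idx = np.argmin(np.abs(raster.lon_centers() - 0.25))
        lat_idx = np.argmin(np.abs(raster.lat_centers() - 0.25))
        assert raster.values[lat_idx, lon_idx] == pytest.approx(0.42, abs=0.0)

    def test_values_bounded_by_input_extrema(self, rng):
        pts = pd.DataFrame({
            "species": [f"s{i}" for i in range(30)],
            "lon": rng.uniform(-3, 3, 30),
            "lat": rng.uniform(-3, 3, 30),
            "rate": rng.uniform(0.05, 0.5, 30),
        })
        raster = idw_interpolate(pts, cell=0.25)
        vals = raster.values[np.isfinite(raster.values)]
        assert vals.min() >= pts.rate.min() - 1e-12
        assert vals.max() <= pts.rate.max() + 1e-12

    def test_small_power_all_neighbours_approaches_global_mean(self, rng):
        pts = pd.DataFrame({
            "species": [f"s{i}" for i in range(12)],
            "lon": rng.uniform(-2, 2, 12),
            "lat": rng.uniform(-2, 2, 12),
            "rate": rng.uniform(0.1, 0.4, 12),
        })
        raster = idw_interpolate(pts, cell=1.0, power=1e-3, k_neighbors=12)
        vals = raster.values[np.isfinite(raster.values)]
        np.testing.assert_allclose(vals, pts.rate.mean(), rtol=0.01)

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            idw_interpolate(pd.DataFrame(columns=["species", "lon", "lat", "rate"]))


class TestRegionSummaries:
    def test_constant_rate_region(self):
        pts = pd.DataFrame({"species": list("abcd"), "lon": [0.1, 0.2, 0.3, 0.4],
                            "lat": [0.1] * 4, "rate": [0.25] * 4})
        out = summarize_regions(pts, {"box": shapely_box(0, 0, 1, 1)}, seed=0)
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.25)
        assert row.ci_hi - row.ci_lo == pytest.approx(0.0, abs=1e-12)

    def test_pooled_mean_invariant_to_region_relabelling(self, rng):
        pts = pd.DataFrame({
            "species": [f"s{i}" for i in range(40)],
            "lon": rng.uniform(0, 2, 40),
            "lat": rng.uniform(0, 2, 40),
            "rate": rng.uniform(0.1, 0.5, 40),
        })
        regions = {"west": shapely_box(0, 0, 1, 2), "east": shapely_box(1, 0, 2, 2)}
        flipped = {"west": regions["east"], "east": regions["west"]}
        a = summarize_regions(pts, regions, seed=1)
        b = summarize_regions(pts, flipped, seed=1)
        pooled_a = (a["mean"] * a["n"]).sum() / a["n"].sum()
        pooled_b = (b["mean"] * b["n"]).sum() / b["n"].sum()
        assert pooled_a == pytest.approx(pooled_b)

    def test_empty_region_warns_with_nan_row(self):
        pts = pd.DataFrame({"species": ["a"], "lon": [0.5], "lat": [0.5],
                            "rate": [0.2]})
        with pytest.warns(UserWarning, match="no points"):
            out = summarize_regions(
                pts, {"far": shapely_box(50, 50, 51, 51)}, seed=0
            )
        assert np.isnan(out.iloc[0]["mean"]) and out.iloc[0]["n"] == 0


class TestRasterIO:
    @pytest.fixture
    def raster(self, rng):
        vals = rng.uniform(0, 1, (4, 5))
        vals[0, 0] = np.nan
        vals[3, 4] = np.nan
        return RateRaster(-72.0, -5.5, 0.5, 5, 4, vals)

    @pytest.mark.parametrize("ext", ["asc", "csv"])
    def test_round_trip_bit_exact(self, raster, tmp_path, ext):
        path = tmp_path / f"r.{ext}"
        write_raster(raster, str(path))
        back = read_raster(str(path))
        np.testing.assert_array_equal(back.values, raster.values)
        assert (back.lon0, back.lat0, back.cell) == (
            raster.lon0, raster.lat0, raster.cell)

    def test_nodata_cells_preserved(self, raster, tmp_path):
        path = tmp_path / "r.asc"
        write_raster(raster, str(path))
        back = read_raster(str(path))
        np.testing.assert_array_equal(
            np.isnan(back.values), np.isnan(raster.values))

    def test_csv_row_count(self, raster, tmp_path):
        path = tmp_path / "r.csv"
        write_raster(raster, str(path))
        with open(path) as fh:
            fh.readline()
            df = pd.read_csv(fh)
        assert len(df) == raster.n_rows * raster.n_cols

    def test_unknown_format_rejected(self, raster, tmp_path):
        with pytest.raises(ValueError):
            write_raster(raster, str(tmp_path / "r.tif"), fmt="geotiff")
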