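"""Regional averages, elevation-band analysis and series comparison."""

import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from pollenmat import GriddedField, RasterGrid, RegionSpec, compare_series, elevation_bands, load_regions, regional_series
from pollenmat.summaries import default_elevation_caps, save_regions


def make_field(values, timeslice=1000.0, lon0=10.0, lat0=46.0, res=0.1):
    values = np.asarray(values, dtype=float)
    nr, nc = values.shape
    return GriddedField(
        values=values,
        lon=lon0 + res * np.arange(nc),
        lat=lat0 - res * np.arange(nr),
        timeslice=timeslice,
    )


def whole_region(field, rid=1, name="all"):
    pad = 0.05
    return RegionSpec(rid, name, box(field.lon.min() - pad, field.lat.min() - pad,
                                     field.lon.max() + pad, field.lat.max() + pad))


class TestRegionalSeries:
    def test_uniform_field(self):
        f = make_field(np.full((5, 6), 55.0))
        out = regional_series([f], [whole_region(f)])
        assert out["mean"].iloc[0] == pytest.approx(55.0)
        assert out["sd"].iloc[0] == pytest.approx(0.0)

    def test_two_region_split(self):
        vals = np.hstack([np.full((4, 3), 30.0), np.full((4, 3), 70.0)])
        f = make_field(vals)
        west = RegionSpec(1, "west", box(9.9, 45.5, 10.25, 46.1))
        east = RegionSpec(2, "east", box(10.25, 45.5, 10.65, 46.1))
        out = regional_series([f], [west, east]).set_index("region")
        assert out.loc[1, "mean"] == pytest.approx(30.0)
        assert out.loc[2, "mean"] == pytest.approx(70.0)

    def test_matches_bruteforce_cosine_weighting(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, (6, 7))
        f = make_field(vals)
        region = whole_region(f)
        out = regional_series([f], [region])
        num = den = 0.0
        for i, lat in enumerate(f.lat):
            for j, lon in enumerate(f.lon):
                if region.polygon.contains_properly(__import__("shapely").geometry.Point(lon, lat)) or region.polygon.contains(__import__("shapely").geometry.Point(lon, lat)):
                    w = np.cos(np.radians(lat))
                    num += w * vals[i, j]
                    den += w
        assert out["mean"].iloc[0] == pytest.approx(num / den, abs=1e-9)

    def test_masked_cells_excluded(self):
        vals = np.full((4, 4), 60.0)
        f = make_field(vals)
        f.water_mask[0, :] = True
        f.values[0, :] = 0.0  # excluded water row must not drag the mean
        out = regional_series([f], [whole_region(f)])
        assert out["mean"].iloc[0] == pytest.approx(60.0)

    def test_empty_region_missing(self):
        f = make_field(np.full((3, 3), 50.0))
        far = RegionSpec(9, "far", box(50.0, 50.0, 51.0, 51.0))
        out = regional_series([f], [far])
        assert np.isnan(out["mean"].iloc[0]) and out["n_cells"].iloc[0] == 0

    def test_mean_bounded_by_extrema(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(10, 90, (5, 5))
        f = make_field(vals)
        out = regional_series([f], [whole_region(f)])
        assert vals.min() <= out["mean"].iloc[0] <= vals.max()


class TestElevationBands:
    def _setup(self, cover_of_elev, timeslice=1000.0):
        n = 30
        elev = np.tile(np.linspace(0.0, 2900.0, n), (4, 1))
        dem = RasterGrid(elev, lon_min=10.0, lat_max=46.0, res=0.1)
        f = make_field(cover_of_elev(elev), timeslice=timeslice)
        return f, dem

    def test_threshold_track_at_crossing(self):
        """Cover decreasing with elevation, crossing 50 % at 2,000 m: the
        track is the upper edge of the band containing 2,000 m."""
        f, dem = self._setup(lambda e: np.clip(50.0 + 0.05 * (2000.0 - e), 0, 100))
        out = elevation_bands([f], dem)
        track = out[out["is_track"]]["mean"].iloc[0]
        assert track == 2000.0

    def test_no_band_above_threshold(self):
        f, dem = self._setup(lambda e: np.full_like(e, 20.0))
        out = elevation_bands([f], dem)
        assert np.isnan(out[out["is_track"]]["mean"].iloc[0])

    def test_caps_before_11000(self):
        f, dem = self._setup(lambda e: np.full_like(e, 60.0), timeslice=11_500.0)
        out = elevation_bands([f], dem)
        high = out[(~out["is_track"]) & (out["band_low"] >= 2400.0)]
        assert high["capped"].all()
        assert high["mean"].isna().all()

    def test_cap_schedule(self):
        assert default_elevation_caps(11_500.0) == 2400.0
        assert default_elevation_caps(10_500.0) == 2600.0
        assert default_elevation_caps(5_000.0) == 2800.0

    def test_bands_contiguous_nonoverlapping(self):
        from pollenmat.summaries import elevation_band_edges

        edges = elevation_band_edges(3000.0)
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            assert hi1 == lo2

    def test_monotone_track_under_uniform_decline(self):
        """A field declining uniformly in time yields a non-increasing
        treeline track toward the present."""
        fields = []
        n = 30
        elev = np.tile(np.linspace(0.0, 2900.0, n), (4, 1))
        dem = RasterGrid(elev, lon_min=10.0, lat_max=46.0, res=0.1)
        for i, t in enumerate((8000.0, 6000.0, 4000.0, 2000.0)):
            cover = np.clip(50.0 + 0.05 * (2400.0 - 300.0 * i - elev), 0, 100)
            fields.append(make_field(cover, timeslice=t))
        out = elevation_bands(fields, dem)
        track = out[out["is_track"]].sort_values("timeslice", ascending=False)["mean"]
        vals = track.dropna().to_numpy()
        assert (np.diff(vals) <= 0).all()


class TestCompareSeries:
    def _series(self, centers, values):
        return pd.DataFrame({"age": centers, "value": values})

    def test_identical_series(self):
        centers = np.arange(11_700.0, -1, -200.0)
        vals = 50.0 + 20.0 * np.sin(centers / 2000.0)
        out = compare_series(self._series(centers, vals), self._series(centers, vals))
        overall = out[out["period"] == "overall"].iloc[0]
        assert overall["r"] == pytest.approx(1.0)
        assert overall["mad"] == pytest.approx(0.0, abs=1e-9)
        assert overall["slope"] == pytest.approx(1.0)
        assert overall["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset(self):
        centers = np.arange(10_000.0, -1, -200.0)
        vals = 40.0 + 10.0 * np.cos(centers / 1500.0)
        out = compare_series(self._series(centers, vals), self._series(centers, vals + 10.0))
        overall = out[out["period"] == "overall"].iloc[0]
        assert overall["r"] == pytest.approx(1.0)
        assert overall["mad"] == pytest.approx(10.0)

    def test_antiphased_series_negative_r(self):
        centers = np.arange(8_000.0, -1, -200.0)
        vals = 50.0 + 20.0 * np.sin(centers / 1000.0)
        out = compare_series(self._series(centers, vals), self._series(centers, 100.0 - vals))
        assert out[out["period"] == "overall"]["r"].iloc[0] < 0

    def test_rebinning_averages_points_within_window(self):
        # points at 1050 and 950 BP fall in the window centered on 1000 BP
        # (width 200 yr, half-open toward older): binned mean = 50
        mat = self._series([1050.0, 950.0, 850.0, 650.0, 450.0], [40.0, 60.0, 80.0, 70.0, 60.0])
        ref = self._series([1000.0, 800.0, 600.0, 400.0], [50.0, 80.0, 70.0, 60.0])
        out = compare_series(mat, ref)
        overall = out[out["period"] == "overall"].iloc[0]
        assert overall["n"] == 4
        assert overall["mad"] == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_windows_missing(self):
        mat = self._series([1000.0, 800.0], [40.0, 50.0])
        ref = self._series([1000.0, 800.0], [45.0, 55.0])
        out = compare_series(mat, ref)
        assert np.isnan(out[out["period"] == "overall"]["r"].iloc[0])

    def test_symmetry_of_r_and_mad(self):
        centers = np.arange(6_000.0, -1, -200.0)
        rng = np.random.default_rng(5)
        a = self._series(centers, rng.uniform(20, 80, len(centers)))
        b = self._series(centers, rng.uniform(20, 80, len(centers)))
        ab = compare_series(a, b)
        ba = compare_series(b, a)
        for period in ("overall", "early", "mid", "late"):
            ra = ab[ab["period"] == period].iloc[0]
            rb = ba[ba["period"] == period].iloc[0]
            if np.isfinite(ra["r"]):
                assert ra["r"] == pytest.approx(rb["r"], abs=1e-9)
                assert ra["mad"] == pytest.approx(rb["mad"], abs=1e-9)


class TestRegionIO:
    def test_geojson_roundtrip(self, tmp_path):
        regions = [
            RegionSpec(1, "west", box(0.0, 0.0, 1.0, 1.0)),
            RegionSpec(2, "east", box(1.0, 0.0, 2.0, 1.0)),
        ]
        save_regions(regions, tmp_path / "r.geojson")
        back = load_regions(tmp_path / "r.geojson")
        assert [r.name for r in back] == ["west", "east"]
        assert back[0].polygon.equals(regions[0].polygon)

    def test_overlapping_regions_rejected(self, tmp_path):
        regions = [
            RegionSpec(1, "a", box(0.0, 0.0, 1.5, 1.0)),
            RegionSpec(2, "b", box(1.0, 0.0, 2.0, 1.0)),
        ]
        save_regions(regions, tmp_path / "r.geojson")
        with pytest.raises(ValueError, match="overlap"):
            load_regions(tmp_path / "r.geojson")
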