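"""Timeslice binning and thin-plate-spline space-time interpolation."""

import numpy as np
import pandas as pd
import pytest

from pollenmat import RasterGrid, assign_timeslices, error_grid, fit_tps, map_timeslice
from pollenmat.mapping import (
    FittingError,
    InterpolationConfig,
    TimesliceScheme,
    TPSInterpolant,
    map_slices,
)


class TestTimesliceScheme:
    def test_49_centers(self):
        assert len(TimesliceScheme().centers) == 49

    def test_center_hit(self):
        assert TimesliceScheme().assign(12_000.0) == 12_000.0

    def test_boundary_goes_to_younger_slice(self):
        assert TimesliceScheme().assign(11_875.0) == 11_750.0

    def test_terminal_window_covers_185_years(self):
        s = TimesliceScheme()
        assert s.assign(125.0) == 0.0
        assert s.assign(-60.0) == 0.0
        assert s.assign(-61.0) is None

    def test_out_of_range_unassigned(self):
        s = TimesliceScheme()
        assert s.assign(12_126.0) is None
        assert s.assign(12_125.0) == 12_000.0

    def test_partition_property(self):
        """Every in-range age lands in exactly one slice within 125 yr of it."""
        s = TimesliceScheme()
        rng = np.random.default_rng(0)
        ages = rng.uniform(-60.0, 12_125.0, 500)
        for a in ages:
            c = s.assign(a)
            assert c is not None
            assert abs(a - c) <= 125.0 + 1e-9
            others = [x for x in s.centers if x != c and abs(a - x) < 125.0]
            assert others == []

    def test_assign_timeslices_frame(self):
        df = pd.DataFrame({"age": [12_000.0, 11_875.0, 20_000.0]})
        out = assign_timeslices(df)
        assert out["timeslice"].tolist()[:2] == [12_000.0, 11_750.0]
        assert np.isnan(out["timeslice"].iloc[2])


def tps_phi(r):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r**2 * np.log(r)
    return np.where(r > 0, out, 0.0)


def dense_tps_solve(points, values, queries, smoothing=0.0):
    """Independent dense solve of the thin-plate system
    [[K + lam I, P], [P^T, 0]] [w; c] = [v; 0]."""
    n, d = points.shape
    K = tps_phi(np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2))
    P = np.hstack([np.ones((n, 1)), points])
    A = np.zeros((n + d + 1, n + d + 1))
    A[:n, :n] = K + smoothing * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.concatenate([values, np.zeros(d + 1)])
    sol = np.linalg.solve(A, rhs)
    w, c = sol[:n], sol[n:]
    Kq = tps_phi(np.linalg.norm(queries[:, None, :] - points[None, :, :], axis=2))
    Pq = np.hstack([np.ones((len(queries), 1)), queries])
    return Kq @ w + Pq @ c


class TestTPS:
    def test_affine_reproduction(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, (20, 3))
        vals = 2.0 + 3.0 * pts[:, 0] - 1.5 * pts[:, 1] + 0.5 * pts[:, 2]
        f = fit_tps(pts, vals, smoothing=0.0)
        q = rng.uniform(0, 1, (10, 3))
        expected = 2.0 + 3.0 * q[:, 0] - 1.5 * q[:, 1] + 0.5 * q[:, 2]
        np.testing.assert_allclose(f(q), expected, atol=1e-6)

    def test_zero_smoothing_interpolates(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (15, 2))
        vals = rng.uniform(0, 100, 15)
        f = fit_tps(pts, vals, smoothing=0.0)
        np.testing.assert_allclose(f(pts), vals, atol=1e-8)

    @pytest.mark.parametrize("smoothing", [0.0, 0.5])
    def test_matches_dense_linear_solve(self, smoothing):
        """12-point toy set against an independent dense-system oracle."""
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 2, (12, 2))
        vals = rng.uniform(0, 100, 12)
        q = rng.uniform(0.2, 1.8, (8, 2))
        f = fit_tps(pts, vals, smoothing=smoothing)
        np.testing.assert_allclose(f(q), dense_tps_solve(pts, vals, q, smoothing), atol=1e-6)

    def test_duplicate_points_averaged(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.5, 0.5]])
        vals = np.array([10.0, 30.0, 50.0, 60.0, 70.0, 40.0])
        f = fit_tps(pts, vals, smoothing=0.0)
        assert f(np.array([[0.0, 0.0]]))[0] == pytest.approx(20.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FittingError):
            TPSInterpolant(np.eye(3), np.zeros(3))

    def test_gcv_returns_valid_interpolant(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1, (12, 2))
        vals = 50.0 + 10.0 * pts[:, 0] + rng.normal(0, 1, 12)
        f = fit_tps(pts, vals, smoothing="gcv")
        assert np.isfinite(f(pts)).all()


def small_dem(n=20, value=300.0):
    vals = np.full((n, n), value)
    return RasterGrid(vals, lon_min=10.0, lat_max=46.0, res=0.05)


def site_frame(values, timeslice=1000.0, n=None):
    n = n or len(values)
    rng = np.random.default_rng(9)
    return pd.DataFrame(
        {
            "site": [f"s{i}" for i in range(n)],
            "lon": np.linspace(10.1, 10.8, n),
            "lat": 45.2 + 0.7 * rng.random(n),
            "elevation": np.full(n, 300.0),
            "prediction": values,
            "se": np.full(n, 2.0),
            "timeslice": timeslice,
        }
    )


class TestMapTimeslice:
    def test_constant_sites_give_constant_field(self):
        df = site_frame([55.0] * 8)
        f = map_timeslice(df, small_dem(), InterpolationConfig(low_density_radius_km=500.0))
        assert f is not None
        np.testing.assert_allclose(f.values[~f.combined_mask()], 55.0, atol=1e-6)

    def test_low_density_mask_contract(self):
        """Removing a site masks its formerly covered neighborhood."""
        cfg = InterpolationConfig(low_density_radius_km=15.0, min_sites=5)
        df = site_frame([50.0, 55.0, 60.0, 65.0, 70.0, 75.0])
        f_all = map_timeslice(df, small_dem(), cfg)
        removed = df[df["site"] != "s5"]
        f_less = map_timeslice(removed, small_dem(), cfg)
        gained = f_less.low_density_mask & ~f_all.low_density_mask
        assert gained.any()

    def test_too_few_sites_skipped(self):
        df = site_frame([50.0, 60.0, 70.0])
        assert map_timeslice(df, small_dem(), InterpolationConfig(min_sites=6)) is None

    def test_gradient_recovered(self):
        """An east-west linear cover gradient survives gridding within 10 %."""
        n = 10
        lons = np.linspace(10.05, 10.95, n)
        truth = lambda lon: 20.0 + 60.0 * (lon - 10.0)  # 20 at west edge, 80 at east
        df = pd.DataFrame(
            {
                "site": [f"s{i}" for i in range(n)],
                "lon": lons,
                "lat": 45.0 + 0.8 * np.random.default_rng(5).random(n),
                "elevation": 300.0,
                "prediction": truth(lons),
                "timeslice": 1000.0,
            }
        )
        f = map_timeslice(df, small_dem(), InterpolationConfig(low_density_radius_km=500.0))
        mid = f.values.shape[0] // 2
        west, east = f.values[mid, 1], f.values[mid, -2]
        lon_w, lon_e = f.lon[1], f.lon[-2]
        assert east > west  # gradient sign
        expected = truth(lon_e) - truth(lon_w)
        assert (east - west) == pytest.approx(expected, rel=0.10)

    def test_values_clamped_and_water_masked(self):
        dem = small_dem()
        dem.values[0, 0] = dem.water
        df = site_frame([0.0, 100.0, 30.0, 90.0, 10.0, 70.0])
        f = map_timeslice(df, dem, InterpolationConfig(low_density_radius_km=500.0, min_sites=5))
        assert f.water_mask[0, 0]
        ok = f.values[~f.combined_mask()]
        assert ok.min() >= 0.0 and ok.max() <= 100.0


class TestFourD:
    def test_adjacent_slices_vary_smoothly(self):
        frames = []
        for c in (1500.0, 1250.0, 1000.0, 750.0, 500.0):
            df = site_frame(np.full(6, 40.0 + c / 100.0), timeslice=c)
            df["id"] = df["site"] + f"_{c:.0f}"
            frames.append(df)
        results = pd.concat(frames, ignore_index=True)
        cfg = InterpolationConfig(low_density_radius_km=500.0, min_sites=5)
        f1 = map_timeslice(results, small_dem(), cfg, center=1000.0)
        f2 = map_timeslice(results, small_dem(), cfg, center=750.0)
        diff = np.abs(f1.values - f2.values)
        # site values change by 2.5 per slice step; the fields must track that
        assert np.nanmedian(diff) <= 5.0

    def test_terminal_slice_uses_spatial_fit(self):
        frames = []
        for c in (500.0, 250.0, 0.0):
            frames.append(site_frame(np.full(6, 50.0), timeslice=c))
        results = pd.concat(frames, ignore_index=True)
        f = map_timeslice(results, small_dem(),
                          InterpolationConfig(low_density_radius_km=500.0, min_sites=5),
                          center=0.0)
        np.testing.assert_allclose(f.values[~f.combined_mask()], 50.0, atol=1e-6)


class TestErrorGrid:
    def test_jackknife_matches_bruteforce(self):
        """The interpolation-uncertainty term equals a brute-force
        delete-one-site recomputation with the dense-system oracle."""
        df = site_frame([30.0, 45.0, 60.0, 50.0, 40.0, 55.0])
        df["se"] = [1.0, 2.0, 3.0, 1.5, 2.5, 2.0]
        df["elevation"] = [100.0, 400.0, 250.0, 600.0, 150.0, 500.0]
        dem = small_dem()
        cfg = InterpolationConfig(error_res_deg=0.5)
        g = error_grid(df, dem, cfg)
        assert g is not None

        pts = cfg.scaled(df["lon"], df["lat"], df["elevation"])
        glon, glat = np.meshgrid(g.lon, g.lat)
        gelev = np.empty(glon.shape)
        for i in range(glon.shape[0]):
            for j in range(glon.shape[1]):
                lon = float(np.clip(glon[i, j], dem.lons().min(), dem.lons().max()))
                lat = float(np.clip(glat[i, j], dem.lats().min(), dem.lats().max()))
                gelev[i, j] = dem.value_at(lon, lat)
        q = cfg.scaled(glon.ravel(), glat.ravel(), gelev.ravel())
        vals = df["prediction"].to_numpy()
        n = len(df)
        preds = np.stack([
            dense_tps_solve(np.delete(pts, i, axis=0), np.delete(vals, i), q)
            for i in range(n)
        ])
        mean = preds.mean(axis=0)
        jack = np.sqrt((n - 1) / n * np.sum((preds - mean) ** 2, axis=0)).reshape(glon.shape)
        analog = dense_tps_solve(pts, df["se"].to_numpy(), q).reshape(glon.shape)
        np.testing.assert_allclose(g.values, np.clip(analog, 0, None) + jack, atol=1e-5)

    def test_duplicate_site_contributes_no_jackknife(self):
        """Deleting one of two co-located equal-valued sites leaves the fit
        unchanged, so a fully duplicated set has zero jackknife term."""
        base = site_frame([30.0, 45.0, 60.0, 50.0], n=4)
        dup = pd.concat([base, base.assign(site=base["site"] + "b")], ignore_index=True)
        dem = small_dem(n=10)
        g = error_grid(dup.assign(se=0.0), dem, InterpolationConfig(error_res_deg=0.5))
        np.testing.assert_allclose(g.values, 0.0, atol=1e-6)

    def test_too_few_sites_skipped(self):
        df = site_frame([30.0, 40.0], n=2)
        assert error_grid(df, small_dem(), InterpolationConfig()) is None


def test_map_slices_skips_sparse_and_orders_fields(small_world):
    from pollenmat import MATConfig, reconstruct_fossils, synthetic_dictionary
    from pollenmat.calibration import build_calibration
    from pollenmat.synthetic import frame_to_samples

    d = synthetic_dictionary()
    modern = frame_to_samples(small_world.modern)
    entries = build_calibration(modern, small_world.cover, d)
    fossils = frame_to_samples(small_world.cores)
    results = reconstruct_fossils(fossils, entries, d)
    fields = map_slices(results, small_world.elevation,
                        InterpolationConfig(min_sites=4, low_density_radius_km=200.0))
    assert len(fields) > 0
    times = [f.timeslice for f in fields]
    assert times == sorted(times, reverse=True)
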