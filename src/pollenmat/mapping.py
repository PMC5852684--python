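"""Timeslice binning and thin-plate-spline space-time interpolation.

Fossil reconstructions are binned into 49 timeslices (centers every 250
years from 12,000 to 0 BP; 250-year windows, with the terminal window
asymmetric: it spans 185 years, from 125 BP down to -60 BP, because it
cannot project into the future).  Point reconstructions are then
interpolated over a digital elevation model with a thin-plate spline in
(longitude, latitude, elevation, age); the 0 BP slice uses a 3-D spatial
fit to avoid skew from the unbalanced sample distribution around 0 BP.

Coordinates are scaled before fitting so that 1,000 m of elevation and one
250-year timeslice step weigh like one horizontal degree (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .data_io import GriddedField, RasterGrid, haversine_m

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TimesliceScheme:
    oldest: float = 12_000.0
    youngest_center: float = 0.0
    step: float = 250.0
    half_width: float = 125.0
    youngest_age: float = -60.0  # terminal window: 185 years centered on 0 BP

    @property
    def centers(self) -> np.ndarray:
        """Slice centers, oldest first."""
        return np.arange(self.oldest, self.youngest_center - self.step / 2, -self.step)

    def assign(self, age: float) -> float | None:
        """Center of the slice owning ``age``; boundaries go to the younger
        slice (age in (c - 125, c + 125]); None when out of range."""
        if age > self.oldest + self.half_width or age < self.youngest_age:
            return None
        c = self.step * np.ceil((age - self.half_width) / self.step)
        c = float(np.clip(c, self.youngest_center, self.oldest))
        return c


def assign_timeslices(
    df: pd.DataFrame, scheme: TimesliceScheme = TimesliceScheme(), age_col: str = "age"
) -> pd.DataFrame:
    """Add a ``timeslice`` column; out-of-range samples get NaN and a log line."""
    out = df.copy()
    slices = [scheme.assign(a) for a in out[age_col]]
    n_out = sum(s is None for s in slices)
    if n_out:
        logger.info("%d samples outside the timeslice scheme left unassigned", n_out)
    out["timeslice"] = [np.nan if s is None else s for s in slices]
    return out


@dataclass(frozen=True)
class InterpolationConfig:
    # degrees per unit in each scaled coordinate: lon, lat, elev(m), age(yr)
    scale_lon: float = 1.0
    scale_lat: float = 1.0
    scale_elev: float = 1.0 / 1000.0
    scale_age: float = 1.0 / 250.0
    smoothing: float | str = 0.0  # float, or "gcv" for a leave-one-out sweep
    low_density_radius_km: float = 250.0
    min_sites: int = 6
    temporal_halfwindow: int = 2  # slices on each side feeding the 4-D fit
    error_res_deg: float = 1.0

    def scaled(self, lon, lat, elev=None, age=None) -> np.ndarray:
        cols = [np.asarray(lon, dtype=float) * self.scale_lon,
                np.asarray(lat, dtype=float) * self.scale_lat]
        if elev is not None:
            cols.append(np.asarray(elev, dtype=float) * self.scale_elev)
        if age is not None:
            cols.append(np.asarray(age, dtype=float) * self.scale_age)
        return np.column_stack(cols)


_GCV_CANDIDATES = (0.0, 1e-3, 1e-2, 1e-1, 1.0, 10.0)


class TPSInterpolant:
    """Thin-plate radial-basis interpolant with degree-1 polynomial tail."""

    def __init__(self, points: np.ndarray, values: np.ndarray, smoothing: float = 0.0):
        points = np.asarray(points, dtype=float)
        values = np.asarray(values, dtype=float)
        # exact duplicates in scaled space are averaged
        df = pd.DataFrame(points)
        df["v"] = values
        agg = df.groupby(list(range(points.shape[1])), as_index=False).mean()
        self.points = agg[list(range(points.shape[1]))].to_numpy()
        self.values = agg["v"].to_numpy()
        self.smoothing = float(smoothing)
        # coordinates constant across all sites (e.g. flat terrain, or a
        # single-slice fit along the age axis) carry no information and would
        # make the polynomial part rank-deficient; drop them from the fit
        spread = self.points.max(axis=0) - self.points.min(axis=0)
        self._active = np.flatnonzero(spread > 0)
        if self._active.size == 0:
            self._constant = float(self.values.mean())
            self._rbf = None
            return
        self._constant = None
        active_pts = self.points[:, self._active]
        if len(active_pts) < self._active.size + 2:
            raise FittingError("too few points for a thin-plate fit")
        try:
            self._rbf = RBFInterpolator(
                active_pts, self.values, kernel="thin_plate_spline", degree=1,
                smoothing=self.smoothing,
            )
        except np.linalg.LinAlgError as exc:
            raise FittingError(f"rank-deficient thin-plate system: {exc}") from exc

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if self._constant is not None:
            return np.full(len(points), self._constant)
        return self._rbf(points[:, self._active])


def _loo_rmse(points: np.ndarray, values: np.ndarray, smoothing: float) -> float:
    n = len(points)
    errs = []
    for i in range(n):
        keep = np.arange(n) != i
        try:
            f = TPSInterpolant(points[keep], values[keep], smoothing)
        except FittingError:
            return np.inf
        errs.append(float(f(points[i : i + 1])[0] - values[i]))
    return float(np.sqrt(np.mean(np.square(errs))))


def fit_tps(
    points: np.ndarray,
    values: np.ndarray,
    smoothing: float | str = 0.0,
) -> TPSInterpolant:
    """Fit a thin-plate spline in scaled coordinates.

    ``smoothing="gcv"`` selects the ridge parameter by leave-one-out error
    over a small log-spaced candidate grid (site counts per slice are small
    enough for the n refits this costs)."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if smoothing == "gcv":
        best, best_err = 0.0, np.inf
        for s in _GCV_CANDIDATES:
            err = _loo_rmse(points, values, s)
            if err < best_err:
                best, best_err = s, err
        smoothing = best
    return TPSInterpolant(points, values, float(smoothing))


def _site_means(slice_df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """One value per site within a slice (mean over the site's samples)."""
    key = "site" if "site" in slice_df.columns else "id"
    g = slice_df.dropna(subset=[value_col]).groupby(key, as_index=False)
    return g.agg({"lon": "first", "lat": "first", "elevation": "first",
                  value_col: "mean"})


def _distance_mask(
    lons: np.ndarray, lats: np.ndarray, site_lon: np.ndarray, site_lat: np.ndarray,
    radius_km: float,
) -> np.ndarray:
    """True where a grid cell is farther than ``radius_km`` from every site."""
    glon, glat = np.meshgrid(lons, lats)
    mind = np.full(glon.shape, np.inf)
    for slon, slat in zip(site_lon, site_lat):
        d = haversine_m(glon, glat, slon, slat)
        mind = np.minimum(mind, d)
    return mind > radius_km * 1000.0


def map_timeslice(
    results: pd.DataFrame,
    dem: RasterGrid,
    config: InterpolationConfig = InterpolationConfig(),
    variable: str = "forest_cover",
    value_col: str = "prediction",
    center: float | None = None,
    scheme: TimesliceScheme | None = None,
) -> GriddedField | None:
    """Interpolate one timeslice onto the DEM grid.

    ``results`` must carry lon/lat/elevation/timeslice plus the value
    column.  When ``center`` is given and the frame holds several slices,
    sites within ±``temporal_halfwindow`` slices feed a 4-D
    (lon, lat, elev, age) fit; the 0 BP slice and single-slice frames use
    the 3-D spatial fit.  Cover/AP fields are clamped to [0, 100]; cells
    farther than the low-density radius from every contributing site are
    masked, as are water cells of the DEM.
    """
    scheme = scheme or TimesliceScheme()
    if center is None:
        center = float(results["timeslice"].iloc[0])
    slice_df = results[results["timeslice"] == center]
    sites = _site_means(slice_df, value_col)
    if len(sites) < config.min_sites:
        logger.info("timeslice %s skipped: %d sites < %d", center, len(sites), config.min_sites)
        return None

    multi = results["timeslice"].nunique() > 1
    use_4d = multi and center != 0.0 and config.temporal_halfwindow > 0
    if use_4d:
        lo = center - config.temporal_halfwindow * scheme.step
        hi = center + config.temporal_halfwindow * scheme.step
        window = results[(results["timeslice"] >= lo) & (results["timeslice"] <= hi)]
        per_slice = [
            _site_means(window[window["timeslice"] == c], value_col).assign(age=c)
            for c in sorted(window["timeslice"].unique())
        ]
        pts_df = pd.concat(per_slice, ignore_index=True)
        pts = config.scaled(pts_df["lon"], pts_df["lat"], pts_df["elevation"], pts_df["age"])
        vals = pts_df[value_col].to_numpy()
    else:
        pts = config.scaled(sites["lon"], sites["lat"], sites["elevation"])
        vals = sites[value_col].to_numpy()

    interp = fit_tps(pts, vals, config.smoothing)

    lons, lats = dem.lons(), dem.lats()
    glon, glat = np.meshgrid(lons, lats)
    gelev = dem.values
    if use_4d:
        gage = np.full(glon.shape, center)
        q = config.scaled(glon.ravel(), glat.ravel(), gelev.ravel(), gage.ravel())
    else:
        q = config.scaled(glon.ravel(), glat.ravel(), gelev.ravel())
    field = interp(q).reshape(glon.shape)
    if variable in ("forest_cover", "ap"):
        field = np.clip(field, 0.0, 100.0)
        vr = (0.0, 100.0)
    else:
        field = np.clip(field, 0.0, None)
        vr = (0.0, float(max(100.0, np.nanmax(field) if np.isfinite(field).any() else 100.0)))

    low_density = _distance_mask(lons, lats, sites["lon"].to_numpy(), sites["lat"].to_numpy(),
                                 config.low_density_radius_km)
    water = (dem.values == dem.water) | (dem.values == dem.nodata)
    return GriddedField(
        values=field, lon=lons, lat=lats, timeslice=center, variable=variable,
        low_density_mask=low_density, water_mask=water, valid_range=vr,
    )


def map_slices(
    results: pd.DataFrame,
    dem: RasterGrid,
    config: InterpolationConfig = InterpolationConfig(),
    variable: str = "forest_cover",
    value_col: str = "prediction",
    scheme: TimesliceScheme | None = None,
) -> list[GriddedField]:
    """Map every timeslice present in ``results`` (skipping sparse ones)."""
    scheme = scheme or TimesliceScheme()
    fields = []
    for center in sorted(results["timeslice"].dropna().unique(), reverse=True):
        f = map_timeslice(results, dem, config, variable, value_col, float(center), scheme)
        if f is not None:
            fields.append(f)
    return fields


def _coarse_axes(dem: RasterGrid, res_deg: float) -> tuple[np.ndarray, np.ndarray]:
    lons, lats = dem.lons(), dem.lats()
    glons = np.arange(lons.min(), lons.max() + res_deg / 2, res_deg)
    glats = np.arange(lats.max(), lats.min() - res_deg / 2, -res_deg)
    return glons, glats


def error_grid(
    slice_df: pd.DataFrame,
    dem: RasterGrid,
    config: InterpolationConfig = InterpolationConfig(),
    se_col: str = "se",
    value_col: str = "prediction",
) -> GriddedField | None:
    """Coarse (1-degree) total-error field for one timeslice.

    Total error = thin-plate-interpolated per-site analog standard error
    plus the interpolation uncertainty of the cover surface itself,
    estimated by a delete-one-site jackknife of the prediction at each
    coarse cell.  Needs at least three sites.
    """
    sites = _site_means(slice_df.dropna(subset=[se_col]), value_col)
    se_sites = _site_means(slice_df.dropna(subset=[se_col]), se_col)
    if len(sites) < 3:
        logger.info("error grid skipped: fewer than 3 sites with analog SEs")
        return None
    glons, glats = _coarse_axes(dem, config.error_res_deg)
    glon, glat = np.meshgrid(glons, glats)
    # elevation at coarse cells: nearest DEM cell value (coarse grid is for
    # error reporting only)
    gelev = np.empty(glon.shape)
    for i in range(glon.shape[0]):
        for j in range(glon.shape[1]):
            lon = float(np.clip(glon[i, j], dem.lons().min(), dem.lons().max()))
            lat = float(np.clip(glat[i, j], dem.lats().min(), dem.lats().max()))
            gelev[i, j] = dem.value_at(lon, lat)
    q = config.scaled(glon.ravel(), glat.ravel(), gelev.ravel())

    pts = config.scaled(sites["lon"], sites["lat"], sites["elevation"])
    smoothing = config.smoothing if isinstance(config.smoothing, float) else 0.0

    se_interp = TPSInterpolant(pts, se_sites[se_col].to_numpy(), smoothing)
    analog_term = np.clip(se_interp(q).reshape(glon.shape), 0.0, None)

    full = TPSInterpolant(pts, sites[value_col].to_numpy(), smoothing)
    n = len(sites)
    preds = np.empty((n,) + glon.shape)
    for i in range(n):
        keep = np.arange(n) != i
        f = TPSInterpolant(pts[keep], sites[value_col].to_numpy()[keep], smoothing)
        preds[i] = f(q).reshape(glon.shape)
    mean_del = preds.mean(axis=0)
    jack = np.sqrt((n - 1) / n * np.sum((preds - mean_del) ** 2, axis=0))

    total = analog_term + jack
    return GriddedField(
        values=total, lon=glons, lat=glats, timeslice=float(slice_df["timeslice"].iloc[0]),
        variable="total_se", valid_range=(0.0, float(max(100.0, total.max()))),
    )
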