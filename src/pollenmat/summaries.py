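"""Regional time series, Alpine elevation-band analysis, series comparison.

Regional means are cosine-latitude-area-weighted averages over unmasked
land cells inside each region polygon; the reported spread is inter-cell
variability, not reconstruction error.  The elevation-band analysis groups
cells into 200-m bands (below 400 m collapsed into one band) and tracks the
upper edge of the highest band whose mean cover exceeds 50 % — a simple
timberline-ecotone indicator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .data_io import GriddedField, RasterGrid

logger = logging.getLogger(__name__)


@dataclass
class RegionSpec:
    region_id: int
    name: str
    polygon: shapely.Geometry

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"region {self.name!r}: invalid (self-intersecting?) polygon")


def load_regions(path: str | Path) -> list[RegionSpec]:
    """Read region polygons from GeoJSON (FeatureCollection with id/name)."""
    gj = json.loads(Path(path).read_text())
    regions = []
    for i, feat in enumerate(gj["features"]):
        props = feat.get("properties", {})
        regions.append(
            RegionSpec(
                region_id=int(props.get("id", i + 1)),
                name=str(props.get("name", f"region{i + 1}")),
                polygon=shapely_shape(feat["geometry"]),
            )
        )
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            inter = regions[a].polygon.intersection(regions[b].polygon)
            if inter.area > 1e-12:
                raise ValueError(f"regions {regions[a].name!r} and {regions[b].name!r} overlap")
    return regions


def save_regions(regions: Sequence[RegionSpec], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"id": r.region_id, "name": r.name},
            "geometry": json.loads(shapely.to_geojson(r.polygon)),
        }
        for r in regions
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def _region_cell_mask(field: GriddedField, region: RegionSpec) -> np.ndarray:
    glon, glat = np.meshgrid(field.lon, field.lat)
    return shapely.contains_xy(region.polygon, glon.ravel(), glat.ravel()).reshape(glon.shape)


def regional_series(
    fields: Sequence[GriddedField],
    regions: Sequence[RegionSpec],
) -> pd.DataFrame:
    """Area-weighted mean and SD per region and timeslice.

    Water/ice and low-density cells are excluded; a region with no unmasked
    cell in a slice yields NaN.
    """
    ref = fields[0]
    for f in fields[1:]:
        if not (np.allclose(f.lon, ref.lon) and np.allclose(f.lat, ref.lat)):
            raise ValueError("fields do not share one grid geometry")
    region_masks = {r.region_id: _region_cell_mask(ref, r) for r in regions}
    glat = np.meshgrid(ref.lon, ref.lat)[1]
    weights = np.cos(np.radians(glat))

    rows = []
    for f in fields:
        ok_cells = ~f.combined_mask()
        for r in regions:
            cells = region_masks[r.region_id] & ok_cells
            if not cells.any():
                rows.append({"region": r.region_id, "name": r.name, "timeslice": f.timeslice,
                             "mean": np.nan, "sd": np.nan, "n_cells": 0})
                continue
            v = f.values[cells]
            w = weights[cells]
            mean = float(np.sum(w * v) / np.sum(w))
            sd = float(np.sqrt(np.sum(w * (v - mean) ** 2) / np.sum(w)))
            rows.append({"region": r.region_id, "name": r.name, "timeslice": f.timeslice,
                         "mean": mean, "sd": sd, "n_cells": int(cells.sum())})
    return pd.DataFrame(rows)


def default_elevation_caps(age: float) -> float:
    """Upper analysis limit (m): 2,400 before 11,000 BP; 2,600 between
    10,000 and 11,000 BP; 2,800 otherwise."""
    if age > 11_000.0:
        return 2_400.0
    if age > 10_000.0:
        return 2_600.0
    return 2_800.0


def elevation_band_edges(top: float = 3_000.0) -> list[tuple[float, float]]:
    """Contiguous 200-m bands; everything below 400 m is one band."""
    edges = [(-np.inf, 400.0)]
    lo = 400.0
    while lo < top:
        edges.append((lo, lo + 200.0))
        lo += 200.0
    return edges


def elevation_bands(
    fields: Sequence[GriddedField],
    dem: RasterGrid,
    region: RegionSpec | None = None,
    caps: Callable[[float], float] = default_elevation_caps,
    threshold: float = 50.0,
) -> pd.DataFrame:
    """Per-slice mean cover in 200-m elevation bands plus the threshold
    track (upper edge of the highest band with mean cover > threshold).

    Bands above the period's elevation cap are flagged ``capped`` with NaN
    means rather than dropped.
    """
    ref = fields[0]
    in_region = (
        _region_cell_mask(ref, region)
        if region is not None
        else np.ones(ref.values.shape, dtype=bool)
    )
    elev = dem.values
    land = dem.land_mask()
    bands = elevation_band_edges(top=float(np.ceil(max(np.nanmax(elev[land]), 400.0) / 200.0) * 200.0))

    rows = []
    for f in fields:
        cap = caps(f.timeslice)
        ok = in_region & land & ~f.combined_mask()
        track = np.nan
        for lo, hi in bands:
            capped = lo >= cap
            cells = ok & (elev >= lo) & (elev < hi) & (elev < cap)
            mean = float(f.values[cells].mean()) if cells.any() and not capped else np.nan
            rows.append({
                "timeslice": f.timeslice,
                "band_low": lo if np.isfinite(lo) else 0.0,
                "band_high": hi,
                "mean": mean,
                "capped": bool(capped),
                "n_cells": int(cells.sum()),
            })
            if not capped and np.isfinite(mean) and mean > threshold:
                track = max(track, hi) if np.isfinite(track) else hi
        rows.append({
            "timeslice": f.timeslice, "band_low": np.nan, "band_high": np.nan,
            "mean": track, "capped": False, "n_cells": -1,  # threshold-track row
        })
    df = pd.DataFrame(rows)
    df["is_track"] = df["n_cells"] == -1
    return df


SUBPERIODS = (
    ("early", 11_700.0, 8_100.0),
    ("mid", 8_100.0, 4_100.0),
    ("late", 4_100.0, 0.0),
)


def _pair_stats(x: np.ndarray, y: np.ndarray) -> dict:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    out = {"n": int(len(x)), "r": np.nan, "mad": np.nan, "slope": np.nan, "intercept": np.nan}
    if len(x) < 3:
        return out
    out["mad"] = float(np.mean(np.abs(x - y)))
    if np.std(x) > 0 and np.std(y) > 0:
        out["r"] = float(np.corrcoef(x, y)[0, 1])
        slope, intercept = np.polyfit(x, y, 1)
        out["slope"], out["intercept"] = float(slope), float(intercept)
    return out


def compare_series(
    mat_series: pd.DataFrame,
    reference: pd.DataFrame,
    window: float = 200.0,
    age_col: str = "age",
    value_col: str = "value",
) -> pd.DataFrame:
    """Align a point-reconstruction series with a reference series.

    The analog series is re-binned to the reference's window width (mean of
    points with age in [center - w/2, center + w/2)); paired Pearson r,
    mean absolute difference and least-squares slope/intercept are returned
    overall and for the Early/Mid/Late Holocene sub-periods.
    """
    centers = reference[age_col].to_numpy(dtype=float)
    ref_vals = reference[value_col].to_numpy(dtype=float)
    ages = mat_series[age_col].to_numpy(dtype=float)
    vals = mat_series[value_col].to_numpy(dtype=float)
    binned = np.full(len(centers), np.nan)
    for i, c in enumerate(centers):
        inside = (ages >= c - window / 2) & (ages < c + window / 2)
        if inside.any():
            binned[i] = np.nanmean(vals[inside])

    rows = [{"period": "overall", **_pair_stats(binned, ref_vals)}]
    for name, old, young in SUBPERIODS:
        sel = (centers <= old) & (centers > young) if name != "late" else (centers <= old) & (centers >= young)
        rows.append({"period": name, **_pair_stats(binned[sel], ref_vals[sel])})
    return pd.DataFrame(rows)
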