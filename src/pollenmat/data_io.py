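"""Readers, writers and shared geometry for the forest-cover pipeline.

Tabular data (modern samples, fossil cores, calibration entries) travel as
delimited text; rasters as ESRI ASCII grids (plain-text, single band, explicit
no-data); gridded timeslice stacks as CF-style NetCDF via xarray.

Grid registration is cell-center with half-open cell intervals: the cell at
index (i, j) owns [center - res/2, center + res/2) along each axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: Mean (authalic) Earth radius in meters, used for all great-circle distances.
EARTH_RADIUS_M = 6_371_007.2

#: Reserved raster codes.  Water is distinct from plain no-data so that the
#: extraction and screening rules can treat open water specially.
NODATA = -9999.0
WATER = -8888.0

#: Recognised sampling contexts (EMPD-style).
CONTEXTS = frozenset(
    {
        "moss",
        "soil",
        "lake",
        "dense_forest",
        "forest_undefined",
        "treeless",
        "tundra",
        "pasture",
        "riverine",
        "estuarine",
        "unknown",
    }
)

#: Metadata columns expected in sample tables; everything else is a taxon.
SAMPLE_META_COLUMNS = (
    "id",
    "lon",
    "lat",
    "elevation",
    "age",
    "context",
    "location_error",
    "lake_area_ha",
)

PERCENT_SUM_TOL = 0.5


class FormatError(ValueError):
    """A file does not match the documented column dictionary."""


class ValidationError(ValueError):
    """Well-formed input carrying invalid values."""


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters on the authalic sphere.

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class PollenSample:
    """One modern or fossil pollen assemblage.

    Percentages are relative to the terrestrial sum (they add to 100 within
    ``PERCENT_SUM_TOL``); ``count_total`` keeps the raw terrestrial grain sum.
    Ages follow the BP convention (years before AD 1950, negative after).
    """

    id: str
    lon: float
    lat: float
    elevation: float
    age: float
    context: str
    percentages: dict[str, float]
    count_total: float
    location_error: float | None = None
    lake_area_ha: float | None = None
    site: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"sample {self.id}: longitude {self.lon} out of range")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"sample {self.id}: latitude {self.lat} out of range")
        if any(v < 0 for v in self.percentages.values()):
            raise ValidationError(f"sample {self.id}: negative percentage")
        total = sum(self.percentages.values())
        if self.percentages and abs(total - 100.0) > PERCENT_SUM_TOL:
            raise ValidationError(
                f"sample {self.id}: percentages sum to {total:.3f}, expected 100 ± {PERCENT_SUM_TOL}"
            )


@dataclass
class RasterGrid:
    """A single-band lon/lat raster with cell-center registration.

    ``values[0, 0]`` is the north-west cell; latitudes decrease along axis 0
    and longitudes increase along axis 1, both with constant step ``res``
    (decimal degrees).
    """

    values: np.ndarray
    lon_min: float  # center longitude of the west-most column
    lat_max: float  # center latitude of the north-most row
    res: float
    nodata: float = NODATA
    water: float = WATER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be 2-D")
        if self.res <= 0:
            raise ValidationError("raster resolution must be positive")
        if self.water == self.nodata:
            raise ValidationError("water code must differ from the no-data code")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lons(self) -> np.ndarray:
        return self.lon_min + self.res * np.arange(self.shape[1])

    def lats(self) -> np.ndarray:
        return self.lat_max - self.res * np.arange(self.shape[0])

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell whose half-open interval contains the point."""
        j = int(np.floor((lon - self.lon_min) / self.res + 0.5))
        i = int(np.floor((self.lat_max - lat) / self.res + 0.5))
        if not (0 <= i < self.shape[0] and 0 <= j < self.shape[1]):
            raise ValidationError(f"point ({lon}, {lat}) off the raster")
        return i, j

    def value_at(self, lon: float, lat: float) -> float:
        i, j = self.index_of(lon, lat)
        return float(self.values[i, j])

    def contains(self, lon: float, lat: float) -> bool:
        try:
            self.index_of(lon, lat)
        except ValidationError:
            return False
        return True

    def land_mask(self) -> np.ndarray:
        return (self.values != self.nodata) & (self.values != self.water)


def write_raster_ascii(grid: RasterGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); water cells keep their code verbatim."""
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.lon_min - grid.res / 2.0:.10f}\n"
        f"yllcorner {grid.lat_max - grid.res * (nrows - 0.5):.10f}\n"
        f"cellsize {grid.res:.10f}\n"
        f"NODATA_value {grid.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%.6g")


def read_raster_ascii(path: str | Path, water: float = WATER) -> RasterGrid:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    res = meta["cellsize"]
    return RasterGrid(
        values=values,
        lon_min=meta["xllcorner"] + res / 2.0,
        lat_max=meta["yllcorner"] + res * (values.shape[0] - 0.5),
        res=res,
        nodata=meta.get("nodata_value", NODATA),
        water=water,
    )


@dataclass
class GriddedField:
    """One gridded timeslice field (cover, AP or SE) plus masks.

    ``values`` is oriented like :class:`RasterGrid`.  Masked cells (either
    mask true) carry no reconstruction.
    """

    values: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    timeslice: float
    variable: str = "forest_cover"
    low_density_mask: np.ndarray | None = None
    water_mask: np.ndarray | None = None
    valid_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.low_density_mask is None:
            self.low_density_mask = np.zeros(self.values.shape, dtype=bool)
        if self.water_mask is None:
            self.water_mask = np.zeros(self.values.shape, dtype=bool)
        lo, hi = self.valid_range
        unmasked = self.values[~self.combined_mask()]
        finite = unmasked[np.isfinite(unmasked)]
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
            raise ValidationError(
                f"unmasked {self.variable} values outside declared range {self.valid_range}"
            )

    def combined_mask(self) -> np.ndarray:
        return self.low_density_mask | self.water_mask


def write_grid_stack(fields: Sequence[GriddedField], path: str | Path) -> None:
    """Write a stack of co-registered timeslice fields as CF-style NetCDF."""
    if not fields:
        raise ValidationError("empty field stack")
    ref = fields[0]
    for f in fields[1:]:
        if f.values.shape != ref.values.shape or not (
            np.allclose(f.lon, ref.lon) and np.allclose(f.lat, ref.lat)
        ):
            raise ValidationError("geometry mismatch within the field stack")
    time = np.array([f.timeslice for f in fields], dtype=float)
    ds = xr.Dataset(
        {
            ref.variable: (
                ("time", "lat", "lon"),
                np.stack([f.values for f in fields]),
            ),
            "low_density_mask": (
                ("time", "lat", "lon"),
                np.stack([f.low_density_mask for f in fields]).astype(np.int8),
            ),
            "water_mask": (
                ("time", "lat", "lon"),
                np.stack([f.water_mask for f in fields]).astype(np.int8),
            ),
        },
        coords={"time": time, "lat": ref.lat, "lon": ref.lon},
        attrs={
            "variable": ref.variable,
            "valid_min": ref.valid_range[0],
            "valid_max": ref.valid_range[1],
            "time_units": "calibrated years BP",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_grid_stack(path: str | Path) -> list[GriddedField]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    variable = ds.attrs.get("variable", "forest_cover")
    vr = (float(ds.attrs.get("valid_min", 0.0)), float(ds.attrs.get("valid_max", 100.0)))
    out = []
    for t in range(ds.sizes["time"]):
        out.append(
            GriddedField(
                values=ds[variable].values[t],
                lon=ds["lon"].values,
                lat=ds["lat"].values,
                timeslice=float(ds["time"].values[t]),
                variable=variable,
                low_density_mask=ds["low_density_mask"].values[t].astype(bool),
                water_mask=ds["water_mask"].values[t].astype(bool),
                valid_range=vr,
            )
        )
    return out


def _normalize_taxon(name: str) -> str:
    return " ".join(str(name).split()).lower()


def read_samples(
    path: str | Path,
    known_taxa: Iterable[str] | None = None,
) -> list[PollenSample]:
    """Read a delimited sample table (comma or tab autodetected).

    Non-metadata columns are taxon *counts*; they are converted to
    percentages of the terrestrial sum and the raw total is retained.
    A taxon column absent from ``known_taxa`` (when given) is carried through
    unmapped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"id", "lon", "lat", "age", "context"} - set(df.columns)
    if missing:
        raise FormatError(f"missing mandatory columns: {sorted(missing)}")
    taxon_cols = [c for c in df.columns if c not in SAMPLE_META_COLUMNS and c != "site"]
    if known_taxa is not None:
        known = {_normalize_taxon(t) for t in known_taxa}
        unknown = [c for c in taxon_cols if _normalize_taxon(c) not in known]
        if unknown:
            warnings.warn(f"taxon columns not in dictionary, carried through unmapped: {unknown}")
    counts = df[taxon_cols].fillna(0.0).to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative pollen count")
    totals = counts.sum(axis=1)
    samples = []
    for r in range(len(df)):
        total = totals[r]
        pct = {t: (100.0 * counts[r, i] / total if total > 0 else 0.0) for i, t in enumerate(taxon_cols)}
        row = df.iloc[r]
        samples.append(
            PollenSample(
                id=str(row["id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                elevation=float(row.get("elevation", np.nan)),
                age=float(row["age"]),
                context=str(row["context"]),
                percentages=pct,
                count_total=float(total),
                location_error=None if pd.isna(row.get("location_error")) else float(row["location_error"]),
                lake_area_ha=None if pd.isna(row.get("lake_area_ha")) else float(row["lake_area_ha"]),
                site=str(row["site"]) if "site" in df.columns and not pd.isna(row["site"]) else None,
            )
        )
    return samples


def samples_to_frame(samples: Sequence[PollenSample]) -> pd.DataFrame:
    """Flatten samples into one DataFrame (metadata + percentage columns)."""
    taxa = sorted({t for s in samples for t in s.percentages})
    rows = []
    for s in samples:
        row = {
            "id": s.id,
            "lon": s.lon,
            "lat": s.lat,
            "elevation": s.elevation,
            "age": s.age,
            "context": s.context,
            "location_error": s.location_error,
            "lake_area_ha": s.lake_area_ha,
            "site": s.site,
            "count_total": s.count_total,
        }
        row.update({t: s.percentages.get(t, 0.0) for t in taxa})
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> dict:
    """Load a pipeline configuration file (YAML or ``key = value`` lines)."""
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise FormatError("configuration file must define a mapping")
    return cfg
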