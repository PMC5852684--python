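"""Synthetic worlds with known ground truth.

Generates internally consistent rasters (forest cover, tree height, land
class, elevation), modern surface samples and fossil cores so that every
downstream stage — calibration, quality control, analog matching, bias
correction, mapping — can be exercised and validated against a known truth
without any external data.

The pollen forward model is deliberately minimal: the expected arboreal
share of an assemblage is the local cover fraction blended with a
long-distance background,

    AP_share = (1 - lam) * FC/100 + lam * background_ap,

with ``lam`` the long-distance-transport fraction.  Within the arboreal and
herbaceous pools, taxa split by fixed productivity multipliers.  Counts are
multinomial at the configured grain total.  This is the simplest model that
exhibits the over-representation of arboreal pollen in open landscapes that
motivates bias correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import (
    NODATA,
    WATER,
    PollenSample,
    RasterGrid,
    samples_to_frame,
    write_raster_ascii,
)
from .pft import PFTDictionary, synthetic_dictionary

# land-class raster codes
CLASS_OPEN = 0.0
CLASS_FOREST = 1.0
CLASS_WATER = 2.0

#: Globcover-style lower cover limit for open forest (percent).
FOREST_CLASS_COVER = 15.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    arboreal: bool
    productivity: float = 1.0


DEFAULT_TAXA = (
    TaxonSpec("Pinus", True, 2.0),
    TaxonSpec("Picea", True, 1.0),
    TaxonSpec("Quercus", True, 1.5),
    TaxonSpec("Corylus", True, 1.0),
    TaxonSpec("Betula", True, 2.5),
    TaxonSpec("Betula nana", False, 0.5),
    TaxonSpec("Poaceae", False, 1.5),
    TaxonSpec("Artemisia", False, 1.0),
)


def default_history(lon, lat, elev, age):
    """Prescribed forest-cover history: sparse late-glacial cover rising to a
    plateau between 8,500 and 6,000 BP, then declining toward the present."""
    age = np.asarray(age, dtype=float)
    m = np.empty_like(age)
    m[...] = 1.0
    rising = age > 8500.0
    m[rising] = 0.3 + 0.7 * np.clip((12000.0 - age[rising]) / 3500.0, 0.0, 1.0)
    declining = age < 6000.0
    m[declining] = 1.0 - 0.45 * np.clip((6000.0 - age[declining]) / 6000.0, 0.0, 1.0)
    return m


@dataclass
class WorldConfig:
    """Parameters of one synthetic world.

    ``resolution_m`` and ``correlation_length_m`` are in meters; they are
    converted to degrees at the domain's central latitude.  ``fc_history``
    multiplies the modern spatial cover field: FC_true(lon, lat, elev, age)
    = FC_modern(lon, lat) * fc_history(lon, lat, elev, age), clipped to
    [0, 100].
    """

    lon_min: float = 8.0
    lon_max: float = 12.0
    lat_min: float = 45.0
    lat_max: float = 48.0
    resolution_m: float = 2000.0
    correlation_length_m: float = 20000.0
    taxa: tuple[TaxonSpec, ...] = DEFAULT_TAXA
    transport_fraction: float = 0.1
    background_ap: float = 0.4
    count_total: int = 400
    n_modern: int = 160
    n_fossil_sites: int = 12
    samples_per_core: int = 60
    age_span: tuple[float, float] = (-60.0, 12000.0)
    fc_history: Callable = default_history
    water_fraction: float = 0.03
    shrubland_patch: bool = False
    constant_cover: float | None = None
    defect_fraction: float = 0.0
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_m <= 0:
            raise ConfigurationError("resolution must be positive")
        if not 0.0 <= self.transport_fraction <= 1.0:
            raise ConfigurationError("transport fraction must lie in [0, 1]")
        if not self.taxa:
            raise ConfigurationError("empty taxon list")

    @property
    def res_deg(self) -> float:
        mid_lat = 0.5 * (self.lat_min + self.lat_max)
        m_per_deg = 111_194.9 * np.cos(np.radians(mid_lat))
        # use the smaller (zonal) meter-per-degree so cells are at least the
        # requested size in both directions
        return self.resolution_m / m_per_deg


@dataclass
class SyntheticWorld:
    """Rasters, sample tables and ground truth of one generated world."""

    config: WorldConfig
    cover: RasterGrid
    height: RasterGrid
    landclass: RasterGrid
    elevation: RasterGrid
    modern: pd.DataFrame | None = None
    modern_truth: pd.DataFrame | None = None
    cores: pd.DataFrame | None = None
    core_truth: pd.DataFrame | None = None

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_raster_ascii(self.cover, d / "cover.asc")
        write_raster_ascii(self.height, d / "height.asc")
        write_raster_ascii(self.landclass, d / "landclass.asc")
        write_raster_ascii(self.elevation, d / "elevation.asc")
        for name in ("modern", "modern_truth", "cores", "core_truth"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(d / f"{name}.csv", index=False)


def _smooth_field(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (f - lo) / (hi - lo)


def generate_cover_raster(config: WorldConfig, rng: np.random.Generator | None = None) -> SyntheticWorld:
    """Generate the co-registered raster set of a world.

    The cover field is filtered Gaussian noise (kernel width = configured
    correlation length) rescaled to [0, 100]; tree height is a monotone
    function of cover plus noise; the land-class raster discretizes cover at
    the open-forest limit; elevation is an independent smooth field.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    res = config.res_deg
    ncols = max(2, int(round((config.lon_max - config.lon_min) / res)))
    nrows = max(2, int(round((config.lat_max - config.lat_min) / res)))
    shape = (nrows, ncols)
    # Gaussian-filtered white noise has autocorrelation exp(-h^2 / (4 s^2));
    # s = L / (2 res) makes the configured correlation length the 1/e
    # decorrelation distance of the field.
    sigma_px = max(1.0, 0.5 * config.correlation_length_m / config.resolution_m)

    if config.constant_cover is not None:
        cover = np.full(shape, float(config.constant_cover))
    else:
        cover = 100.0 * _smooth_field(shape, sigma_px, rng)

    elev = 2500.0 * _smooth_field(shape, 2.0 * sigma_px, rng)

    height = np.clip(0.25 * cover + rng.normal(0.0, 0.5, shape), 0.0, None)
    height[cover <= 0.5] = 0.0

    if config.shrubland_patch:
        # tall-shrubland: positive cover, zero detectable tree height
        r0, c0 = nrows // 4, ncols // 4
        height[r0 : r0 + max(2, nrows // 8), c0 : c0 + max(2, ncols // 8)] = 0.0

    landclass = np.where(cover >= FOREST_CLASS_COVER, CLASS_FOREST, CLASS_OPEN)

    if config.water_fraction > 0:
        n_lakes = max(1, int(round(config.water_fraction * nrows * ncols / 25.0)))
        for _ in range(n_lakes):
            ci = rng.integers(2, nrows - 2)
            cj = rng.integers(2, ncols - 2)
            rad = rng.integers(1, 4)
            ii, jj = np.ogrid[:nrows, :ncols]
            blob = (ii - ci) ** 2 + (jj - cj) ** 2 <= rad**2
            cover[blob] = WATER
            height[blob] = WATER
            landclass[blob] = CLASS_WATER
            elev[blob] = elev[blob]  # lakes keep terrain elevation

    lon_min_c = config.lon_min + res / 2.0
    lat_max_c = config.lat_max - res / 2.0

    def grid(vals):
        return RasterGrid(vals, lon_min_c, lat_max_c, res)

    return SyntheticWorld(
        config=config,
        cover=grid(cover),
        height=grid(height),
        landclass=grid(landclass),
        elevation=grid(elev),
    )


def expected_assemblage(fc_percent: float, config: WorldConfig) -> dict[str, float]:
    """Expected taxon proportions for a location with true cover ``fc_percent``."""
    lam = config.transport_fraction
    ap = (1.0 - lam) * fc_percent / 100.0 + lam * config.background_ap
    ap = float(np.clip(ap, 0.0, 1.0))
    arb = [t for t in config.taxa if t.arboreal]
    herb = [t for t in config.taxa if not t.arboreal]
    props: dict[str, float] = {}
    arb_w = sum(t.productivity for t in arb)
    herb_w = sum(t.productivity for t in herb)
    for t in arb:
        props[t.name] = ap * t.productivity / arb_w if arb_w > 0 else 0.0
    for t in herb:
        props[t.name] = (1.0 - ap) * t.productivity / herb_w if herb_w > 0 else 0.0
    return props


def _draw_counts(props: dict[str, float], config: WorldConfig, rng: np.random.Generator) -> dict[str, float]:
    names = list(props)
    p = np.array([props[n] for n in names], dtype=float)
    p = p / p.sum() if p.sum() > 0 else np.full(len(p), 1.0 / len(p))
    if config.noiseless:
        counts = p * config.count_total
    else:
        counts = rng.multinomial(config.count_total, p).astype(float)
    return dict(zip(names, counts))


_DEFECTS = ("location_error", "elevation_mismatch", "low_count", "riverine")


def _land_cells(world: SyntheticWorld) -> tuple[np.ndarray, np.ndarray]:
    mask = world.cover.land_mask()
    return np.nonzero(mask)


def generate_modern_samples(
    world: SyntheticWorld,
    config: WorldConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticWorld:
    """Draw modern surface samples with contexts, metadata and optional
    injected defects; ground-truth cover and defect labels are retained."""
    config = world.config if config is None else config
    if not config.taxa:
        raise ConfigurationError("empty taxon list")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    rows_idx, cols_idx = _land_cells(world)
    lons = world.cover.lons()
    lats = world.cover.lats()
    choice = rng.choice(len(rows_idx), size=config.n_modern, replace=len(rows_idx) < config.n_modern)
    contexts = rng.choice(
        ["moss", "soil", "lake", "dense_forest", "treeless"],
        p=[0.35, 0.25, 0.2, 0.1, 0.1],
        size=config.n_modern,
    )
    n_defective = int(round(config.defect_fraction * config.n_modern))
    defective = set(rng.choice(config.n_modern, size=n_defective, replace=False).tolist())

    records, truths = [], []
    for s in range(config.n_modern):
        i, j = rows_idx[choice[s]], cols_idx[choice[s]]
        lon, lat = float(lons[j]), float(lats[i])
        fc = float(world.cover.values[i, j])
        elev = float(world.elevation.values[i, j])
        context = str(contexts[s])
        props = expected_assemblage(fc, config)
        counts = _draw_counts(props, config, rng)
        loc_err = float(rng.uniform(0.0, 80.0))
        age = float(rng.uniform(-60.0, 40.0))
        lake_area = float(rng.uniform(1.0, 200.0)) if context == "lake" else np.nan
        defect = ""
        if s in defective:
            defect = str(rng.choice(_DEFECTS))
            if defect == "location_error":
                loc_err = float(rng.uniform(120.0, 500.0))
            elif defect == "elevation_mismatch":
                elev = elev + float(rng.choice([-1.0, 1.0])) * rng.uniform(250.0, 600.0)
            elif defect == "low_count":
                total = sum(counts.values())
                scale = rng.uniform(30.0, 90.0) / total if total > 0 else 0.0
                counts = {k: np.floor(v * scale) for k, v in counts.items()}
            elif defect == "riverine":
                context = "riverine"
        rec = {
            "id": f"mod{s:04d}",
            "lon": lon,
            "lat": lat,
            "elevation": elev,
            "age": age,
            "context": context,
            "location_error": loc_err,
            "lake_area_ha": lake_area,
        }
        rec.update(counts)
        records.append(rec)
        truths.append({"id": rec["id"], "true_cover": fc, "defect": defect})
    world.modern = pd.DataFrame(records)
    world.modern_truth = pd.DataFrame(truths)
    return world


def true_cover_at(world: SyntheticWorld, lon: float, lat: float, elev: float, age: float) -> float:
    base = world.cover.value_at(lon, lat)
    if base in (world.cover.nodata, world.cover.water):
        return np.nan
    m = float(np.asarray(world.config.fc_history(lon, lat, elev, np.asarray(age, dtype=float))))
    return float(np.clip(base * m, 0.0, 100.0))


def generate_fossil_cores(
    world: SyntheticWorld,
    config: WorldConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticWorld:
    """Generate fossil cores at irregular ages driven by the prescribed
    forest-cover history; the true history is retained per (site, age)."""
    config = world.config if config is None else config
    a0, a1 = config.age_span
    if a1 > 12000.0 or a0 < -125.0:
        raise ConfigurationError("age span outside the domain of FC_true")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rows_idx, cols_idx = _land_cells(world)
    lons = world.cover.lons()
    lats = world.cover.lats()
    choice = rng.choice(len(rows_idx), size=config.n_fossil_sites, replace=False)

    records, truths = [], []
    for s in range(config.n_fossil_sites):
        i, j = rows_idx[choice[s]], cols_idx[choice[s]]
        lon, lat = float(lons[j]), float(lats[i])
        elev = float(world.elevation.values[i, j])
        ages = np.sort(rng.uniform(a0, a1, size=config.samples_per_core))
        for q, age in enumerate(ages):
            fc = true_cover_at(world, lon, lat, elev, float(age))
            props = expected_assemblage(fc, config)
            counts = _draw_counts(props, config, rng)
            rec = {
                "id": f"site{s:02d}_{q:03d}",
                "site": f"site{s:02d}",
                "lon": lon,
                "lat": lat,
                "elevation": elev,
                "age": float(age),
                "context": "lake",
                "location_error": np.nan,
                "lake_area_ha": 120.0,
            }
            rec.update(counts)
            records.append(rec)
            truths.append({"id": rec["id"], "site": rec["site"], "age": float(age), "true_cover": fc})
    world.cores = pd.DataFrame(records)
    world.core_truth = pd.DataFrame(truths)
    return world


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Convenience: rasters + modern samples + fossil cores in one call."""
    world = generate_cover_raster(config)
    generate_modern_samples(world)
    generate_fossil_cores(world)
    return world


def frame_to_samples(df: pd.DataFrame, taxa: Sequence[str] | None = None) -> list[PollenSample]:
    """Convert a generated table (counts in taxon columns) to PollenSample
    objects with percentages of the terrestrial sum."""
    from .data_io import SAMPLE_META_COLUMNS

    taxon_cols = taxa if taxa is not None else [
        c for c in df.columns if c not in SAMPLE_META_COLUMNS and c != "site"
    ]
    out = []
    for _, row in df.iterrows():
        counts = {t: float(row[t]) for t in taxon_cols}
        total = sum(counts.values())
        pct = {t: (100.0 * v / total if total > 0 else 0.0) for t, v in counts.items()}
        out.append(
            PollenSample(
                id=str(row["id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                elevation=float(row["elevation"]),
                age=float(row["age"]),
                context=str(row["context"]),
                percentages=pct,
                count_total=total,
                location_error=None if pd.isna(row.get("location_error")) else float(row["location_error"]),
                lake_area_ha=None if pd.isna(row.get("lake_area_ha")) else float(row["lake_area_ha"]),
                site=str(row["site"]) if "site" in df.columns and not pd.isna(row["site"]) else None,
            )
        )
    return out
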