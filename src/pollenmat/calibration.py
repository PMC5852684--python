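"""Pairing modern samples with distance-weighted satellite forest cover.

Each modern sample receives the Gaussian-distance-weighted mean of the
forest-cover raster inside a circular search window:

    cover = sum_i w_i v_i / sum_i w_i,   w_i = exp(-r_i^2 / (2 sigma^2)),

over land pixels whose center lies within the search radius R (50 km by
default).  Water and no-data pixels are excluded from both sums, so around
lakes the weight automatically shifts to the vegetated shoreline and beyond.

The kernel width sigma depends on the sampling context: 500 m for moss and
soil polsters; 100 m for samples from dense forest when it yields a *higher*
cover than 500 m (denser forest right at the spot); 10 km for lakes, except
small lakes (< 20 ha) surrounded by forest which fall back to 500 m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import PollenSample, RasterGrid, haversine_m
from .pft import PFTDictionary, PFTVector, ap_percentage, taxa_to_pft

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    radius_m: float = 50_000.0
    sigma_options: tuple[float, ...] = (100.0, 500.0, 10_000.0)
    dense_forest_trigger: float = 40.0  # percent
    small_lake_ha: float = 20.0
    lake_surround_trigger: float = 40.0  # percent within sigma=500 m
    dense_forest_contexts: frozenset[str] = frozenset({"dense_forest", "forest_undefined"})

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("search radius must be positive")
        opts = tuple(self.sigma_options)
        if any(s <= 0 for s in opts) or list(opts) != sorted(opts):
            raise ValueError("sigma options must be positive and sorted")

    @property
    def sigma_local(self) -> float:
        return self.sigma_options[0]

    @property
    def sigma_default(self) -> float:
        return self.sigma_options[1]

    @property
    def sigma_lake(self) -> float:
        return self.sigma_options[2]


@dataclass
class CalibrationEntry:
    """A quality-passed modern sample paired with its extracted cover."""

    sample_id: str
    pft_vector: PFTVector
    cover: float
    sigma: float
    context: str
    ap: float
    height_pass: bool = True


def _window(raster: RasterGrid, lon: float, lat: float, radius_m: float):
    """Distances (m) and values of raster cells within ``radius_m`` of a point."""
    # degrees subtended by the radius (meridional, and zonal at this latitude)
    m_per_deg_lat = haversine_m(lon, lat - 0.5, lon, lat + 0.5)
    m_per_deg_lon = max(haversine_m(lon - 0.5, lat, lon + 0.5, lat), 1e-6)
    dlat = radius_m / m_per_deg_lat
    dlon = radius_m / m_per_deg_lon
    lons = raster.lons()
    lats = raster.lats()
    jmask = (lons >= lon - dlon - raster.res) & (lons <= lon + dlon + raster.res)
    imask = (lats >= lat - dlat - raster.res) & (lats <= lat + dlat + raster.res)
    ji = np.flatnonzero(jmask)
    ii = np.flatnonzero(imask)
    if ji.size == 0 or ii.size == 0:
        return np.empty(0), np.empty(0)
    sub = raster.values[np.ix_(ii, ji)]
    glon, glat = np.meshgrid(lons[ji], lats[ii])
    dist = haversine_m(glon, glat, lon, lat)
    inside = dist <= radius_m
    return dist[inside], sub[inside]


def extract_cover(
    raster: RasterGrid,
    lon: float,
    lat: float,
    sigma: float,
    radius_m: float = 50_000.0,
) -> float:
    """Gaussian-distance-weighted mean cover within the search radius.

    Returns NaN (flagged by the caller) when no valid land pixel lies in the
    window.
    """
    dist, vals = _window(raster, lon, lat, radius_m)
    valid = (vals != raster.nodata) & (vals != raster.water)
    dist, vals = dist[valid], vals[valid]
    if dist.size == 0:
        logger.warning("no valid pixels within %.0f m of (%.4f, %.4f)", radius_m, lon, lat)
        return float("nan")
    w = np.exp(-(dist**2) / (2.0 * sigma**2))
    wsum = w.sum()
    if wsum <= 0:
        # all weights underflowed; fall back to nearest valid pixel
        return float(vals[np.argmin(dist)])
    return float(np.sum(w * vals) / wsum)


@dataclass
class SigmaSelection:
    sigma: float
    cover: float


def select_sigma(
    sample: PollenSample,
    raster: RasterGrid,
    config: ExtractionConfig = ExtractionConfig(),
) -> SigmaSelection:
    """Apply the context-dependent kernel-width rules and extract cover."""
    R = config.radius_m
    context = sample.context
    if context not in {"moss", "soil", "lake", "treeless", "tundra", "pasture",
                       "riverine", "estuarine"} | set(config.dense_forest_contexts):
        logger.warning("unknown context %r for sample %s; defaulting to sigma=%g",
                       context, sample.id, config.sigma_default)
        context = "unknown"

    if context == "lake":
        area = sample.lake_area_ha
        if area is not None and area < config.small_lake_ha:
            surround = extract_cover(raster, sample.lon, sample.lat, config.sigma_default, R)
            if np.isfinite(surround) and surround > config.lake_surround_trigger:
                return SigmaSelection(config.sigma_default, surround)
        return SigmaSelection(
            config.sigma_lake, extract_cover(raster, sample.lon, sample.lat, config.sigma_lake, R)
        )

    cover_default = extract_cover(raster, sample.lon, sample.lat, config.sigma_default, R)
    if context in config.dense_forest_contexts and np.isfinite(cover_default) \
            and cover_default > config.dense_forest_trigger:
        cover_local = extract_cover(raster, sample.lon, sample.lat, config.sigma_local, R)
        if np.isfinite(cover_local) and cover_local > cover_default:
            return SigmaSelection(config.sigma_local, cover_local)
    return SigmaSelection(config.sigma_default, cover_default)


def median_height_within(
    height: RasterGrid, lon: float, lat: float, radius_m: float
) -> float:
    dist, vals = _window(height, lon, lat, radius_m)
    valid = (vals != height.nodata) & (vals != height.water)
    vals = vals[valid]
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def tree_height_screen(
    sample: PollenSample,
    sigma: float,
    height: RasterGrid | None,
    landclass: RasterGrid | None,
    config: ExtractionConfig = ExtractionConfig(),
) -> bool:
    """True when the sample stays in the analog pool.

    Only lacustrine samples with the wide kernel (sigma = 10 km) located
    inside the land-class coverage are screened: they are dropped when the
    median tree height within 1 sigma is zero (tall-shrub or treeless
    terrain misread as forest by the cover raster).
    """
    if height is None:
        logger.warning("height raster absent; tree-height screen skipped for %s", sample.id)
        return True
    if sigma != config.sigma_lake:
        return True
    if landclass is not None:
        if not landclass.contains(sample.lon, sample.lat):
            return True
        if landclass.value_at(sample.lon, sample.lat) == landclass.nodata:
            return True
    med = median_height_within(height, sample.lon, sample.lat, sigma)
    if not np.isfinite(med):
        return True
    return med != 0.0


def build_calibration(
    samples: Sequence[PollenSample],
    cover_raster: RasterGrid,
    pft_dict: PFTDictionary,
    height_raster: RasterGrid | None = None,
    landclass_raster: RasterGrid | None = None,
    config: ExtractionConfig = ExtractionConfig(),
    theta: float = 0.5,
) -> list[CalibrationEntry]:
    """Pair every sample with its extracted cover, kernel width, PFT vector
    and AP percentage; the tree-height screen verdict is recorded but entries
    failing it are dropped from the returned pool."""
    entries = []
    for s in samples:
        sel = select_sigma(s, cover_raster, config)
        keep = tree_height_screen(s, sel.sigma, height_raster, landclass_raster, config)
        entry = CalibrationEntry(
            sample_id=s.id,
            pft_vector=taxa_to_pft(s, pft_dict, theta),
            cover=sel.cover,
            sigma=sel.sigma,
            context=s.context,
            ap=ap_percentage(s, pft_dict),
            height_pass=keep,
        )
        if keep and np.isfinite(sel.cover):
            entries.append(entry)
    return entries


def entries_to_frame(entries: Sequence[CalibrationEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        row = {
            "sample_id": e.sample_id,
            "cover": e.cover,
            "sigma": e.sigma,
            "context": e.context,
            "ap": e.ap,
            "height_pass": e.height_pass,
        }
        row.update({f"pft_{p}": v for p, v in zip(e.pft_vector.pfts, e.pft_vector.scores)})
        rows.append(row)
    return pd.DataFrame(rows)
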