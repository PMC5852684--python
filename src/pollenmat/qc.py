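"""Sample-exclusion rules for the modern calibration pool and fossil series.

The modern rules are conjunctive (a sample survives only if it trips no
rule), so the surviving set does not depend on rule order; the per-sample
report still records every rule a sample trips, in application order:

1. duplicate removal (identical coordinates + identical assemblage),
2. geolocation error > 100 m,
3. |sample elevation - DEM elevation| > 200 m,
4. riverine / estuarine context,
5. terrestrial pollen sum <= 100 grains,
6. land-class consistency (open-context samples inside forested classes
   with cover > 15 % and median tree height > 0, and vice versa),
7. AP/cover consistency (AP > 80 % with extracted cover < 25 %), from which
   extensive treeless contexts (tundra, deserts, alpine grasslands) are
   exempt because long-distance arboreal pollen dominates their sums.

Samples with *missing* location error are retained so the analog pool is not
depopulated.  The fossil set only gets the minimum-count rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationEntry, median_height_within
from .data_io import PollenSample, RasterGrid
from .synthetic import CLASS_FOREST, CLASS_OPEN, CLASS_WATER

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    max_location_error_m: float = 100.0
    max_elevation_mismatch_m: float = 200.0
    min_terrestrial_count: float = 100.0  # strictly-greater-than rule
    ap_threshold: float = 80.0
    cover_threshold: float = 25.0
    open_forest_cover: float = 15.0
    excluded_contexts: frozenset[str] = frozenset({"riverine", "estuarine"})
    exempt_treeless_contexts: frozenset[str] = frozenset({"treeless", "tundra"})
    open_contexts: frozenset[str] = frozenset({"treeless", "tundra", "pasture"})
    forest_contexts: frozenset[str] = frozenset({"dense_forest", "forest_undefined"})
    strict_count: bool = True


RULES = (
    "duplicate",
    "location_error",
    "elevation_mismatch",
    "excluded_context",
    "low_count",
    "landclass_inconsistent",
    "ap_cover",
)


@dataclass
class QCReport:
    verdicts: pd.DataFrame  # columns: sample_id, kept, rules (comma-joined)

    @property
    def rule_counts(self) -> pd.Series:
        counts = {r: 0 for r in RULES}
        for rules in self.verdicts["rules"]:
            for r in rules.split(",") if rules else []:
                counts[r] += 1
        return pd.Series(counts)

    @property
    def surviving_ids(self) -> list[str]:
        return self.verdicts.loc[self.verdicts["kept"], "sample_id"].tolist()


def _count_fails(count: float, config: QCConfig) -> bool:
    if config.strict_count:
        return not count > config.min_terrestrial_count
    return count < config.min_terrestrial_count


def qc_modern(
    samples: Sequence[PollenSample],
    entries: Mapping[str, CalibrationEntry] | Sequence[CalibrationEntry],
    dem: RasterGrid | None,
    landclass: RasterGrid | None,
    height: RasterGrid | None = None,
    config: QCConfig = QCConfig(),
) -> tuple[QCReport, list[CalibrationEntry]]:
    """Apply the modern exclusion rules; returns the report and the
    calibration entries of surviving samples."""
    if not isinstance(entries, Mapping):
        entries = {e.sample_id: e for e in entries}

    # duplicate detection: first occurrence of (coords, assemblage) kept
    seen: dict[tuple, str] = {}
    duplicate: set[str] = set()
    for s in samples:
        key = (
            round(s.lon, 8),
            round(s.lat, 8),
            tuple(sorted((t, round(p, 6)) for t, p in s.percentages.items() if p > 0)),
        )
        if key in seen:
            duplicate.add(s.id)
        else:
            seen[key] = s.id

    if dem is None:
        logger.warning("DEM missing; elevation-mismatch rule skipped")

    rows = []
    survivors = []
    for s in samples:
        entry = entries.get(s.id)
        tripped: list[str] = []
        if s.id in duplicate:
            tripped.append("duplicate")
        if s.location_error is not None and s.location_error > config.max_location_error_m:
            tripped.append("location_error")
        if dem is not None and np.isfinite(s.elevation) and dem.contains(s.lon, s.lat):
            dem_elev = dem.value_at(s.lon, s.lat)
            if dem_elev not in (dem.nodata, dem.water) and abs(s.elevation - dem_elev) > config.max_elevation_mismatch_m:
                tripped.append("elevation_mismatch")
        if s.context in config.excluded_contexts:
            tripped.append("excluded_context")
        if _count_fails(s.count_total, config):
            tripped.append("low_count")
        if entry is not None and landclass is not None and landclass.contains(s.lon, s.lat):
            cls = landclass.value_at(s.lon, s.lat)
            med = (
                median_height_within(height, s.lon, s.lat, entry.sigma)
                if height is not None
                else np.nan
            )
            if (
                s.context in config.open_contexts
                and cls == CLASS_FOREST
                and np.isfinite(entry.cover)
                and entry.cover > config.open_forest_cover
                and np.isfinite(med)
                and med > 0
            ):
                tripped.append("landclass_inconsistent")
            elif (
                s.context in config.forest_contexts
                and cls == CLASS_OPEN
                and np.isfinite(entry.cover)
                and entry.cover < config.open_forest_cover
                and (np.isfinite(med) and med == 0)
            ):
                tripped.append("landclass_inconsistent")
        if (
            entry is not None
            and s.context not in config.exempt_treeless_contexts
            and entry.ap > config.ap_threshold
            and np.isfinite(entry.cover)
            and entry.cover < config.cover_threshold
        ):
            tripped.append("ap_cover")

        kept = not tripped and entry is not None
        rows.append({"sample_id": s.id, "kept": bool(kept), "rules": ",".join(tripped)})
        if kept:
            survivors.append(entry)
    return QCReport(pd.DataFrame(rows)), survivors


def qc_fossil(
    samples: Sequence[PollenSample],
    config: QCConfig = QCConfig(),
) -> list[PollenSample]:
    """Fossil series keep only the minimum terrestrial-count rule."""
    return [s for s in samples if not _count_fails(s.count_total, config)]
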