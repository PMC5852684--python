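"""End-to-end orchestration: simulate -> calibrate -> qc -> reconstruct ->
bias-correct -> map -> summarize.

This is the programmatic spine used by the command-line interface, the
examples and the recovery tests: a synthetic world with a known forest-cover
history is pushed through the full chain and the recovered regional series
can be compared against the generator's truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import biascorr, calibration, mapping, mat, qc, summaries, synthetic
from .data_io import GriddedField, PollenSample
from .pft import PFTDictionary, ap_percentage, synthetic_dictionary, taxa_to_pft

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    world: synthetic.SyntheticWorld
    entries: list[calibration.CalibrationEntry]
    qc_report: qc.QCReport
    survivors: list[calibration.CalibrationEntry]
    results: pd.DataFrame  # per-fossil-sample reconstructions
    cv: mat.CVResult
    curve: biascorr.CalibrationCurve
    fields: list[GriddedField]
    series: pd.DataFrame
    truth_series: pd.DataFrame


def reconstruct_fossils(
    fossils: Sequence[PollenSample],
    survivors: Sequence[calibration.CalibrationEntry],
    pft_dict: PFTDictionary,
    mat_config: mat.MATConfig = mat.MATConfig(),
    theta: float = 0.5,
    scheme: mapping.TimesliceScheme = mapping.TimesliceScheme(),
) -> pd.DataFrame:
    """Analog reconstruction for every fossil sample, timeslice-labelled."""
    matrix = np.vstack([e.pft_vector.normalized for e in survivors])
    covers = np.array([e.cover for e in survivors])
    ids = [e.sample_id for e in survivors]
    rows = []
    for s in fossils:
        vec = taxa_to_pft(s, pft_dict, theta).normalized
        res = mat.reconstruct(vec, config=mat_config, sample_id=s.id,
                              matrix=matrix, covers=covers, ids=ids)
        rows.append({
            "id": s.id, "site": s.site or s.id, "lon": s.lon, "lat": s.lat,
            "elevation": s.elevation, "age": s.age,
            "ap": ap_percentage(s, pft_dict),
            "prediction": res.prediction, "se": res.se,
            "n_used": res.n_used, "no_analog": res.no_analog,
        })
    df = pd.DataFrame(rows)
    return mapping.assign_timeslices(df, scheme)


def run_pipeline(
    world_config: synthetic.WorldConfig,
    mat_config: mat.MATConfig = mat.MATConfig(),
    cv_iterations: int = 99,
    interp_config: mapping.InterpolationConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the whole chain on a freshly generated synthetic world."""
    pft_dict = synthetic_dictionary()
    world = synthetic.generate_world(world_config)
    modern = synthetic.frame_to_samples(world.modern)

    entries = calibration.build_calibration(
        modern, world.cover, pft_dict,
        height_raster=world.height, landclass_raster=world.landclass,
    )
    report, survivors = qc.qc_modern(
        modern, entries, dem=world.elevation, landclass=world.landclass,
        height=world.height,
    )

    fossils = qc.qc_fossil(synthetic.frame_to_samples(world.cores))
    scheme = mapping.TimesliceScheme()
    results = reconstruct_fossils(fossils, survivors, pft_dict, mat_config, scheme=scheme)

    cv = mat.twofold_cv(survivors, iterations=cv_iterations, seed=seed, config=mat_config)
    curve = biascorr.fit_curve(
        cv.residuals["predicted"], cv.residuals["observed"],
        biascorr.ResampleConfig(iterations=max(cv_iterations, 99), seed=seed),
    )
    results["prediction_calibrated"] = biascorr.apply_curve(curve, results["prediction"])

    interp_config = interp_config or mapping.InterpolationConfig(
        low_density_radius_km=150.0, min_sites=5,
    )
    fields = mapping.map_slices(
        results, world.elevation, interp_config,
        variable="forest_cover", value_col="prediction_calibrated", scheme=scheme,
    )

    cfg = world.config
    region = summaries.RegionSpec(
        1, "whole_domain",
        box(cfg.lon_min, cfg.lat_min, cfg.lon_max, cfg.lat_max),
    )
    series = summaries.regional_series(fields, [region])
    truth_series = true_regional_series(world, [f.timeslice for f in fields])
    return PipelineResult(world, entries, report, survivors, results, cv, curve,
                          fields, series, truth_series)


def true_regional_series(
    world: synthetic.SyntheticWorld, centers: Sequence[float]
) -> pd.DataFrame:
    """Ground-truth area-mean cover per timeslice from the generator."""
    cover = world.cover
    land = cover.land_mask()
    glat = np.meshgrid(cover.lons(), cover.lats())[1]
    w = np.cos(np.radians(glat))[land]
    base = cover.values[land]
    elev = world.elevation.values[land]
    glon = np.meshgrid(cover.lons(), cover.lats())[0][land]
    glat_l = glat[land]
    rows = []
    for c in centers:
        m = np.asarray(world.config.fc_history(glon, glat_l, elev, np.full(base.shape, float(c))))
        fc = np.clip(base * m, 0.0, 100.0)
        rows.append({"timeslice": float(c), "true_mean": float(np.sum(w * fc) / np.sum(w))})
    return pd.DataFrame(rows)


def recovery_stats(series: pd.DataFrame, truth: pd.DataFrame, plateau_tol: float = 1.0) -> dict:
    """Correlation between recovered and true regional series, and how far
    the recovered maximum falls from the true one.

    A prescribed history can hold its maximum over a plateau, where the
    argmax of the true series is ill-defined; the true maximum is therefore
    treated as the *set* of slices within ``plateau_tol`` cover points of
    the true peak, and the offset is the distance (years) from the
    recovered peak age to that set (zero when it lands inside).
    """
    merged = series.merge(truth, on="timeslice")
    r = float(np.corrcoef(merged["mean"], merged["true_mean"])[0, 1])
    ages = merged["timeslice"].to_numpy(dtype=float)
    rec = merged["mean"].to_numpy(dtype=float)
    tru = merged["true_mean"].to_numpy(dtype=float)
    rec_peak = float(ages[np.argmax(rec)])
    plateau = ages[tru >= tru.max() - plateau_tol]
    offset = 0.0 if plateau.min() <= rec_peak <= plateau.max() else float(
        np.min(np.abs(plateau - rec_peak))
    )
    return {"r": r, "recovered_peak_bp": rec_peak,
            "true_peak_bp": float(ages[np.argmax(tru)]),
            "true_plateau_bp": (float(plateau.min()), float(plateau.max())),
            "peak_offset_yr": offset}
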