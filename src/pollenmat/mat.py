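"""The analog transfer function.

Dissimilarity between two assemblages (normalized proportion vectors p, q)
is the squared-chord distance

    d(p, q) = sum_k (sqrt(p_k) - sqrt(q_k))^2,   d in [0, 2].

For each fossil sample the k nearest calibration entries (default k = 8) are
selected; entries beyond the dissimilarity threshold T (default 0.3) are
discarded; the prediction is the inverse-distance-weighted mean of the
retained analogs' cover values, with standard error sd(covers)/sqrt(n).
A fossil sample whose nearest analog exceeds T has no analog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationEntry

logger = logging.getLogger(__name__)

# h-block cross-validation is deliberately not offered: European land cover
# is spatially fragmented enough that distance-based exclusion of training
# samples is not an appropriate screen for this response variable.
__all__ = [
    "MATConfig",
    "AnalogResult",
    "CVResult",
    "squared_chord",
    "reconstruct",
    "loo_cv",
    "twofold_cv",
    "no_analog_rates",
]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class MATConfig:
    k: int = 8
    threshold: float = 0.3
    epsilon: float = 1e-9  # zero-distance guard in the analog weights
    mode: Literal["pft", "taxa"] = "pft"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.threshold <= 0:
            raise ValidationError("threshold T must be positive")


@dataclass
class AnalogResult:
    sample_id: str
    analogs: list[tuple[str, float, float]]  # (analog id, distance, cover)
    n_used: int
    prediction: float  # NaN when no analog survives
    se: float  # NaN when n_used <= 1
    no_analog: bool


def _check_normalized(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if (v < -1e-12).any():
        raise ValidationError(f"{name} has negative components")
    s = v.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValidationError(f"{name} must sum to 1 (got {s:.6g})")
    return np.clip(v, 0.0, None)


def squared_chord(p: Sequence[float], q: Sequence[float]) -> float:
    """Squared-chord distance between two normalized assemblages."""
    p = _check_normalized(np.asarray(p), "p")
    q = _check_normalized(np.asarray(q), "q")
    if p.shape != q.shape:
        raise ValidationError("assemblage vectors differ in length")
    return float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def _distances(fossil: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    return np.sum((np.sqrt(matrix) - np.sqrt(fossil)[None, :]) ** 2, axis=1)


def _select(
    d: np.ndarray, ids: Sequence[str], config: MATConfig
) -> np.ndarray:
    """Indices of the k nearest entries, ties at the k-th rank included,
    stable in (distance, id) order."""
    order = sorted(range(len(d)), key=lambda i: (d[i], str(ids[i])))
    if len(order) <= config.k:
        return np.array(order, dtype=int)
    cutoff = d[order[config.k - 1]]
    take = list(order[: config.k])
    for i in order[config.k :]:
        if d[i] == cutoff:
            take.append(i)
        else:
            break
    return np.array(take, dtype=int)


def reconstruct(
    fossil: np.ndarray,
    calibration: Sequence[CalibrationEntry] | None = None,
    config: MATConfig = MATConfig(),
    sample_id: str = "",
    *,
    matrix: np.ndarray | None = None,
    covers: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
) -> AnalogResult:
    """Reconstruct one fossil sample against the calibration pool.

    The pool may be given either as entries or pre-assembled as
    (matrix of normalized assemblages, covers, ids) for speed.
    """
    if matrix is None:
        if not calibration:
            raise ValidationError("empty calibration pool")
        matrix = np.vstack([e.pft_vector.normalized for e in calibration])
        covers = np.array([e.cover for e in calibration], dtype=float)
        ids = [e.sample_id for e in calibration]
    fossil = np.asarray(fossil, dtype=float)
    if fossil.sum() <= 0:
        raise ValidationError("all-zero fossil assemblage")
    fossil = _check_normalized(fossil, "fossil assemblage")

    d = _distances(fossil, matrix)
    take = _select(d, ids, config)
    within = take[d[take] <= config.threshold]
    analogs = [(str(ids[i]), float(d[i]), float(covers[i])) for i in within]
    n = len(within)
    if n == 0:
        return AnalogResult(sample_id, [], 0, float("nan"), float("nan"), True)
    dd = np.maximum(d[within], config.epsilon)
    w = 1.0 / dd
    cov = covers[within]
    pred = float(np.sum(w * cov) / np.sum(w))
    se = float(np.std(cov, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return AnalogResult(sample_id, analogs, n, pred, se, False)


@dataclass
class CVResult:
    r2: float
    rmsep: float
    residuals: pd.DataFrame  # columns: predicted, observed, residual, obs_class
    per_iteration: pd.DataFrame | None = None
    rmsep_by_k: pd.Series | None = None

    @property
    def best_k(self) -> int | None:
        if self.rmsep_by_k is None:
            return None
        return int(self.rmsep_by_k.idxmin())


def _obs_class(observed: np.ndarray) -> np.ndarray:
    """10-percentage-point observed-cover classes partitioning [0, 100]."""
    cls = np.floor(np.asarray(observed, dtype=float) / 10.0).astype(int)
    return np.clip(cls, 0, 9) * 10


def _pooled_stats(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(predicted) & np.isfinite(observed)
    predicted, observed = predicted[ok], observed[ok]
    if len(predicted) < 2:
        return float("nan"), float("nan")
    rmsep = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    if np.std(predicted) == 0 or np.std(observed) == 0:
        r2 = float("nan")  # degenerate: correlation undefined
    else:
        r2 = float(np.corrcoef(predicted, observed)[0, 1] ** 2)
    return r2, rmsep


def _pool_arrays(calibration: Sequence[CalibrationEntry]):
    matrix = np.vstack([e.pft_vector.normalized for e in calibration])
    covers = np.array([e.cover for e in calibration], dtype=float)
    ids = [e.sample_id for e in calibration]
    return matrix, covers, ids


def _predict_set(
    targets: np.ndarray,
    pool_matrix: np.ndarray,
    pool_covers: np.ndarray,
    pool_ids: Sequence[str],
    config: MATConfig,
) -> np.ndarray:
    out = np.full(len(targets), np.nan)
    for i, vec in enumerate(targets):
        res = reconstruct(vec, config=config, matrix=pool_matrix, covers=pool_covers, ids=pool_ids)
        out[i] = res.prediction
    return out


def loo_cv(
    calibration: Sequence[CalibrationEntry],
    config: MATConfig = MATConfig(),
    k_grid: Sequence[int] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation; optionally sweeps candidate k values
    and reports RMSEP per k (the analog-count selection exercise)."""
    if len(calibration) < config.k + 1:
        raise ValidationError("too few calibration entries for LOO")
    matrix, covers, ids = _pool_arrays(calibration)
    n = len(calibration)

    def run(k: int) -> np.ndarray:
        cfg = MATConfig(k=k, threshold=config.threshold, epsilon=config.epsilon, mode=config.mode)
        preds = np.full(n, np.nan)
        for i in range(n):
            keep = np.arange(n) != i
            res = reconstruct(
                matrix[i],
                config=cfg,
                matrix=matrix[keep],
                covers=covers[keep],
                ids=[ids[j] for j in range(n) if j != i],
            )
            preds[i] = res.prediction
        return preds

    predicted = run(config.k)
    r2, rmsep = _pooled_stats(predicted, covers)
    residuals = pd.DataFrame(
        {
            "sample_id": ids,
            "predicted": predicted,
            "observed": covers,
            "residual": predicted - covers,
            "obs_class": _obs_class(covers),
        }
    )
    rmsep_by_k = None
    if k_grid is not None:
        vals = {}
        for k in k_grid:
            _, v = _pooled_stats(run(k), covers)
            vals[int(k)] = v
        rmsep_by_k = pd.Series(vals)
    return CVResult(r2=r2, rmsep=rmsep, residuals=residuals, rmsep_by_k=rmsep_by_k)


def twofold_cv(
    calibration: Sequence[CalibrationEntry],
    iterations: int = 999,
    seed: int = 0,
    config: MATConfig = MATConfig(),
) -> CVResult:
    """Repeated random half-split cross-validation.

    Each iteration splits the pool into two halves (odd sizes: one half
    larger by 1); each half predicts the other; residuals are pooled over
    all iterations.
    """
    n = len(calibration)
    if n < 2 * (config.k + 1):
        raise ValidationError("too few calibration entries for two-fold CV")
    rng = np.random.default_rng(seed)
    matrix, covers, ids = _pool_arrays(calibration)
    preds_all, obs_all = [], []
    per_iter = []
    for it in range(iterations):
        perm = rng.permutation(n)
        half = n // 2
        a, b = perm[:half], perm[half:]
        preds = np.full(n, np.nan)
        for train, test in ((a, b), (b, a)):
            p = _predict_set(
                matrix[test],
                matrix[train],
                covers[train],
                [ids[j] for j in train],
                config,
            )
            preds[test] = p
        r2_i, rmsep_i = _pooled_stats(preds, covers)
        per_iter.append({"iteration": it, "r2": r2_i, "rmsep": rmsep_i})
        preds_all.append(preds)
        obs_all.append(covers)
    predicted = np.concatenate(preds_all)
    observed = np.concatenate(obs_all)
    r2, rmsep = _pooled_stats(predicted, observed)
    residuals = pd.DataFrame(
        {
            "predicted": predicted,
            "observed": observed,
            "residual": predicted - observed,
            "obs_class": _obs_class(observed),
        }
    )
    return CVResult(r2=r2, rmsep=rmsep, residuals=residuals, per_iteration=pd.DataFrame(per_iter))


def nearest_distance(fossil: np.ndarray, matrix: np.ndarray) -> float:
    return float(_distances(np.asarray(fossil, dtype=float), matrix).min())


def no_analog_rates(
    fossil_vectors: Mapping[float, Sequence[np.ndarray]],
    calibration_matrix: np.ndarray,
    config: MATConfig = MATConfig(),
) -> pd.Series:
    """Per-timeslice percentage of fossil samples whose nearest analog
    exceeds T.  ``fossil_vectors`` maps slice center -> list of normalized
    assemblage vectors (taxa- or PFT-mode, matching the calibration matrix).
    Empty slices yield NaN."""
    rates = {}
    for center, vecs in fossil_vectors.items():
        if len(vecs) == 0:
            rates[center] = float("nan")
            continue
        n_no = sum(
            1 for v in vecs if nearest_distance(np.asarray(v), calibration_matrix) > config.threshold
        )
        rates[center] = 100.0 * n_no / len(vecs)
    return pd.Series(rates).sort_index()
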