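"""Empirical distribution (quantile-mapping) bias correction.

The analog method systematically under-predicts high forest cover: dense
forest is rare in the modern landscape, so fossil samples from closed
forests find only moderately forested analogs.  The correction maps the
distribution of modeled values onto that of observed values:

1. the pooled (modeled, observed) cross-validation pairs are resampled with
   randomly placed 5-percentage-point-wide windows along the modeled axis
   (10 windows per iteration) to counter the predominance of low-cover
   samples; within each window the three quartiles of modeled and of
   observed values are extracted as paired points;
2. empirical quantiles of the pooled quartile points are computed at every
   second percentile (1, 3, ..., 99) for both margins;
3. a smoothing spline is fitted to the quantile-quantile pairs and projected
   onto the monotone cone, yielding an order-preserving calibration curve
   clamped to [0, 100].

The curve is applied mechanically to every prediction regardless of age,
composition or location; missing values and no-analog flags pass through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ResampleConfig:
    window_width: float = 5.0  # percentage points, along the modeled axis
    windows_per_iteration: int = 10
    iterations: int = 999
    percentiles: tuple[float, ...] = tuple(range(1, 100, 2))
    spline_lam: float | None = None  # None -> generalized cross-validation
    min_pairs_per_window: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window width must be positive")
        grid = np.asarray(self.percentiles, dtype=float)
        if not ((grid > 0).all() and (grid < 100).all() and (np.diff(grid) > 0).all()):
            raise ValueError("percentile grid must be strictly increasing within (0, 100)")


@dataclass
class CalibrationCurve:
    """Monotone mapping from raw analog prediction to corrected cover."""

    grid_x: np.ndarray  # dense support in [0, 100]
    grid_y: np.ndarray  # corrected values, non-decreasing, in [0, 100]
    support: pd.DataFrame | None = None  # quantile-quantile pairs
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        if (np.diff(self.grid_y) < -1e-9).any():
            raise FittingError("calibration curve is not monotone")

    def __call__(self, values):
        values = np.asarray(values, dtype=float)
        out = np.interp(values, self.grid_x, self.grid_y)
        out = np.clip(out, 0.0, 100.0)
        out = np.where(np.isnan(values), np.nan, out)
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.grid_x, "corrected": self.grid_y})

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        g = np.linspace(0.0, 100.0, 401)
        return cls(grid_x=g, grid_y=g.copy())


def _median_by_class(modeled: np.ndarray, observed: np.ndarray) -> pd.Series:
    cls = np.clip(np.floor(observed / 10.0).astype(int), 0, 9) * 10
    return pd.Series(modeled - observed).groupby(cls).median()


def fit_curve(
    modeled: Sequence[float],
    observed: Sequence[float],
    config: ResampleConfig = ResampleConfig(),
) -> CalibrationCurve:
    """Fit the quantile-mapping calibration curve from CV pairs."""
    modeled = np.asarray(modeled, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = np.isfinite(modeled) & np.isfinite(observed)
    modeled, observed = modeled[ok], observed[ok]
    if len(modeled) < 100:
        raise FittingError("need at least 100 (modeled, observed) pairs")

    rng = np.random.default_rng(config.seed)
    width = config.window_width
    qm_pts: list[np.ndarray] = []
    qo_pts: list[np.ndarray] = []
    n_windows = config.iterations * config.windows_per_iteration
    starts = rng.uniform(0.0, 100.0 - width, size=n_windows)
    skipped = 0
    for u in starts:
        inside = (modeled >= u) & (modeled < u + width)
        if inside.sum() < config.min_pairs_per_window:
            skipped += 1
            continue
        qm_pts.append(np.percentile(modeled[inside], (25, 50, 75)))
        qo_pts.append(np.percentile(observed[inside], (25, 50, 75)))
    if not qm_pts:
        raise FittingError("all resampling windows were empty")
    if skipped:
        logger.debug("%d of %d windows skipped (too few pairs)", skipped, n_windows)

    pooled_m = np.concatenate(qm_pts)
    pooled_o = np.concatenate(qo_pts)
    grid = np.asarray(config.percentiles, dtype=float)
    qx = np.percentile(pooled_m, grid)
    qy = np.percentile(pooled_o, grid)

    # collapse duplicate abscissae before the spline fit
    df = pd.DataFrame({"x": qx, "y": qy}).groupby("x", as_index=False).mean()
    x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if len(x) < 4:
        raise FittingError("too few distinct quantile support points")
    try:
        spline = make_smoothing_spline(x, y, lam=config.spline_lam)
        dense = np.linspace(0.0, 100.0, 401)
        fitted = spline(dense)
    except Exception as exc:  # pragma: no cover - degenerate spline systems
        logger.warning("spline fit failed (%s); falling back to linear interpolation", exc)
        dense = np.linspace(0.0, 100.0, 401)
        fitted = np.interp(dense, x, y)

    # beyond the quantile support the spline extrapolates wildly; pin the
    # tails to a linear continuation of the boundary quantile pairs
    lo, hi = x[0], x[-1]
    fitted = np.where(dense < lo, y[0] + (dense - lo), fitted)
    fitted = np.where(dense > hi, y[-1] + (dense - hi), fitted)

    iso = IsotonicRegression(y_min=0.0, y_max=100.0)
    mono = iso.fit_transform(dense, fitted)

    curve = CalibrationCurve(
        grid_x=dense,
        grid_y=mono,
        support=pd.DataFrame({"modeled_q": qx, "observed_q": qy, "percentile": grid}),
    )
    pre = _median_by_class(modeled, observed)
    post = _median_by_class(curve(modeled), observed)
    curve.diagnostics = pd.DataFrame({"median_residual_pre": pre, "median_residual_post": post})
    return curve


def apply_curve(curve: CalibrationCurve, predictions) -> np.ndarray:
    """Element-wise correction; missing values stay missing."""
    return curve(predictions)
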