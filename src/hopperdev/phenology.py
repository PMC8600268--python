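"""Development-index phenology: stage counts -> DI -> adult timing.

Field surveys tabulate individuals in six developmental classes
(instars 1-5 and adults).  The development index (DI) is the
count-weighted mean stage, ranging from 1 (all first instars) to 6 (all
adults).  DI rises smoothly through the season, so the timing of
adulthood is estimated by fitting a cubic smoothing spline to DI against
day of year or against cumulative growing degree-days and locating the
first upward crossing of DI = 5.5 — the point just before the curve
saturates at 6.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.optimize import brentq

__all__ = [
    "SurveyRecord",
    "DICurve",
    "AdultTimingEstimate",
    "development_index",
    "di_points",
    "smooth_di_series",
    "estimate_adult_timing",
]

logger = logging.getLogger(__name__)

N_STAGES = 6
DEFAULT_THRESHOLD = 5.5


@dataclass(frozen=True)
class SurveyRecord:
    """Stage counts from one field visit."""

    site: str
    doy: int
    counts: tuple[int, ...]  # stages 1..6

    def __post_init__(self) -> None:
        if len(self.counts) != N_STAGES:
            raise ValueError(f"expected {N_STAGES} stage counts, got {len(self.counts)}")
        if any(c < 0 or c != int(c) for c in self.counts):
            raise ValueError("stage counts must be non-negative integers")


def development_index(counts) -> float:
    """Count-weighted mean developmental stage, in [1, 6].

    counts: per-stage tallies for stages 1..6 (instars 1-5, adult=6).

    Raises
    ------
    ValueError
        If all counts are zero (no individuals observed).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] != N_STAGES:
        raise ValueError(f"expected {N_STAGES} stage counts, got {counts.shape[-1]}")
    if np.any(counts < 0):
        raise ValueError("stage counts must be non-negative")
    total = counts.sum(axis=-1)
    if np.any(total == 0):
        raise ValueError("all-zero stage counts: DI undefined")
    stages = np.arange(1, N_STAGES + 1, dtype=float)
    return (counts @ stages) / total


def di_points(surveys: pd.DataFrame, gdd: pd.DataFrame | None = None) -> pd.DataFrame:
    """DI per survey, optionally joined with cumulative GDD.

    Parameters
    ----------
    surveys:
        Table with columns ``site``, ``date`` (or ``doy``) and
        ``stage1``..``stage6``.  Rows with zero total count are dropped
        with a logged warning.
    gdd:
        Optional output of :func:`hopperdev.degree_days.cumulative_gdd`;
        when given, each survey is matched to its site/doy cumulative
        GDD and the result carries a ``gdd`` column.

    Returns
    -------
    DataFrame with columns ``site, doy, di, n`` (+ ``gdd``).
    """
    stage_cols = [f"stage{i}" for i in range(1, N_STAGES + 1)]
    missing = set(stage_cols) - set(surveys.columns)
    if missing:
        raise ValueError(f"survey table missing column(s): {sorted(missing)}")
    s = surveys.copy()
    if "doy" not in s.columns:
        s["doy"] = pd.to_datetime(s["date"]).dt.dayofyear
    counts = s[stage_cols].to_numpy(float)
    total = counts.sum(axis=1)
    empty = total == 0
    if empty.any():
        logger.warning("dropping %d survey record(s) with zero total count", empty.sum())
        s, counts, total = s[~empty], counts[~empty], total[~empty]
    out = pd.DataFrame(
        {
            "site": s["site"].to_numpy(),
            "doy": s["doy"].to_numpy(int),
            "di": development_index(counts),
            "n": total.astype(int),
        }
    )
    if gdd is not None:
        out = out.merge(gdd[["site", "doy", "gdd"]], on=["site", "doy"], how="left")
    return out


@dataclass
class DICurve:
    """A fitted cubic smoothing-spline DI curve on one axis."""

    spline: UnivariateSpline
    x_min: float
    x_max: float
    axis: str = "doy"
    smoothing: float = 0.0

    def __call__(self, x) -> np.ndarray:
        """Evaluate the curve, clamped to the DI range [1, 6]."""
        return np.clip(self.spline(np.asarray(x, dtype=float)), 1.0, N_STAGES)


class InsufficientDataError(ValueError):
    """Fewer points than a cubic smoothing spline can be fitted to."""


def _loocv_smoothing(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pick the spline smoothing factor by leave-one-out cross-validation.

    Candidates span interpolation (s ~ 0) to a near-parametric fit, on a
    log grid scaled by n * var(y).  The automatic choice keeps noiseless
    curves nearly interpolated while damping survey noise.
    """
    n = len(x)
    scale = n * max(np.var(y), 1e-8)
    candidates = scale * np.logspace(-6, 0, 13)
    best_s, best_err = float(candidates[0]), math.inf
    for s in candidates:
        err = 0.0
        ok = True
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            if m.sum() < 4:
                ok = False
                break
            try:
                sp = UnivariateSpline(x[m], y[m], w=w[m], k=3, s=s * (n - 1) / n)
            except Exception:
                ok = False
                break
            err += (float(sp(x[i])) - y[i]) ** 2
        if ok and err < best_err:
            best_err, best_s = err, float(s)
    return best_s


def smooth_di_series(
    x,
    di,
    weights=None,
    smoothing: float | str = "auto",
    axis: str = "doy",
) -> DICurve:
    """Fit a cubic smoothing spline to DI against doy or cumulative GDD.

    Surveys sharing an axis value are count-weighted-averaged before
    fitting.  The smoothing factor is chosen by leave-one-out
    cross-validation unless given explicitly.

    Raises
    ------
    InsufficientDataError
        With fewer than 4 distinct axis values (cubic spline minimum).
    """
    x = np.asarray(x, dtype=float)
    di = np.asarray(di, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.mean()  # s is on the weighted-residual scale; keep it comparable
    order = np.argsort(x, kind="stable")
    x, di, w = x[order], di[order], w[order]

    # average ties, weighting by counts
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size != x.size:
        wsum = np.bincount(inv, weights=w)
        di = np.bincount(inv, weights=w * di) / wsum
        x, w = ux, wsum

    if x.size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct axis values for a cubic spline, got {x.size}"
        )
    s = _loocv_smoothing(x, di, w) if smoothing == "auto" else float(smoothing)
    spline = UnivariateSpline(x, di, w=w, k=3, s=s)
    return DICurve(spline, float(x[0]), float(x[-1]), axis=axis, smoothing=s)


@dataclass(frozen=True)
class AdultTimingEstimate:
    """When the smoothed DI first crosses the adulthood threshold."""

    axis: str
    threshold: float
    value: float | None
    status: str  # "estimated" | "not_reached" | "insufficient_data"
    at_boundary: bool = False


def estimate_adult_timing(
    curve: DICurve,
    threshold: float = DEFAULT_THRESHOLD,
    n_grid: int = 2000,
) -> AdultTimingEstimate:
    """Locate the first upward crossing of DI = threshold.

    The fitted curve is scanned on a dense grid over the observed axis
    range; the first bracket where it passes the threshold from below is
    refined by root finding to 1e-3 axis units.  No extrapolation: if
    the curve never reaches the threshold the status is ``not_reached``;
    if the series already starts above it, the first axis value is
    returned with ``at_boundary=True``.
    """
    grid = np.linspace(curve.x_min, curve.x_max, n_grid)
    vals = curve(grid)
    if vals[0] >= threshold:
        return AdultTimingEstimate(curve.axis, threshold, float(grid[0]), "estimated", True)
    above = vals >= threshold
    if not above.any():
        return AdultTimingEstimate(curve.axis, threshold, None, "not_reached")
    i = int(np.argmax(above))
    f = lambda t: float(curve(t)) - threshold
    root = brentq(f, grid[i - 1], grid[i], xtol=1e-3)
    return AdultTimingEstimate(curve.axis, threshold, float(root), "estimated")
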