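"""Fluctuating-temperature Q10 models for development time and adult mass.

Under a square-wave regime with half-amplitude ``Tvar`` about a fixed
mean, an organism spends 12 h per day at the warm phase and 12 h at the
cool phase.  With an exponential (Q10-type) rate–temperature relation
normalized to rate 1 at the regime mean, the development accrued per day
is proportional to the bracket

    B(Q10, Tvar) = Q10**(Tvar/10) + Q10**(-Tvar/10)

so the number of days to adulthood is d = c / B and, symmetrically,
adult mass accumulated at a growth-rate Q10 over d days is
M = c * d * B.  Fitting (c, Q10) per experimental group by nonlinear
least squares yields a thermal-sensitivity estimate per group; dividing
all estimates by the largest expresses them as relative Q10s on (0, 1].

A built-in consequence of the paired models: if development time itself
follows the development model with the *same* Q10, the brackets cancel
and adult mass is independent of Tvar — accelerated development carries
no size cost under shared thermal sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RearingObservation",
    "Q10Fit",
    "UnidentifiableModelError",
    "development_days",
    "adult_mass",
    "fit_development_q10",
    "fit_growth_q10",
    "normalize_relative",
    "observations_to_frame",
]

# Optimizer settings: start Q10 at 2 (a typical biological rate
# sensitivity), bound it to (0.1, 20]; c is positive and started from a
# moment estimate.  Tolerance 1e-10 on the sum of squares.
Q10_BOUNDS = (0.1, 20.0)
_FIT_TOL = 1e-10
DEFAULT_GROUP_BY = ("site", "photoperiod", "sex")


class UnidentifiableModelError(ValueError):
    """Raised when a group's design cannot identify (c, Q10).

    Both models have two free parameters; a group observed at a single
    Tvar level provides only one design point.
    """


@dataclass(frozen=True)
class RearingObservation:
    """One individual's rearing outcome."""

    site: str
    sex: str
    photoperiod: str
    tvar: float
    development_days: float
    adult_mass: float
    mother_id: str | None = None

    def __post_init__(self) -> None:
        if self.development_days <= 0:
            raise ValueError("development_days must be > 0")
        if self.adult_mass <= 0:
            raise ValueError("adult_mass must be > 0")
        if self.tvar < 0:
            raise ValueError("tvar must be >= 0")


@dataclass(frozen=True)
class Q10Fit:
    """A fitted (c, Q10) pair for one experimental group."""

    group: tuple
    model: str  # "development" or "growth"
    q10: float
    c: float
    residual_sd: float
    n_obs: int
    converged: bool


def observations_to_frame(observations: Iterable[RearingObservation]) -> pd.DataFrame:
    """Convert observation records to the rearing-table layout."""
    return pd.DataFrame(
        {
            "site": [o.site for o in observations],
            "sex": [o.sex for o in observations],
            "photoperiod": [o.photoperiod for o in observations],
            "tvar_c": [o.tvar for o in observations],
            "dev_days": [o.development_days for o in observations],
            "mass_g": [o.adult_mass for o in observations],
            "mother_id": [o.mother_id for o in observations],
        }
    )


def _bracket(q10, tvar):
    q10 = np.asarray(q10, dtype=float)
    tvar = np.asarray(tvar, dtype=float)
    return q10 ** (tvar / 10.0) + q10 ** (-tvar / 10.0)


def development_days(c, q10, tvar):
    """Days to adulthood under the fluctuating-temperature model.

    d = c / [Q10**(Tvar/10) + Q10**(-Tvar/10)].  Strictly decreasing in
    Tvar for Q10 > 1 (warm-phase acceleration outweighs cool-phase
    slowing) and increasing for Q10 < 1.  At Tvar = 0 or Q10 = 1 the
    bracket equals 2 and d = c/2.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("c must be > 0")
    if np.any(np.asarray(q10, dtype=float) <= 0):
        raise ValueError("q10 must be > 0")
    if np.any(np.asarray(tvar, dtype=float) < 0):
        raise ValueError("tvar must be >= 0")
    out = c / _bracket(q10, tvar)
    return float(out) if out.ndim == 0 else out


def adult_mass(c, d, q10, tvar):
    """Adult mass under the fluctuating-temperature growth model.

    M = c * d * [Q10**(Tvar/10) + Q10**(-Tvar/10)], with development
    time d entering as a known covariate.
    """
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(c <= 0):
        raise ValueError("c must be > 0")
    if np.any(d <= 0):
        raise ValueError("d must be > 0")
    if np.any(np.asarray(q10, dtype=float) <= 0):
        raise ValueError("q10 must be > 0")
    if np.any(np.asarray(tvar, dtype=float) < 0):
        raise ValueError("tvar must be >= 0")
    out = c * d * _bracket(q10, tvar)
    return float(out) if out.ndim == 0 else out


def _check_identifiable(group_key: tuple, tvar: np.ndarray) -> None:
    if np.unique(tvar).size < 2:
        raise UnidentifiableModelError(
            f"group {group_key}: only one distinct Tvar level "
            f"({np.unique(tvar)[0]:g}); two parameters (c, q10) need at "
            "least two"
        )


def _fit_group(x, y, f, c0):
    """Least-squares fit of (c, q10); returns (c, q10, residual_sd, converged)."""
    try:
        popt, _ = curve_fit(
            f,
            x,
            y,
            p0=(c0, 2.0),
            bounds=((1e-12, Q10_BOUNDS[0]), (np.inf, Q10_BOUNDS[1])),
            ftol=_FIT_TOL,
            xtol=_FIT_TOL,
            gtol=_FIT_TOL,
            maxfev=20000,
        )
        converged = True
    except RuntimeError:  # max evaluations without convergence
        return np.nan, np.nan, np.nan, False
    c_hat, q10_hat = popt
    resid = y - f(x, c_hat, q10_hat)
    dof = max(len(y) - 2, 1)
    return float(c_hat), float(q10_hat), float(np.sqrt(resid @ resid / dof)), converged


def fit_development_q10(
    observations: pd.DataFrame,
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
) -> list[Q10Fit]:
    """Fit the development-time model per group.

    Parameters
    ----------
    observations:
        Rearing table with columns ``tvar_c``, ``dev_days`` plus the
        grouping columns (default site, photoperiod, sex).
    group_by:
        Columns defining independent fits; no parameters are shared
        across groups.

    Returns
    -------
    list of :class:`Q10Fit`, one per group, in group-sorted order.
    Groups where the optimizer fails to converge are returned with
    ``converged=False`` rather than raising.

    Raises
    ------
    UnidentifiableModelError
        If any group contains a single distinct Tvar level.
    """
    fits: list[Q10Fit] = []
    for key, sub in observations.groupby(list(group_by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        tvar = sub["tvar_c"].to_numpy(float)
        d = sub["dev_days"].to_numpy(float)
        _check_identifiable(key, tvar)
        c_hat, q10_hat, sd, ok = _fit_group(
            tvar, d, lambda x, c, q: c / _bracket(q, x), c0=2.0 * d.mean()
        )
        fits.append(Q10Fit(key, "development", q10_hat, c_hat, sd, len(sub), ok))
    return fits


def fit_growth_q10(
    observations: pd.DataFrame,
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
) -> list[Q10Fit]:
    """Fit the adult-mass model per group.

    Mass is the response; observed development days enter as a known
    covariate.  Requires columns ``tvar_c``, ``dev_days``, ``mass_g``.
    """
    fits: list[Q10Fit] = []
    for key, sub in observations.groupby(list(group_by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        tvar = sub["tvar_c"].to_numpy(float)
        d = sub["dev_days"].to_numpy(float)
        m = sub["mass_g"].to_numpy(float)
        _check_identifiable(key, tvar)
        x = np.vstack([tvar, d])
        c_hat, q10_hat, sd, ok = _fit_group(
            x,
            m,
            lambda xd, c, q: c * xd[1] * _bracket(q, xd[0]),
            c0=float(np.mean(m / (2.0 * d))),
        )
        fits.append(Q10Fit(key, "growth", q10_hat, c_hat, sd, len(sub), ok))
    return fits


def normalize_relative(fits: Sequence[Q10Fit]) -> list[tuple[tuple, float]]:
    """Express fitted Q10s relative to the largest, which maps to 1.

    Order and ratios are preserved; the result is scale-invariant and
    idempotent.  All fits passed in one call share one normalization
    constant (one shared axis); call separately per subset for
    per-subset normalization.
    """
    if not fits:
        raise ValueError("normalize_relative requires at least one fit")
    q10s = np.array([f.q10 for f in fits], dtype=float)
    if np.any(~np.isfinite(q10s)) or np.any(q10s <= 0):
        raise ValueError("all fits must have finite positive q10")
    rel = q10s / q10s.max()
    return [(f.group, float(r)) for f, r in zip(fits, rel)]
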