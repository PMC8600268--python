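"""Growing degree-days from daily Tmin/Tmax by the single-sine method.

The daily temperature course is modelled as one symmetric sine wave
between the day's minimum and maximum, with a fixed 12 h spacing between
the minimum and the maximum.  Degree-days are the area of that sine
above the lower developmental threshold (LDT), integrated analytically:

with Tmean = (tmin + tmax)/2 and alpha = (tmax - tmin)/2,

* LDT <= tmin: the whole wave is above threshold -> Tmean - LDT
* LDT >= tmax: the whole wave is below threshold -> 0
* otherwise (the sine is intercepted):
    (1/pi) * [(Tmean - LDT) * (pi/2 - theta) + alpha * cos(theta)],
    theta = arcsin((LDT - Tmean)/alpha)

The default LDT is 0 °C, the constant-temperature rearing estimate for
the focal montane grasshopper; the 12 °C threshold from earlier pooled
field fits can be supplied instead.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "daily_degree_days_single_sine",
    "cumulative_gdd",
    "season_gdd",
]

DEFAULT_LDT = 0.0


def daily_degree_days_single_sine(tmin, tmax, ldt: float = DEFAULT_LDT):
    """Degree-days (°C·day) for one day from its Tmin/Tmax.

    Vectorized over tmin/tmax.  Continuous across the case boundaries
    ldt = tmin and ldt = tmax.

    Raises
    ------
    ValueError
        If any tmax < tmin.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        bad = np.argwhere(tmax < tmin).ravel()
        raise ValueError(
            f"tmax < tmin at position(s) {bad.tolist()}: "
            "daily extremes are inconsistent"
        )
    tmean = (tmin + tmax) / 2.0
    alpha = (tmax - tmin) / 2.0

    above = ldt <= tmin
    below = ldt >= tmax
    intercepted = ~(above | below)

    dd = np.where(above, tmean - ldt, 0.0)
    if np.any(intercepted):
        # alpha > 0 wherever intercepted (tmin < ldt < tmax)
        a = np.where(intercepted, alpha, 1.0)
        theta = np.arcsin(np.clip((ldt - tmean) / a, -1.0, 1.0))
        part = (1.0 / np.pi) * ((tmean - ldt) * (np.pi / 2.0 - theta) + a * np.cos(theta))
        dd = np.where(intercepted, part, dd)
    return float(dd) if dd.ndim == 0 else dd


def _validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    required = {"site", "date", "tmin_c", "tmax_c"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"weather table missing column(s): {sorted(missing)}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    for site, sub in w.groupby("site", sort=False):
        if not sub["date"].is_monotonic_increasing:
            raise ValueError(f"site {site!r}: dates are not sorted ascending")
        if sub["date"].duplicated().any():
            dup = sub.loc[sub["date"].duplicated(), "date"].iloc[0]
            raise ValueError(f"site {site!r}: duplicate date {dup.date()}")
    return w


def cumulative_gdd(
    weather: pd.DataFrame,
    ldt: float = DEFAULT_LDT,
    start_doy: int = 1,
    allow_gaps: bool = False,
) -> pd.DataFrame:
    """Daily and cumulative degree-days per site.

    Parameters
    ----------
    weather:
        Table with columns ``site``, ``date`` (ISO-8601 or datetime),
        ``tmin_c``, ``tmax_c``; sorted ascending and date-unique per
        site.
    ldt:
        Lower developmental threshold, °C.
    start_doy:
        1-based day of year at which accumulation starts; earlier days
        are dropped.
    allow_gaps:
        Missing calendar days are a hard error by default; when True,
        gaps are skipped and the returned frame carries
        ``attrs["contiguous"] = False`` (cumulative values are then
        lower bounds).

    Returns
    -------
    DataFrame with columns ``site, date, doy, dd, gdd``; ``gdd`` is the
    running within-site sum of ``dd`` and is non-decreasing.
    """
    w = _validate_weather(weather)
    w["doy"] = w["date"].dt.dayofyear
    w = w[w["doy"] >= start_doy].reset_index(drop=True)
    contiguous = True
    for site, sub in w.groupby("site", sort=False):
        step = sub["date"].diff().dt.days.iloc[1:]
        if (step > 1).any():
            if not allow_gaps:
                gap_at = sub["date"].iloc[int(np.argmax(step.to_numpy() > 1)) + 1]
                raise ValueError(
                    f"site {site!r}: gap in daily series before "
                    f"{gap_at.date()}; pass allow_gaps=True to skip"
                )
            contiguous = False
    out = w[["site", "date", "doy"]].copy()
    out["dd"] = daily_degree_days_single_sine(
        w["tmin_c"].to_numpy(), w["tmax_c"].to_numpy(), ldt
    )
    out["gdd"] = out.groupby("site", sort=False)["dd"].cumsum()
    out.attrs["contiguous"] = contiguous
    out.attrs["ldt"] = float(ldt)
    out.attrs["start_doy"] = int(start_doy)
    return out


def season_gdd(
    weather: pd.DataFrame,
    ldt: float = DEFAULT_LDT,
    window: Sequence[int] = (1, 366),
) -> pd.Series:
    """Total degree-days within a day-of-year window, per site.

    Used to rank seasons warm -> cool.  ``window`` is an inclusive
    (start_doy, end_doy) pair.

    Returns a Series indexed by site.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window ({lo}, {hi})")
    series = cumulative_gdd(weather, ldt=ldt, start_doy=1, allow_gaps=True)
    series = series[(series["doy"] >= lo) & (series["doy"] <= hi)]
    if series.empty:
        raise ValueError(f"no weather records in doy window ({lo}, {hi})")
    return series.groupby("site", sort=False)["dd"].sum()
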