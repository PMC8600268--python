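"""Synthetic rearing cohorts, weather series, and stage-count surveys.

The generator emulates the study design end-to-end so every analysis
stage is testable without external data:

* a 2 x 2 rearing design — high (±4 °C) vs low (±2 °C) diurnal
  square-wave amplitude about a 24 °C mean, crossed with long (14:10)
  vs short (12:12) photoperiods — over three source sites on an
  elevation gradient (2,195 / 2,591 / 3,048 m) and two sexes;
* daily site weather as a sinusoidal annual cycle with a fixed diurnal
  range, day-to-day noise, and cooler offsets for higher sites;
* weekly stage-count surveys of a cohort whose individuals advance
  through six developmental classes as cumulative growing degree-days
  pass per-stage requirements, with binomial detection.

Development-time and mass outcomes are drawn from the fluctuating-
temperature Q10 models, so fitted parameters can be checked against the
configured truths.  Everything is a pure function of (config, seed):
per-generator streams are spawned from one root seed and repeated runs
are byte-identical.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degree_days import cumulative_gdd
from .q10fit import adult_mass, development_days

__all__ = [
    "DesignCell",
    "SimulationConfig",
    "daylength",
    "simulate_rearing_cohort",
    "simulate_weather",
    "simulate_surveys",
]

SITES = {"A1": 2195, "B1": 2591, "C1": 3048}
STUDY_LATITUDE = 40.03  # degrees N, the elevation transect's parallel


@dataclass(frozen=True)
class DesignCell:
    """One rearing-design cell with its generating parameters."""

    site: str
    photoperiod: str  # "long" (14:10) or "short" (12:12)
    sex: str
    tvar: float  # °C half-amplitude (HV=4, LV=2 in the design)
    c_dev: float
    q10_dev: float
    c_growth: float
    q10_growth: float
    n: int = 10  # individuals per (treatment, site, sex) cell

    def validate(self) -> None:
        if self.tvar < 0:
            raise ValueError(f"cell {self.key()}: tvar must be >= 0")
        if min(self.c_dev, self.q10_dev, self.c_growth, self.q10_growth) <= 0:
            raise ValueError(f"cell {self.key()}: model parameters must be > 0")
        if self.n < 1:
            raise ValueError(f"cell {self.key()}: n must be >= 1")

    def key(self) -> tuple:
        return (self.site, self.photoperiod, self.sex, self.tvar)


def default_design(n_per_cell: int = 10) -> list[DesignCell]:
    """The emulated rearing design.

    Thermal sensitivity of development is flat across sites under long
    days but increases with elevation under short days (the focal
    plasticity pattern); growth Q10s are flat across sites with females
    slightly above males.  c_dev ≈ 100 development-units puts
    development times in the observed 40–55 day range; c_growth is set
    so adult mass falls near 0.5 g.
    """
    q10_dev_short = {"A1": 1.8, "B1": 2.5, "C1": 3.5}
    q10_growth_sex = {"female": 2.2, "male": 1.8}
    cells = []
    for site in SITES:
        for photoperiod in ("long", "short"):
            q10_dev = 2.0 if photoperiod == "long" else q10_dev_short[site]
            for sex in ("female", "male"):
                for tvar in (2.0, 4.0):
                    cells.append(
                        DesignCell(
                            site=site,
                            photoperiod=photoperiod,
                            sex=sex,
                            tvar=tvar,
                            c_dev=100.0,
                            q10_dev=q10_dev,
                            c_growth=0.005,
                            q10_growth=q10_growth_sex[sex],
                            n=n_per_cell,
                        )
                    )
    return cells


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the three generators, with study-design defaults."""

    seed: int = 0
    design: tuple[DesignCell, ...] = field(
        default_factory=lambda: tuple(default_design())
    )
    noise_sd_days: float = 2.0
    noise_sd_mass: float = 0.05  # g

    # weather: annual sinusoid for the daily mean + diurnal range
    annual_mean_c: float = 9.0  # reference (lowest) site
    seasonal_amplitude_c: float = 12.0
    peak_doy: int = 200
    diurnal_range_c: float = 12.0
    day_noise_sd_c: float = 2.0
    site_offsets_c: dict = field(
        default_factory=lambda: {"A1": 0.0, "B1": -2.5, "C1": -5.5}
    )

    # surveys: GDD-driven stage progression
    cohort_size: int = 100
    survey_interval_days: int = 7
    survey_start_doy: int = 100
    survey_end_doy: int = 260
    detection_prob: float = 0.7
    # cumulative GDD (°C·day, LDT 0) required to *enter* stages 2..6
    stage_gdd_requirements: tuple[float, ...] = (250.0, 400.0, 550.0, 700.0, 850.0)
    hatch_mode: str = "gdd"  # "gdd": hatch at a GDD requirement; "doy": calendar
    hatch_gdd_mean: float = 120.0
    hatch_gdd_sd: float = 40.0
    hatch_doy_mean: float = 130.0
    hatch_doy_sd: float = 7.0
    # optional photoperiod modulation of development rate:
    # multiplier 1 + beta * (p0 - daylength(doy)) / p0, default off
    daylength_beta: float = 0.0
    daylength_p0: float = 14.0
    latitude: float = STUDY_LATITUDE

    def validate(self) -> None:
        if self.noise_sd_days < 0 or self.noise_sd_mass < 0 or self.day_noise_sd_c < 0:
            raise ValueError("noise standard deviations must be >= 0")
        req = self.stage_gdd_requirements
        if len(req) != 5 or any(b <= a for a, b in zip(req, req[1:])):
            raise ValueError(
                "stage_gdd_requirements must be 5 strictly increasing values "
                "(entry to stages 2..6)"
            )
        if self.hatch_mode not in ("gdd", "doy"):
            raise ValueError(f"unknown hatch_mode {self.hatch_mode!r}")
        for cell in self.design:
            cell.validate()


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators (PCG64) spawned from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _rngs(config: SimulationConfig) -> dict[str, np.random.Generator]:
    rearing, weather, surveys = _streams(config.seed, 3)
    return {"rearing": rearing, "weather": weather, "surveys": surveys}


def daylength(doy: float, latitude: float) -> float:
    """Hours of daylight from the standard hour-angle formula.

    Solar declination is approximated by a sinusoid of day of year;
    daylength follows as (24/pi) * arccos(-tan(lat) * tan(decl)), with
    the arccos argument clipped at the polar day/night limits.

    Raises
    ------
    ValueError
        For latitudes poleward of ±66° (polar day/night regimes are out
        of scope) or doy outside [1, 366].
    """
    if not -66.0 < latitude < 66.0:
        raise ValueError(f"latitude {latitude} is outside the supported (-66, 66)")
    if not 1 <= doy <= 366:
        raise ValueError(f"doy {doy} outside [1, 366]")
    decl = math.radians(23.44) * math.sin(2.0 * math.pi * (284.0 + doy) / 365.0)
    cos_h = -math.tan(math.radians(latitude)) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


def simulate_rearing_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Individual rearing outcomes on the configured design.

    Per cell, n individuals with development time
    d = development_days(c_dev, q10_dev, tvar) + N(0, noise_sd_days)
    and mass M = adult_mass(c_growth, d_model, q10_growth, tvar)
    + N(0, noise_sd_mass), both truncated positive (redrawn).  Mass
    noise is applied about the model surface evaluated at the model
    development time, so the two responses carry independent errors.

    Returns the rearing-table layout: site, elevation_m, sex,
    photoperiod, tvar_c, dev_days, mass_g, mother_id.
    """
    config.validate()
    rng = _rngs(config)["rearing"]
    rows = []
    for cell in config.design:
        d_model = development_days(cell.c_dev, cell.q10_dev, cell.tvar)
        m_model = adult_mass(cell.c_growth, d_model, cell.q10_growth, cell.tvar)
        for i in range(cell.n):
            d = _positive_normal(rng, d_model, config.noise_sd_days)
            m = _positive_normal(rng, m_model, config.noise_sd_mass)
            rows.append(
                {
                    "site": cell.site,
                    "elevation_m": SITES.get(cell.site, np.nan),
                    "sex": cell.sex,
                    "photoperiod": cell.photoperiod,
                    "tvar_c": cell.tvar,
                    "dev_days": d,
                    "mass_g": m,
                    "mother_id": f"{cell.site}-{cell.sex[0]}{i % 5}",
                }
            )
    return pd.DataFrame(rows)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("positive-truncated normal failed after 1000 draws")


def simulate_weather(
    config: SimulationConfig, site: str = "A1", year: int = 2015
) -> pd.DataFrame:
    """One site-year of daily Tmin/Tmax.

    Daily mean = annual_mean + site offset + seasonal sinusoid peaking
    at ``peak_doy`` + N(0, day_noise_sd); Tmin/Tmax are the mean minus/
    plus half the fixed diurnal range (tmax >= tmin by construction).
    The weather stream is seeded per (site, year) so different
    site-years are independent but reproducible.
    """
    config.validate()
    site_code = zlib.crc32(str(site).encode()) % (2**31)
    key = np.random.SeedSequence([config.seed, site_code, int(year)])
    rng = np.random.default_rng(key)
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    offset = config.site_offsets_c.get(site, 0.0)
    mean = (
        config.annual_mean_c
        + offset
        + config.seasonal_amplitude_c
        * np.cos(2.0 * np.pi * (doy - config.peak_doy) / 365.25)
        + rng.normal(0.0, config.day_noise_sd_c, size=doy.size)
    )
    half = config.diurnal_range_c / 2.0
    return pd.DataFrame(
        {
            "site": site,
            "date": dates,
            "tmin_c": mean - half,
            "tmax_c": mean + half,
        }
    )


def _stage_from_phys_time(phys: np.ndarray, hatch_req: np.ndarray, stage_req) -> np.ndarray:
    """Stage (1..6) of each individual given its physiological time.

    ``phys`` is each individual's accumulated (possibly daylength-
    modulated) degree-days; pre-hatch individuals are stage 0 and are
    not surveyed.
    """
    post = phys[:, None] - hatch_req[:, None] - np.asarray(stage_req)[None, :]
    stage = 1 + (post >= 0).sum(axis=1)
    stage[phys < hatch_req] = 0
    return stage


def simulate_surveys(
    config: SimulationConfig,
    weather: pd.DataFrame,
    return_truth: bool = False,
):
    """Weekly stage-count surveys of a GDD-driven cohort.

    Each individual hatches once its site's cumulative GDD passes a
    per-individual requirement (Gaussian spread; or on a Gaussian
    calendar date with hatch_mode="doy") and then advances one stage
    each time accumulated physiological time passes that stage's
    requirement.  Physiological time is daily degree-days optionally
    scaled by the photoperiod multiplier
    ``1 + beta * (p0 - daylength(doy)) / p0`` (beta = 0: pure GDD
    development, making population stage structure an exact function of
    cumulative GDD).  Surveys every ``survey_interval_days`` draw a
    binomial detection sample of hatched individuals and tabulate
    stages 1-6.

    Returns the survey table (site, date, doy, stage1..stage6); with
    ``return_truth=True`` also a per-day frame of true cohort stages
    and DI.
    """
    config.validate()
    rng = _rngs(config)["surveys"]
    site = weather["site"].iloc[0]
    gdd = cumulative_gdd(weather, ldt=0.0, allow_gaps=True)
    doy = gdd["doy"].to_numpy(int)
    dd = gdd["dd"].to_numpy(float)
    cum = gdd["gdd"].to_numpy(float)

    if config.daylength_beta != 0.0:
        mult = np.array(
            [
                1.0
                + config.daylength_beta
                * (config.daylength_p0 - daylength(int(d), config.latitude))
                / config.daylength_p0
                for d in doy
            ]
        )
        phys = np.cumsum(dd * mult)
    else:
        phys = cum

    n = config.cohort_size
    if config.hatch_mode == "gdd":
        hatch_req = np.clip(
            rng.normal(config.hatch_gdd_mean, config.hatch_gdd_sd, n), 0.0, None
        )
    else:
        hatch_doy = rng.normal(config.hatch_doy_mean, config.hatch_doy_sd, n)
        # convert each calendar hatch date to the GDD already accrued then
        hatch_req = np.interp(hatch_doy, doy, phys)

    survey_doys = np.arange(
        config.survey_start_doy, config.survey_end_doy + 1, config.survey_interval_days
    )
    date_by_doy = dict(zip(doy, pd.to_datetime(gdd["date"]).dt.date))
    rows = []
    for sdoy in survey_doys:
        if sdoy not in date_by_doy:
            continue
        i = int(np.searchsorted(doy, sdoy))
        stage = _stage_from_phys_time(phys[i : i + 1].repeat(n), hatch_req,
                                      config.stage_gdd_requirements)
        hatched = stage > 0
        detected = hatched & (rng.random(n) < config.detection_prob)
        counts = np.bincount(stage[detected], minlength=7)[1:7]
        rows.append(
            {"site": site, "date": date_by_doy[sdoy], "doy": int(sdoy),
             **{f"stage{k + 1}": int(counts[k]) for k in range(6)}}
        )
    surveys = pd.DataFrame(rows)
    if not return_truth:
        return surveys

    truth_rows = []
    for i, d_ in enumerate(doy):
        stage = _stage_from_phys_time(phys[i : i + 1].repeat(n), hatch_req,
                                      config.stage_gdd_requirements)
        hatched = stage > 0
        di = float(stage[hatched].mean()) if hatched.any() else np.nan
        truth_rows.append(
            {"site": site, "doy": int(d_), "gdd": float(cum[i]),
             "n_hatched": int(hatched.sum()), "di_true": di}
        )
    return surveys, pd.DataFrame(truth_rows)
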