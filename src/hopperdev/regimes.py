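"""Square-wave rearing regimes and constant-temperature equivalents.

A diurnal square-wave regime alternates 12 h at ``mean + amplitude`` with
12 h at ``mean - amplitude``.  Because development rate is a convex
(exponential, Q10-type) function of temperature, such a fluctuating regime
is developmentally equivalent to a constant temperature *above* the
arithmetic mean; the constant temperature equivalent (CTE) quantifies
this.  Two published CTE formulations are provided:

``cte_rate_weighted``
    the development-rate-weighted mean of the two phase temperatures —
    the "median developmental temperature after accounting for
    development speed increasing with temperature".
``cte_rate_equivalent``
    the constant temperature whose rate equals the time-averaged rate
    over the cycle (closed form via the hyperbolic cosine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SquareWaveRegime",
    "ExponentialRateModel",
    "rate_at",
    "q10_from_rates",
    "cte_rate_weighted",
    "cte_rate_equivalent",
]


@dataclass(frozen=True)
class SquareWaveRegime:
    """A two-phase diurnal temperature + photoperiod treatment.

    Parameters
    ----------
    mean_temp:
        Cycle mean temperature, °C.
    amplitude:
        Half-amplitude of the square wave (the treatment's Tvar), °C;
        the warm phase sits at ``mean_temp + amplitude`` and the cool
        phase at ``mean_temp - amplitude``, each lasting 12 h.
    photophase_hours:
        Hours of light per 24 h cycle (scotophase is the remainder).
    label:
        Free-text treatment label, e.g. ``"HV-long"``.
    """

    mean_temp: float
    amplitude: float
    photophase_hours: float = 12.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0.0 <= self.photophase_hours <= 24.0:
            raise ValueError(
                f"photophase_hours must lie in [0, 24], got {self.photophase_hours}"
            )

    @property
    def scotophase_hours(self) -> float:
        return 24.0 - self.photophase_hours

    @property
    def warm_temp(self) -> float:
        return self.mean_temp + self.amplitude

    @property
    def cool_temp(self) -> float:
        return self.mean_temp - self.amplitude


@dataclass(frozen=True)
class ExponentialRateModel:
    """Q10-type exponential rate–temperature relationship.

    The rate at temperature T is ``R1 * q10 ** ((T - T1) / 10)``: every
    10 °C increase multiplies the rate by ``q10``.
    """

    q10: float
    reference_temp: float = 24.0
    reference_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.q10 <= 0:
            raise ValueError(f"q10 must be > 0, got {self.q10}")
        if self.reference_rate <= 0:
            raise ValueError(f"reference_rate must be > 0, got {self.reference_rate}")


def rate_at(model: ExponentialRateModel, temp: float) -> float:
    """Rate at ``temp`` °C under the exponential Q10 model.

    R(T) = R1 * Q10 ** ((T - T1) / 10); defined for all real temperatures.
    """
    return model.reference_rate * model.q10 ** ((temp - model.reference_temp) / 10.0)


def q10_from_rates(r1: float, t1: float, r2: float, t2: float) -> float:
    """Q10 implied by two (rate, temperature) observations.

    Q10 = (R2 / R1) ** (10 / (T2 - T1)); the inverse of :func:`rate_at`.

    Raises
    ------
    ValueError
        If the temperatures coincide (Q10 undefined) or a rate is
        non-positive (outside the model's domain).
    """
    if t1 == t2:
        raise ValueError("q10 is undefined for equal temperatures (t1 == t2)")
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"rates must be > 0, got r1={r1}, r2={r2}")
    return (r2 / r1) ** (10.0 / (t2 - t1))


def cte_rate_weighted(regime: SquareWaveRegime, model: ExponentialRateModel) -> float:
    """Rate-weighted-mean constant temperature equivalent, °C.

    Weights each phase temperature by the development rate realized
    there:

        CTE = [T_warm r(T_warm) + T_cool r(T_cool)] / [r(T_warm) + r(T_cool)]

    For q10 > 1 this exceeds the arithmetic mean — warm hours carry more
    development than cool hours.  Lies in
    ``[mean - amplitude, mean + amplitude]``.
    """
    rw = rate_at(model, regime.warm_temp)
    rc = rate_at(model, regime.cool_temp)
    return (regime.warm_temp * rw + regime.cool_temp * rc) / (rw + rc)


def cte_rate_equivalent(regime: SquareWaveRegime, model: ExponentialRateModel) -> float:
    """Rate-equivalent constant temperature, °C.

    The temperature T* at which the constant rate equals the 50:50
    time-average of the two phase rates.  Closed form for q10 != 1::

        T* = mean + (10 / ln q10) * ln(cosh((amplitude / 10) * ln q10))

    q10 = 1 (temperature-insensitive rate) is handled as the limit and
    returns the mean.
    """
    if regime.amplitude == 0 or model.q10 == 1.0:
        return regime.mean_temp
    lnq = math.log(model.q10)
    return regime.mean_temp + (10.0 / lnq) * math.log(
        math.cosh(regime.amplitude / 10.0 * lnq)
    )


# The study's rearing treatments: 24 °C mean, ±4 °C (HV) or ±2 °C (LV),
# crossed with long (14:10) and short (12:12) photoperiods.
STUDY_REGIMES: dict[str, SquareWaveRegime] = {
    "HV-long": SquareWaveRegime(24.0, 4.0, 14.0, "HV-long"),
    "HV-short": SquareWaveRegime(24.0, 4.0, 12.0, "HV-short"),
    "LV-long": SquareWaveRegime(24.0, 2.0, 14.0, "LV-long"),
    "LV-short": SquareWaveRegime(24.0, 2.0, 12.0, "LV-short"),
}
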