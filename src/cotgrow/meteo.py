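"""Daily and cumulative crop-growth drivers: growing degree days and FAO-56
Penman-Monteith reference evapotranspiration.

Two seasonal drivers are supported. Thermal time (GDD) accumulates the daily
mean temperature above a crop base temperature, with the mean clamped between
the crop's lower and upper activity limits (10 and 40 degC for cotton).
Reference evapotranspiration (ETo) is the atmospheric water demand of a
well-watered grass surface computed from net radiation, temperature, vapour
pressure deficit and wind speed. Either cumulative driver, divided by its
season total, maps the growing season onto the unit interval and serves as
the independent variable of the relative logistic growth models in
:mod:`cotgrow.growth`.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DriverKind",
    "WeatherDay",
    "ThermalLimits",
    "AtmosDerived",
    "AccumSeries",
    "saturation_vapor_pressure",
    "pressure_at_elevation",
    "actual_vapor_pressure_from_rh",
    "saturation_vapor_terms",
    "effective_mean_temperature",
    "daily_gdd",
    "cumulative_gdd",
    "daily_eto",
    "cumulative_eto",
    "relative_accumulation",
    "STANDARD_PRESSURE_KPA",
]

STANDARD_PRESSURE_KPA = 101.3


class DriverKind(str, enum.Enum):
    """Which cumulative driver a series or model parameterisation refers to."""

    CGDD = "CGDD"
    CETO = "CETO"


@dataclass(frozen=True)
class ThermalLimits:
    """Crop temperature activity window for thermal-time accumulation.

    Defaults are the cotton limits: growth effectively stops below 10 degC
    and does not accelerate further above 40 degC.
    """

    t_base: float = 10.0
    t_upper: float = 40.0

    def __post_init__(self) -> None:
        if not self.t_base < self.t_upper:
            raise ValueError(
                f"t_base ({self.t_base}) must be below t_upper ({self.t_upper})"
            )


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological forcing.

    Parameters
    ----------
    date : datetime.date
        Calendar day.
    t_max, t_min : float
        Daily maximum and minimum air temperature, degC.
    e_s, e_a : float
        Saturation and actual vapour pressure, kPa. Their difference is the
        vapour pressure deficit driving the aerodynamic ETo term.
    u2 : float
        Wind speed at 2 m, m/s.
    r_n : float
        Daily net radiation at the crop surface, MJ/m2/d.
    g_flux : float
        Soil heat flux, MJ/m2/d; negligible at the daily step, default 0.
    t_mean : float, optional
        Mean air temperature, degC; defaults to (t_max + t_min)/2.
    """

    date: datetime.date
    t_max: float
    t_min: float
    e_s: float
    e_a: float
    u2: float
    r_n: float
    g_flux: float = 0.0
    t_mean: float | None = None

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise ValueError(
                f"{self.date}: t_max ({self.t_max}) < t_min ({self.t_min})"
            )
        if not (self.e_s >= self.e_a >= 0.0):
            raise ValueError(
                f"{self.date}: require e_s >= e_a >= 0, got e_s={self.e_s}, e_a={self.e_a}"
            )
        if self.u2 < 0:
            raise ValueError(f"{self.date}: negative wind speed {self.u2}")
        if self.t_mean is None:
            object.__setattr__(self, "t_mean", 0.5 * (self.t_max + self.t_min))


@dataclass(frozen=True)
class AtmosDerived:
    """Psychrometric quantities entering the Penman-Monteith equation.

    delta is the slope of the saturation-vapour-pressure curve and gamma the
    psychrometric constant, both in kPa/degC.
    """

    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.gamma <= 0:
            raise ValueError("delta and gamma must be positive")


@dataclass
class AccumSeries:
    """A cumulative driver series and its season-relative form.

    ``daily`` holds non-negative per-day increments (degC*d for thermal time,
    mm for ETo); ``cumulative`` is the running sum and ``relative`` the
    running sum divided by the season total, so relative values lie on [0, 1]
    with the final value exactly 1.
    """

    driver_kind: DriverKind
    dates: list[datetime.date]
    daily: np.ndarray

    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.daily = np.asarray(self.daily, dtype=float)
        if self.daily.size == 0:
            raise ValueError("empty driver series")
        if len(self.dates) != self.daily.size:
            raise ValueError("dates and daily increments differ in length")
        if np.any(self.daily < 0):
            raise ValueError("daily driver increments must be non-negative")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        self.cumulative = np.cumsum(self.daily)

    @property
    def season_total(self) -> float:
        return float(self.cumulative[-1])

    @property
    def relative(self) -> np.ndarray:
        return relative_accumulation(self)


def saturation_vapor_pressure(t: float | np.ndarray) -> float | np.ndarray:
    """Saturation vapour pressure (kPa) at air temperature ``t`` (degC),
    Tetens form used throughout FAO-56."""
    t = np.asarray(t, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if out.ndim == 0 else out


def pressure_at_elevation(elevation_m: float) -> float:
    """Atmospheric pressure (kPa) from station elevation (m), FAO-56 form."""
    return 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26


def actual_vapor_pressure_from_rh(
    t_max: float, t_min: float, rh_pct: float
) -> tuple[float, float]:
    """Derive (e_s, e_a) in kPa from daily temperature extremes and mean
    relative humidity (percent).

    e_s is the mean of the saturation pressures at t_max and t_min (FAO-56
    daily convention); e_a scales it by mean relative humidity.
    """
    if not 0 <= rh_pct <= 100:
        raise ValueError(f"relative humidity {rh_pct}% outside [0, 100]")
    e_s = 0.5 * (
        saturation_vapor_pressure(t_max) + saturation_vapor_pressure(t_min)
    )
    return e_s, e_s * rh_pct / 100.0


def saturation_vapor_terms(
    t_mean: float, atmospheric_pressure: float = STANDARD_PRESSURE_KPA
) -> AtmosDerived:
    """Slope of the saturation-vapour-pressure curve and psychrometric
    constant at mean temperature ``t_mean`` (degC) and pressure (kPa)."""
    if not -40.0 <= t_mean <= 60.0:
        raise ValueError(f"t_mean {t_mean} degC outside physical range")
    if atmospheric_pressure <= 0:
        raise ValueError("atmospheric pressure must be positive")
    delta = (
        4098.0
        * (0.6108 * math.exp(17.27 * t_mean / (t_mean + 237.3)))
        / (t_mean + 237.3) ** 2
    )
    gamma = 0.000665 * atmospheric_pressure
    return AtmosDerived(delta=delta, gamma=gamma)


def effective_mean_temperature(
    t_max: float, t_min: float, limits: ThermalLimits = ThermalLimits()
) -> float:
    """Daily mean temperature clamped into the crop activity window.

    The raw mean (t_max + t_min)/2 is computed first and then clamped to
    [t_base, t_upper]; the extremes themselves are not clamped.
    """
    if t_max < t_min:
        raise ValueError(f"t_max ({t_max}) < t_min ({t_min})")
    t_avg = 0.5 * (t_max + t_min)
    return min(max(t_avg, limits.t_base), limits.t_upper)


def daily_gdd(
    t_max: float, t_min: float, limits: ThermalLimits = ThermalLimits()
) -> float:
    """One day's growing-degree-day increment (degC*d), never negative."""
    return effective_mean_temperature(t_max, t_min, limits) - limits.t_base


def cumulative_gdd(
    series: list[WeatherDay], limits: ThermalLimits = ThermalLimits()
) -> AccumSeries:
    """Accumulate daily GDD over a date-ordered weather series."""
    if not series:
        raise ValueError("empty weather series")
    daily = np.array([daily_gdd(d.t_max, d.t_min, limits) for d in series])
    return AccumSeries(DriverKind.CGDD, [d.date for d in series], daily)


def daily_eto(day: WeatherDay, atmos: AtmosDerived | None = None) -> float:
    """Daily reference evapotranspiration (mm/d), FAO-56 Penman-Monteith.

    May be negative when net radiation falls below the soil heat flux under
    a saturated atmosphere; accumulation clamps such days to zero, but the
    raw value is returned here.
    """
    if atmos is None:
        atmos = saturation_vapor_terms(day.t_mean)
    num = 0.408 * atmos.delta * (day.r_n - day.g_flux) + atmos.gamma * (
        900.0 / (day.t_mean + 273.0)
    ) * day.u2 * (day.e_s - day.e_a)
    den = atmos.delta + atmos.gamma * (1.0 + 0.34 * day.u2)
    return num / den


def cumulative_eto(
    series: list[WeatherDay],
    atmos: list[AtmosDerived] | None = None,
    atmospheric_pressure: float = STANDARD_PRESSURE_KPA,
) -> AccumSeries:
    """Accumulate daily ETo over a weather series.

    Negative daily values (rare radiation-deficit days) are clamped to zero
    before summing so the cumulative driver is monotone, as the relative
    logistic forms require. Per-day psychrometric terms are computed from
    each day's mean temperature unless supplied.
    """
    if not series:
        raise ValueError("empty weather series")
    if atmos is None:
        atmos = [
            saturation_vapor_terms(d.t_mean, atmospheric_pressure) for d in series
        ]
    daily = np.array(
        [max(daily_eto(d, a), 0.0) for d, a in zip(series, atmos, strict=True)]
    )
    return AccumSeries(DriverKind.CETO, [d.date for d in series], daily)


def relative_accumulation(accum: AccumSeries) -> np.ndarray:
    """Cumulative driver divided by its season total, on [0, 1]."""
    total = accum.cumulative[-1]
    if total <= 0:
        raise ValueError("season total is zero; relative driver undefined")
    return accum.cumulative / total
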