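"""Synthetic seasonal weather and noisy growth observations.

The generator emulates an April-October cotton season's daily forcing for
contrasting Chinese cotton climates: a dry continental (Xinjiang-like)
profile with large annual temperature range, abundant radiation, low
humidity, and a warm-temperate monsoon (North China-like) profile that is
milder, moister and cloudier in summer. Temperatures follow a sinusoidal
annual cycle peaking in mid-July plus lag-1 autocorrelated day-to-day noise
(synoptic persistence); net radiation follows its own seasonal sinusoid
floored at zero; vapour pressures are derived from humidity and temperature;
wind is log-normal around the profile mean. Everything is reproducible from
(profile, year, seed).

Growth observations are the logistic model evaluated at a subset of the
season's relative driver values plus additive Gaussian noise truncated into
(0, 1), mirroring the scatter of multi-study field data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace

import numpy as np

from .growth import LogisticLinear, LogisticQuadratic
from .meteo import (
    AccumSeries,
    DriverKind,
    ThermalLimits,
    WeatherDay,
    actual_vapor_pressure_from_rh,
    cumulative_eto,
    cumulative_gdd,
)

__all__ = [
    "ClimateProfile",
    "GrowthSimSpec",
    "RegionSeason",
    "ARID_CONTINENTAL",
    "WARM_TEMPERATE_MONSOON",
    "generate_weather",
    "generate_growth_observations",
    "generate_region_set",
]

_PEAK_DOY = 197  # annual temperature cycle peaks mid-July


@dataclass(frozen=True)
class ClimateProfile:
    """Statistical description of one region's growing-season climate."""

    label: str
    mean_annual_temp_c: float
    seasonal_amplitude_c: float
    diurnal_range_c: float
    mean_net_radiation: float  # MJ/m2/d at the summer peak's annual mean
    net_radiation_amplitude: float
    mean_rh_pct: float
    mean_wind_ms: float
    temp_noise_sd: float = 1.5
    radiation_noise_sd: float = 1.2
    rh_noise_sd: float = 6.0
    wind_log_sd: float = 0.30
    temp_autocorr: float = 0.6
    season_start: tuple[int, int] = (4, 10)  # (month, day)
    season_end: tuple[int, int] = (10, 20)

    def __post_init__(self) -> None:
        if not 0 < self.mean_rh_pct < 100:
            raise ValueError("mean relative humidity must lie in (0, 100)")
        if self.seasonal_amplitude_c < 0 or self.diurnal_range_c < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.season_start >= self.season_end:
            raise ValueError("season start must precede season end")


#: Dry continental profile: hot summers, large annual range, strong
#: radiation, low humidity. Season thermal time lands in the 1400-2000
#: degC*d range typical of the region.
ARID_CONTINENTAL = ClimateProfile(
    label="arid-continental",
    mean_annual_temp_c=10.0,
    seasonal_amplitude_c=15.0,
    diurnal_range_c=13.0,
    mean_net_radiation=10.0,
    net_radiation_amplitude=6.0,
    mean_rh_pct=45.0,
    mean_wind_ms=2.2,
)

#: Warm-temperate monsoon profile: milder annual cycle, humid cloudy
#: summers, weaker winds.
WARM_TEMPERATE_MONSOON = ClimateProfile(
    label="warm-temperate-monsoon",
    mean_annual_temp_c=13.0,
    seasonal_amplitude_c=13.0,
    diurnal_range_c=9.0,
    mean_net_radiation=9.0,
    net_radiation_amplitude=5.0,
    mean_rh_pct=65.0,
    mean_wind_ms=1.8,
)


@dataclass(frozen=True)
class GrowthSimSpec:
    """Recipe for simulated relative growth observations."""

    true_params: LogisticLinear | LogisticQuadratic
    count: int = 50
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.count < 4:
            raise ValueError("need at least 4 observations")


@dataclass(frozen=True)
class RegionSeason:
    """One simulated region-season: weather plus both cumulative drivers."""

    profile: ClimateProfile
    weather: list[WeatherDay]
    cgdd: AccumSeries
    ceto: AccumSeries


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + rng.normal(0.0, innov_sd)
    return out


def generate_weather(
    profile: ClimateProfile, year: int = 2020, seed: int = 0
) -> list[WeatherDay]:
    """Generate one season of daily weather for a climate profile.

    Deterministic for fixed (profile, year, seed).
    """
    rng = np.random.default_rng(seed)
    start = datetime.date(year, *profile.season_start)
    end = datetime.date(year, *profile.season_end)
    n = (end - start).days + 1
    dates = [start + datetime.timedelta(days=i) for i in range(n)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    phase = 2.0 * np.pi * (doy - _PEAK_DOY) / 365.0
    t_mean = (
        profile.mean_annual_temp_c
        + profile.seasonal_amplitude_c * np.cos(phase)
        + _ar1_noise(rng, n, profile.temp_noise_sd, profile.temp_autocorr)
    )
    half_range = 0.5 * profile.diurnal_range_c * (
        1.0 + rng.normal(0.0, 0.08, n).clip(-0.5, 0.5)
    )
    t_max = t_mean + half_range
    t_min = t_mean - half_range

    r_n = (
        profile.mean_net_radiation
        + profile.net_radiation_amplitude * np.cos(phase)
        + rng.normal(0.0, profile.radiation_noise_sd, n)
    ).clip(min=0.0)

    rh = (profile.mean_rh_pct + rng.normal(0.0, profile.rh_noise_sd, n)).clip(5.0, 98.0)
    u2 = np.exp(
        np.log(profile.mean_wind_ms) + rng.normal(0.0, profile.wind_log_sd, n)
    )

    days = []
    for i, d in enumerate(dates):
        e_s, e_a = actual_vapor_pressure_from_rh(t_max[i], t_min[i], rh[i])
        days.append(
            WeatherDay(
                date=d,
                t_max=float(t_max[i]),
                t_min=float(t_min[i]),
                e_s=float(e_s),
                e_a=float(e_a),
                u2=float(u2[i]),
                r_n=float(r_n[i]),
            )
        )
    return days


def generate_growth_observations(
    spec: GrowthSimSpec, driver: AccumSeries
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate relative growth observations along a season's driver.

    Observation abscissae are ``spec.count`` evenly spaced quantiles of the
    season's relative driver values; ordinates are the true model plus
    Gaussian noise, clipped into the open unit interval. Requires the driver
    to span at least 0.8 of [0, 1] so the sigmoid is identifiable.
    """
    rel = driver.relative
    if rel.max() - rel.min() < 0.8:
        raise ValueError("relative driver spans less than 0.8 of [0, 1]")
    rng = np.random.default_rng(spec.seed)
    idx = np.linspace(0, rel.size - 1, spec.count).round().astype(int)
    x = rel[idx]
    y_true = spec.true_params.predict(x)
    y = y_true + rng.normal(0.0, spec.noise_sd, x.size)
    eps = 1e-6
    return x, np.clip(y, eps, 1.0 - eps)


def generate_region_set(
    profiles: list[ClimateProfile],
    year: int = 2020,
    seed: int = 0,
    limits: ThermalLimits = ThermalLimits(),
) -> dict[str, RegionSeason]:
    """Simulate a season of weather and both cumulative drivers per region.

    Each region draws from an independent substream of ``seed``. The
    emergent relation between the two relative drivers is near-linear,
    which the linkage module exploits.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a region set")
    out: dict[str, RegionSeason] = {}
    for k, profile in enumerate(profiles):
        weather = generate_weather(profile, year=year, seed=seed + 1000 * k)
        out[profile.label] = RegionSeason(
            profile=profile,
            weather=weather,
            cgdd=cumulative_gdd(weather, limits),
            ceto=cumulative_eto(weather),
        )
    return out
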