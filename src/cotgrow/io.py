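"""Delimited-text readers and writers for weather, driver and observation
tables.

Weather files are comma-separated with a header row and unit-bearing column
names: ``date`` (ISO-8601), ``tmax_c``, ``tmin_c``, either ``es_kpa`` and
``ea_kpa`` or ``rh_pct``, plus ``u2_ms`` and ``rn_mj_m2_d``; ``g_mj_m2_d``
is optional (default 0). Leading ``# key: value`` comment lines carry
metadata such as ``elevation_m``. Row-level violations are reported with
their line number.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .meteo import (
    AccumSeries,
    WeatherDay,
    actual_vapor_pressure_from_rh,
)

__all__ = [
    "WeatherTableError",
    "read_weather_table",
    "write_weather_table",
    "write_driver_table",
    "read_driver_table",
    "read_growth_observations",
    "write_growth_observations",
]

_REQUIRED = ("date", "tmax_c", "tmin_c", "u2_ms", "rn_mj_m2_d")


class WeatherTableError(ValueError):
    """Malformed weather table (missing columns, bad values, bad dates)."""


def _read_metadata(path: Path) -> dict[str, float]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    pass
    return meta


def read_weather_table(path) -> tuple[list[WeatherDay], dict[str, float]]:
    """Read a weather CSV into validated :class:`WeatherDay` records.

    Returns ``(days, metadata)``; metadata comes from leading ``#`` comment
    lines (e.g. ``elevation_m``). Vapour pressures are taken directly from
    ``es_kpa``/``ea_kpa`` when present, otherwise derived from ``rh_pct``.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise WeatherTableError(f"{path}: missing mandatory columns {missing}")
    has_vp = {"es_kpa", "ea_kpa"} <= set(df.columns)
    if not has_vp and "rh_pct" not in df.columns:
        raise WeatherTableError(
            f"{path}: need either (es_kpa, ea_kpa) or rh_pct columns"
        )

    # header occupies one line; comment/blank lines precede it
    first_data_line = _count_preamble_lines(path) + 2
    days: list[WeatherDay] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = first_data_line + i
        try:
            date = datetime.date.fromisoformat(str(row.date))
        except ValueError as exc:
            raise WeatherTableError(f"{path}, line {line}: bad date {row.date!r}") from exc
        if has_vp:
            e_s, e_a = float(row.es_kpa), float(row.ea_kpa)
        else:
            e_s, e_a = actual_vapor_pressure_from_rh(
                float(row.tmax_c), float(row.tmin_c), float(row.rh_pct)
            )
        g = float(getattr(row, "g_mj_m2_d", 0.0) or 0.0)
        try:
            days.append(
                WeatherDay(
                    date=date,
                    t_max=float(row.tmax_c),
                    t_min=float(row.tmin_c),
                    e_s=e_s,
                    e_a=e_a,
                    u2=float(row.u2_ms),
                    r_n=float(row.rn_mj_m2_d),
                    g_flux=g,
                )
            )
        except ValueError as exc:
            raise WeatherTableError(f"{path}, line {line}: {exc}") from exc
    if not days:
        raise WeatherTableError(f"{path}: no data rows")
    return days, meta


def _count_preamble_lines(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                n += 1
            else:
                break
    return n


def write_weather_table(path, days: list[WeatherDay], metadata: dict | None = None) -> None:
    """Write weather records in the dialect :func:`read_weather_table` reads."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "date": [d.date.isoformat() for d in days],
            "tmax_c": [d.t_max for d in days],
            "tmin_c": [d.t_min for d in days],
            "es_kpa": [d.e_s for d in days],
            "ea_kpa": [d.e_a for d in days],
            "u2_ms": [d.u2 for d in days],
            "rn_mj_m2_d": [d.r_n for d in days],
            "g_mj_m2_d": [d.g_flux for d in days],
        }
    )
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False)


def write_driver_table(path, cgdd: AccumSeries, ceto: AccumSeries) -> None:
    """Write the paired driver table: daily and cumulative thermal time and
    reference evapotranspiration with their relative forms."""
    if cgdd.dates != ceto.dates:
        raise ValueError("driver series must share dates")
    pd.DataFrame(
        {
            "date": [d.isoformat() for d in cgdd.dates],
            "daily_gdd": cgdd.daily,
            "cgdd": cgdd.cumulative,
            "daily_eto": ceto.daily,
            "ceto": ceto.cumulative,
            "r_cgdd": cgdd.relative,
            "r_ceto": ceto.relative,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_driver_table(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def write_growth_observations(
    path, x: np.ndarray, y: np.ndarray, index_kind: str, driver_kind: str, region: str = ""
) -> None:
    """Write relative growth observations (one row per observation)."""
    pd.DataFrame(
        {
            "region": region,
            "driver_kind": driver_kind,
            "x_relative": np.asarray(x, dtype=float),
            "index_kind": index_kind,
            "y_relative": np.asarray(y, dtype=float),
        }
    ).to_csv(path, index=False, float_format="%.8f")


def read_growth_observations(path) -> pd.DataFrame:
    """Read a relative growth observation table.

    Accepts either precomputed ``x_relative``/``y_relative`` columns or raw
    columns: ``driver_cumulative`` with ``season_total`` (for x) and
    ``value`` with ``observed_max`` and ``factor`` (for y).
    """
    df = pd.read_csv(path)
    if "x_relative" not in df.columns:
        if {"driver_cumulative", "season_total"} <= set(df.columns):
            df["x_relative"] = df["driver_cumulative"] / df["season_total"]
        else:
            raise ValueError(
                f"{path}: need x_relative or (driver_cumulative, season_total)"
            )
    if "y_relative" not in df.columns:
        if {"value", "observed_max", "factor"} <= set(df.columns):
            df["y_relative"] = df["value"] / (df["observed_max"] * df["factor"])
        else:
            raise ValueError(
                f"{path}: need y_relative or (value, observed_max, factor)"
            )
    return df
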