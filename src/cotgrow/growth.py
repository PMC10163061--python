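"""Relative logistic growth models for cotton height, leaf area index and
dry matter.

Each growth index is normalised by its theoretical seasonal maximum and
modelled as a logistic function of a relative cumulative driver x (thermal
time or reference evapotranspiration, both on [0, 1]):

    R = 1 / (1 + exp(a + b*x))            height, dry matter (monotone)
    R = 1 / (1 + exp(a + b*x + c*x^2))    leaf area index (rise then fall)

The exponent is kept in the published sign convention, so increasing curves
carry a negative slope b and the LAI curve has positive curvature c with an
interior maximum at x = -b/(2c). Published coefficient sets, both pooled and
per region, are available from :func:`preset_registry`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .meteo import DriverKind

__all__ = [
    "IndexKind",
    "ExtrapolationWarning",
    "LogisticLinear",
    "LogisticQuadratic",
    "predict_linear",
    "predict_quadratic",
    "growth_rate",
    "quadratic_peak",
    "theoretical_max",
    "denormalize",
    "preset_registry",
    "all_region_preset",
    "regional_table",
]


class IndexKind(str, enum.Enum):
    """Growth index: plant height (cm), leaf area index (dimensionless leaf
    area per ground area) or above-ground dry matter (g/plant)."""

    H = "H"
    LAI = "LAI"
    D = "D"


class ExtrapolationWarning(UserWarning):
    """Raised when a model is evaluated outside the relative-driver domain [0, 1]."""


def _check_domain(x: np.ndarray) -> None:
    if np.any((x < 0) | (x > 1)):
        warnings.warn(
            "relative driver outside [0, 1]; extrapolating the logistic form",
            ExtrapolationWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class LogisticLinear:
    """Logistic model with a linear exponent a + b*x (height or dry matter)."""

    intercept: float
    slope: float
    driver_kind: DriverKind = DriverKind.CGDD
    index_kind: IndexKind = IndexKind.H

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def predict(self, x):
        return predict_linear(self, x)

    def rate(self, x):
        return growth_rate(self, x)


@dataclass(frozen=True)
class LogisticQuadratic:
    """Logistic model with a quadratic exponent a + b*x + c*x^2 (LAI).

    Positive curvature gives the rise-then-fall seasonal LAI shape with an
    interior maximum at x = -b/(2c).
    """

    intercept: float
    slope: float
    curvature: float
    driver_kind: DriverKind = DriverKind.CGDD
    index_kind: IndexKind = IndexKind.LAI

    def predict(self, x):
        return predict_quadratic(self, x)

    def rate(self, x):
        return growth_rate(self, x)

    def peak(self) -> float:
        return quadratic_peak(self)


def _as_float_or_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def predict_linear(params: LogisticLinear, x):
    """Relative growth index 1/(1 + exp(a + b*x)) at relative driver x."""
    arr, scalar = _as_float_or_array(x)
    _check_domain(arr)
    out = 1.0 / (1.0 + np.exp(params.intercept + params.slope * arr))
    return float(out) if scalar else out


def predict_quadratic(params: LogisticQuadratic, x):
    """Relative growth index 1/(1 + exp(a + b*x + c*x^2))."""
    arr, scalar = _as_float_or_array(x)
    _check_domain(arr)
    expo = params.intercept + params.slope * arr + params.curvature * arr**2
    out = 1.0 / (1.0 + np.exp(expo))
    return float(out) if scalar else out


def growth_rate(params: LogisticLinear | LogisticQuadratic, x):
    """Derivative of the relative index with respect to the relative driver.

    Uses the logistic identity dR/dx = -(exponent)' * R * (1 - R).
    """
    arr, scalar = _as_float_or_array(x)
    if isinstance(params, LogisticQuadratic):
        r = predict_quadratic(params, arr)
        grad = params.slope + 2.0 * params.curvature * arr
    else:
        r = predict_linear(params, arr)
        grad = np.full_like(arr, params.slope) if arr.ndim else params.slope
    out = -np.asarray(grad) * r * (1.0 - r)
    return float(out) if scalar else out


def quadratic_peak(params: LogisticQuadratic) -> float:
    """Relative driver value maximising the quadratic-exponent logistic,
    -b/(2c). Requires positive curvature (an interior maximum)."""
    if params.curvature <= 0:
        raise ValueError(
            "no interior maximum: curvature must be positive, got "
            f"{params.curvature}"
        )
    return -params.slope / (2.0 * params.curvature)


def theoretical_max(
    observed_max: float, factor: float, *, allow_out_of_range: bool = False
) -> float:
    """Inflate a season's observed index maximum to its theoretical maximum.

    Field observations rarely catch the true seasonal peak, so the observed
    maximum is multiplied by a small factor, conventionally within
    [1.01, 1.05]. Factors outside that range are rejected unless explicitly
    allowed.
    """
    if observed_max <= 0:
        raise ValueError("observed maximum must be positive")
    if not allow_out_of_range and not 1.01 <= factor <= 1.05:
        raise ValueError(
            f"incremental factor {factor} outside the conventional [1.01, 1.05]"
            " range; pass allow_out_of_range=True to override"
        )
    return observed_max * factor


def denormalize(relative_value, theoretical_maximum):
    """Convert a relative index back to absolute units (cm, LAI or g/plant)."""
    if np.any(np.asarray(theoretical_maximum) <= 0):
        raise ValueError("theoretical maximum must be positive")
    return relative_value * theoretical_maximum


# ---------------------------------------------------------------------------
# Preset registry

_REGISTRY_CACHE: dict | None = None


def _load_registry() -> dict:
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        text = (
            resources.files("cotgrow").joinpath("data/presets.yaml").read_text()
        )
        _REGISTRY_CACHE = yaml.safe_load(text)
    return _REGISTRY_CACHE


def _build(index: IndexKind, driver: DriverKind, coeffs: dict):
    if "curvature" in coeffs:
        return LogisticQuadratic(
            coeffs["intercept"],
            coeffs["slope"],
            coeffs["curvature"],
            driver_kind=driver,
            index_kind=index,
        )
    return LogisticLinear(
        coeffs["intercept"],
        coeffs["slope"],
        driver_kind=driver,
        index_kind=index,
    )


def preset_registry() -> dict:
    """Raw registry of published coefficients (nested dict, as stored)."""
    return _load_registry()


def all_region_preset(
    index: IndexKind | str, driver: DriverKind | str
) -> LogisticLinear | LogisticQuadratic:
    """Pooled multi-region growth model for one index under one driver."""
    index = IndexKind(index)
    driver = DriverKind(driver)
    coeffs = _load_registry()["all_region"][index.value][driver.value]
    return _build(index, driver, coeffs)


def regional_table(index: IndexKind | str) -> dict[str, dict]:
    """Per-region coefficient table for one growth index.

    For each region, ``cgdd`` is the thermal-time fit, ``ceto_fit`` the
    directly fitted evapotranspiration model, ``ceto_cal`` its algebraic
    reconstruction through the driver link, and ``re`` the published
    relative deviation between the two.
    """
    index = IndexKind(index)
    return _load_registry()["regional"][index.value]
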