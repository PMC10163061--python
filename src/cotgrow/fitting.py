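"""Nonlinear least-squares estimation of the logistic growth models and the
goodness-of-fit metrics used to evaluate them.

Fitting minimises the untransformed residual sum of squares with a
Levenberg-Marquardt scheme (scipy's ``curve_fit``); starting values come
from ordinary least squares on the logit transform ln(1/y - 1), which is
linear (or quadratic) in the relative driver and already exact for
noise-free data. Reported diagnostics are the squared Pearson correlation
R^2, the root-mean-square error, and a sum-of-squares relative error in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .growth import IndexKind, LogisticLinear, LogisticQuadratic
from .meteo import DriverKind

__all__ = [
    "GrowthObservation",
    "FitReport",
    "fit_logistic_linear",
    "fit_logistic_quadratic",
    "r_squared",
    "rmse",
    "relative_error_ss",
    "scalar_relative_deviation",
]

_LOGIT_EPS = 1e-6
_MAX_ITER = 200


@dataclass(frozen=True)
class GrowthObservation:
    """One normalised growth observation: relative driver x, relative index y."""

    x: float
    y: float
    index_kind: IndexKind = IndexKind.H
    region: str = ""


@dataclass(frozen=True)
class FitReport:
    """Estimated logistic parameters with fit diagnostics."""

    params: LogisticLinear | LogisticQuadratic
    n: int
    r_squared: float
    rmse: float
    re_pct: float

    def summary(self) -> str:
        p = self.params
        lines = [
            f"model: logistic/{'quadratic' if isinstance(p, LogisticQuadratic) else 'linear'}",
            f"index: {p.index_kind.value}  driver: {p.driver_kind.value}",
            f"intercept: {p.intercept:.6g}",
            f"slope: {p.slope:.6g}",
        ]
        if isinstance(p, LogisticQuadratic):
            lines.append(f"curvature: {p.curvature:.6g}")
        lines += [
            f"n: {self.n}",
            f"r_squared: {self.r_squared:.4f}",
            f"rmse: {self.rmse:.4g}",
            f"re_pct: {self.re_pct:.4g}",
        ]
        return "\n".join(lines)


def _coerce_xy(observations) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(observations, tuple) and len(observations) == 2:
        x, y = observations
    else:
        x = [o.x for o in observations]
        y = [o.y for o in observations]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("observations must form equal-length 1-d arrays")
    order = np.argsort(x, kind="stable")
    return x[order], y[order]


def _logit(y: np.ndarray) -> np.ndarray:
    yc = np.clip(y, _LOGIT_EPS, 1.0 - _LOGIT_EPS)
    return np.log(1.0 / yc - 1.0)


def _report(params, x, y) -> FitReport:
    pred = params.predict(x)
    return FitReport(
        params=params,
        n=x.size,
        r_squared=r_squared(pred, y),
        rmse=rmse(y, pred),
        re_pct=relative_error_ss(y, pred),
    )


def fit_logistic_linear(
    observations,
    driver_kind: DriverKind = DriverKind.CGDD,
    index_kind: IndexKind = IndexKind.H,
) -> FitReport:
    """Fit R = 1/(1 + exp(a + b*x)) to relative growth observations.

    ``observations`` is either a sequence of :class:`GrowthObservation` or a
    ``(x, y)`` pair of arrays. Requires at least three distinct driver
    values; y values at the 0/1 boundary only affect the logit initialiser,
    which clips them inward by 1e-6.
    """
    x, y = _coerce_xy(observations)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 observations with distinct x")

    b0, a0 = np.polyfit(x, _logit(y), 1)

    def model(xv, a, b):
        return 1.0 / (1.0 + np.exp(a + b * xv))

    popt, _ = curve_fit(
        model, x, y, p0=[a0, b0], method="lm", maxfev=_MAX_ITER * 4, xtol=1e-10
    )
    params = LogisticLinear(
        float(popt[0]), float(popt[1]), driver_kind=driver_kind, index_kind=index_kind
    )
    return _report(params, x, y)


def fit_logistic_quadratic(
    observations,
    driver_kind: DriverKind = DriverKind.CGDD,
    index_kind: IndexKind = IndexKind.LAI,
) -> FitReport:
    """Fit R = 1/(1 + exp(a + b*x + c*x^2)) to relative growth observations."""
    x, y = _coerce_xy(observations)
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 observations with distinct x")

    c0, b0, a0 = np.polyfit(x, _logit(y), 2)

    def model(xv, a, b, c):
        return 1.0 / (1.0 + np.exp(a + b * xv + c * xv**2))

    popt, _ = curve_fit(
        model,
        x,
        y,
        p0=[a0, b0, c0],
        method="lm",
        maxfev=_MAX_ITER * 4,
        xtol=1e-10,
    )
    params = LogisticQuadratic(
        float(popt[0]),
        float(popt[1]),
        float(popt[2]),
        driver_kind=driver_kind,
        index_kind=index_kind,
    )
    return _report(params, x, y)


def r_squared(x, y) -> float:
    """Squared Pearson correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length vectors with >= 2 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = np.sum(dx**2)
    syy = np.sum(dy**2)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.sum(dx * dy) ** 2 / (sxx * syy))


def rmse(measured, calculated) -> float:
    """Root-mean-square error between measured and calculated values."""
    m = np.asarray(measured, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if m.size == 0 or m.size != c.size:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.sqrt(np.mean((m - c) ** 2)))


def relative_error_ss(measured, calculated) -> float:
    """Sum-of-squares relative error, in percent.

    Ratio of the residual sum of squares to the sum of squared measured
    values, scaled by 100.
    """
    m = np.asarray(measured, dtype=float)
    c = np.asarray(calculated, dtype=float)
    if m.size == 0 or m.size != c.size:
        raise ValueError("need equal-length non-empty vectors")
    denom = np.sum(m**2)
    if denom == 0:
        raise ValueError("all-zero measured vector")
    return float(100.0 * np.sum((m - c) ** 2) / denom)


def scalar_relative_deviation(fitted: float, calculated: float) -> float:
    """Relative deviation |calculated - fitted| / |fitted| between a directly
    fitted coefficient and its algebraic reconstruction."""
    if fitted == 0:
        raise ValueError("fitted value must be nonzero")
    return abs(calculated - fitted) / abs(fitted)
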