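"""Linear linkage between the two relative drivers and the closed-form
conversion of logistic parameters between driver bases.

Within a region the relative cumulative evapotranspiration is very nearly an
affine function of relative thermal time, X = m*x + n with m > 0. Under that
link a logistic exponent in x maps exactly onto one in X:

    linear    d = a - b*n/m,                e = b/m
    quadratic f = c/m^2,  e = (b*m - 2*c*n)/m^2,
              d = a - (b*m*n - c*n^2)/m^2

so evapotranspiration-driven model coefficients can be obtained from a
thermal-time fit without refitting, and vice versa through the inverted link
(1/m, -n/m). Since published tables list parameter pairs but not the links
themselves, :func:`recover_link_from_params` inverts the algebra to recover
(m, n) from an (a, b)/(d, e) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .growth import LogisticLinear, LogisticQuadratic, regional_table
from .fitting import r_squared

__all__ = [
    "LinkLinear",
    "LinkCubic",
    "fit_link_linear",
    "evaluate_cubic_link",
    "convert_linear_params",
    "convert_quadratic_params",
    "recover_link_from_params",
    "recover_link_from_quadratic",
    "invert_link",
    "link_registry",
]


@dataclass(frozen=True)
class LinkLinear:
    """Affine map from relative thermal time to relative evapotranspiration:
    R_CETo = m * R_CGDD + n."""

    m: float
    n: float
    r_squared: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"link slope m must be positive, got {self.m}")

    def __call__(self, x):
        return self.m * np.asarray(x, dtype=float) + self.n


@dataclass(frozen=True)
class LinkCubic:
    """Cubic driver link g*x^3 + h*x^2 + k*x + l (evaluation only; the linear
    link is used for all parameter conversion)."""

    g: float
    h: float
    k: float
    l: float


def fit_link_linear(r_cgdd, r_ceto) -> LinkLinear:
    """Ordinary least-squares fit of R_CETo = m*R_CGDD + n on paired,
    date-matched relative driver series; reports R^2 alongside."""
    x = np.asarray(r_cgdd, dtype=float)
    y = np.asarray(r_ceto, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length paired series with >= 2 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate link fit: constant R_CGDD")
    m, n = np.polyfit(x, y, 1)
    r2 = 1.0 if np.ptp(y) == 0 else r_squared(x, y)
    return LinkLinear(float(m), float(n), r_squared=float(r2), provenance="fitted")


def evaluate_cubic_link(link: LinkCubic, x):
    """Evaluate the cubic driver link at relative thermal time x."""
    arr = np.asarray(x, dtype=float)
    out = ((link.g * arr + link.h) * arr + link.k) * arr + link.l
    return float(out) if out.ndim == 0 else out


def convert_linear_params(a: float, b: float, link: LinkLinear) -> tuple[float, float]:
    """Convert a linear logistic exponent a + b*x into the (d, e) exponent of
    the linked driver, satisfying d + e*(m*x + n) = a + b*x for all x."""
    if link.m == 0:
        raise ValueError("link slope m must be nonzero")
    return a - b * link.n / link.m, b / link.m


def convert_quadratic_params(
    a: float, b: float, c: float, link: LinkLinear
) -> tuple[float, float, float]:
    """Convert a quadratic logistic exponent a + b*x + c*x^2 into (d, e, f)
    under the linked driver X = m*x + n."""
    if link.m == 0:
        raise ValueError("link slope m must be nonzero")
    m, n = link.m, link.n
    f = c / m**2
    e = (b * m - 2.0 * c * n) / m**2
    d = a - (b * m * n - c * n**2) / m**2
    return d, e, f


def recover_link_from_params(a: float, b: float, d: float, e: float) -> LinkLinear:
    """Back-solve the linear link from a linear parameter pair: m = b/e and
    n = (a - d)*m/b, so that converting (a, b) through the result returns
    (d, e) exactly."""
    if b == 0 or e == 0:
        raise ValueError("slopes must be nonzero to recover the link")
    m = b / e
    n = (a - d) * m / b
    return LinkLinear(m, n, provenance="back-solved")


def recover_link_from_quadratic(
    a: float, b: float, c: float, d: float, e: float, f: float
) -> LinkLinear:
    """Back-solve the link from a quadratic parameter pair via m = sqrt(c/f)
    and the slope-term identity n = m*(b - e*m)/(2c)."""
    if c == 0 or f == 0 or c / f <= 0:
        raise ValueError("curvatures must be nonzero with matching sign")
    m = sqrt(c / f)
    n = m * (b - e * m) / (2.0 * c)
    return LinkLinear(m, n, provenance="back-solved")


def invert_link(link: LinkLinear) -> LinkLinear:
    """Inverse map x = (X - n)/m, for converting in the opposite direction."""
    return LinkLinear(
        1.0 / link.m, -link.n / link.m, provenance=f"inverse of {link.provenance}"
    )


def link_registry() -> dict[str, LinkLinear]:
    """Per-region links back-solved from the published parameter table.

    One shared link per region, recovered from the height row where the
    region has one, else the dry-matter row, else the quadratic LAI row.
    """
    registry: dict[str, LinkLinear] = {}
    for index, recover in (("H", "lin"), ("D", "lin"), ("LAI", "quad")):
        for region, rows in regional_table(index).items():
            if region in registry:
                continue
            cg, cal = rows["cgdd"], rows["ceto_cal"]
            if recover == "lin":
                link = recover_link_from_params(
                    cg["intercept"], cg["slope"], cal["intercept"], cal["slope"]
                )
            else:
                link = recover_link_from_quadratic(
                    cg["intercept"],
                    cg["slope"],
                    cg["curvature"],
                    cal["intercept"],
                    cal["slope"],
                    cal["curvature"],
                )
            registry[region] = LinkLinear(
                link.m, link.n, provenance=f"back-solved from {index} row"
            )
    return registry
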