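"""Seed-cotton yield, maximum leaf area index and irrigation response models.

Two concave quadratic responses, fitted to binned multi-study field data,
close the loop from irrigation to yield:

    Y       = -36.9 * LAI_max^2 + 446 * LAI_max + 5824        (kg/ha)
    LAI_max = -1.319e-4 * W^2 + 0.1513 * W - 36.95            (per mm of W)

Their vertices give the yield-maximising LAI_max and the irrigation amount
at which LAI_max saturates; inverting the second on its ascending branch
gives the water-economical irrigation that reaches the yield-optimal
LAI_max. Irrigation water use efficiency IWUE = Y/W is provided in two
modes: AS_PRINTED evaluates the published quartic-over-W expression with its
coefficients verbatim, while COMPOSED substitutes one quadratic into the
other exactly. The two disagree materially at the optimum because the
published quartic rounds its cubic coefficient (0.0015 vs the exact
1.47279e-3); both are exposed and labelled rather than reconciled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseRole",
    "IwueMode",
    "Branch",
    "QuadraticResponse",
    "IwueResult",
    "BinnedAverages",
    "YIELD_VS_LAIMAX",
    "LAIMAX_VS_W",
    "IWUE_PRINTED_NUMERATOR",
    "bin_and_average",
    "yield_from_laimax",
    "laimax_from_irrigation",
    "vertex",
    "irrigation_for_laimax",
    "iwue",
    "compose_yield_vs_irrigation",
    "fit_quadratic_response",
    "optimal_irrigation_report",
]


class ResponseRole(str, enum.Enum):
    YIELD_VS_LAIMAX = "YIELD_VS_LAIMAX"
    LAIMAX_VS_W = "LAIMAX_VS_W"


class IwueMode(str, enum.Enum):
    """AS_PRINTED: published quartic-over-W coefficients verbatim.
    COMPOSED: exact composition of the two quadratic responses."""

    AS_PRINTED = "AS_PRINTED"
    COMPOSED = "COMPOSED"


class Branch(str, enum.Enum):
    """Root branch of a concave quadratic: ASCENDING is the smaller root
    (water-economical side), DESCENDING the larger."""

    ASCENDING = "ASCENDING"
    DESCENDING = "DESCENDING"


@dataclass(frozen=True)
class QuadraticResponse:
    """Concave quadratic response q2*x^2 + q1*x + q0."""

    q2: float
    q1: float
    q0: float
    role: ResponseRole

    def __call__(self, x):
        arr = np.asarray(x, dtype=float)
        out = (self.q2 * arr + self.q1) * arr + self.q0
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IwueResult:
    """Irrigation water use efficiency at irrigation amount w (mm)."""

    w: float
    iwue: float
    mode: IwueMode


@dataclass(frozen=True)
class BinnedAverages:
    """Per-bin arithmetic means of a binned variable and its response."""

    edges: np.ndarray
    x_means: np.ndarray
    y_means: np.ndarray
    counts: np.ndarray
    n_dropped: int = 0


#: Published yield response to maximum leaf area index (kg/ha).
YIELD_VS_LAIMAX = QuadraticResponse(-36.9, 446.0, 5824.0, ResponseRole.YIELD_VS_LAIMAX)

#: Published maximum-LAI response to seasonal irrigation amount (mm).
LAIMAX_VS_W = QuadraticResponse(-1.319e-4, 0.1513, -36.95, ResponseRole.LAIMAX_VS_W)

#: Published quartic numerator of IWUE(W), coefficients verbatim
#: (descending powers W^4 ... W^0).
IWUE_PRINTED_NUMERATOR = np.array(
    [-6.4197e-7, 0.0015, -1.2632, 480.061, -61035.362]
)


def bin_and_average(xs, ys, edges) -> BinnedAverages:
    """Average paired data within half-open bins [lo, hi) over ``edges``.

    The final bin is closed on the right so the overall maximum is kept;
    values outside the edge range are dropped and counted. Empty bins are
    omitted from the output.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if xs.size != ys.size:
        raise ValueError("xs and ys must have equal length")
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")

    # right=False gives [lo, hi); fold the exact top edge into the last bin
    idx = np.digitize(xs, edges, right=False) - 1
    idx[xs == edges[-1]] = edges.size - 2
    keep = (idx >= 0) & (idx <= edges.size - 2)

    x_means, y_means, counts = [], [], []
    for b in range(edges.size - 1):
        sel = keep & (idx == b)
        if not sel.any():
            continue
        x_means.append(xs[sel].mean())
        y_means.append(ys[sel].mean())
        counts.append(int(sel.sum()))
    if not counts:
        raise ValueError("no data fall inside the bin edges")
    return BinnedAverages(
        edges=edges,
        x_means=np.array(x_means),
        y_means=np.array(y_means),
        counts=np.array(counts),
        n_dropped=int((~keep).sum()),
    )


def yield_from_laimax(
    laimax, resp: QuadraticResponse = YIELD_VS_LAIMAX
):
    """Seed-cotton yield (kg/ha) from maximum leaf area index."""
    if np.any(np.asarray(laimax) < 0):
        raise ValueError("LAI_max must be non-negative")
    return resp(laimax)


def laimax_from_irrigation(w, resp: QuadraticResponse = LAIMAX_VS_W):
    """Maximum leaf area index from seasonal irrigation amount (mm)."""
    if np.any(np.asarray(w) <= 0):
        raise ValueError("irrigation amount must be positive")
    return resp(w)


def vertex(resp: QuadraticResponse) -> tuple[float, float]:
    """Stationary point (x*, y*) of the quadratic: x* = -q1/(2 q2),
    y* = q0 - q1^2/(4 q2)."""
    if resp.q2 == 0:
        raise ValueError("not a quadratic: q2 = 0")
    x_star = -resp.q1 / (2.0 * resp.q2)
    y_star = resp.q0 - resp.q1**2 / (4.0 * resp.q2)
    return x_star, y_star


def irrigation_for_laimax(
    target_laimax: float,
    branch: Branch = Branch.ASCENDING,
    resp: QuadraticResponse = LAIMAX_VS_W,
) -> float:
    """Irrigation amount (mm) at which the LAI_max response reaches a target.

    Solves q2*W^2 + q1*W + (q0 - target) = 0. The ASCENDING branch (smaller
    root) is the default: it is the water-economical solution below the
    response vertex.
    """
    branch = Branch(branch)
    _, peak_value = vertex(resp)
    disc = resp.q1**2 - 4.0 * resp.q2 * (resp.q0 - target_laimax)
    if -1e-12 * max(1.0, resp.q1**2) < disc < 0:
        disc = 0.0  # target numerically at the vertex
    if disc < 0:
        raise ValueError(
            f"target LAI_max {target_laimax} exceeds the response maximum "
            f"{peak_value:.3f}; no real irrigation amount reaches it"
        )
    sq = np.sqrt(disc)
    roots = sorted(
        ((-resp.q1 + s * sq) / (2.0 * resp.q2) for s in (-1.0, 1.0))
    )
    root = roots[0] if branch is Branch.ASCENDING else roots[1]
    if root < 0:
        raise ValueError(f"negative irrigation root {root:.3f} rejected")
    return float(root)


def compose_yield_vs_irrigation(
    yield_resp: QuadraticResponse = YIELD_VS_LAIMAX,
    laimax_resp: QuadraticResponse = LAIMAX_VS_W,
) -> np.ndarray:
    """Exact quartic Y(W) obtained by substituting the LAI_max response into
    the yield response; coefficients in descending powers W^4 ... W^0."""
    inner = np.array([laimax_resp.q2, laimax_resp.q1, laimax_resp.q0])
    inner_sq = np.polymul(inner, inner)
    quartic = yield_resp.q2 * inner_sq
    quartic = np.polyadd(quartic, yield_resp.q1 * inner)
    quartic = np.polyadd(quartic, np.array([yield_resp.q0]))
    return quartic


def iwue(w: float, mode: IwueMode = IwueMode.AS_PRINTED) -> IwueResult:
    """Irrigation water use efficiency Y/W (kg/(ha*mm)) at irrigation w (mm).

    AS_PRINTED divides the published quartic numerator, coefficients
    verbatim, by W; COMPOSED evaluates the exact composition
    yield(laimax(W))/W. The published headline value is reproducible only in
    AS_PRINTED mode; COMPOSED is the internally consistent one.
    """
    if w <= 0:
        raise ValueError("irrigation amount must be positive")
    mode = IwueMode(mode)
    if mode is IwueMode.AS_PRINTED:
        value = float(np.polyval(IWUE_PRINTED_NUMERATOR, w)) / w
    else:
        value = float(yield_from_laimax(laimax_from_irrigation(w))) / w
    return IwueResult(w=w, iwue=value, mode=mode)


def fit_quadratic_response(xs, ys, role: ResponseRole) -> QuadraticResponse:
    """Least-squares quadratic through (typically binned) response data."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.unique(xs).size < 3:
        raise ValueError("need >= 3 distinct x values for a quadratic fit")
    q2, q1, q0 = np.polyfit(xs, ys, 2)
    return QuadraticResponse(float(q2), float(q1), float(q0), role)


def optimal_irrigation_report(laimax_decimals: int | None = 3) -> dict:
    """Headline optimum under the published responses.

    Returns the yield-maximising LAI_max and yield, the irrigation amount
    reaching that LAI_max on the ascending branch, the LAI_max response
    vertex irrigation, and IWUE at the required irrigation under both modes.

    ``laimax_decimals`` rounds the yield-optimal LAI_max before the root
    solve (default 3, the precision at which the optimum is conventionally
    quoted and propagated; the published irrigation figure follows from the
    3-decimal value). Pass ``None`` to propagate full precision instead.
    """
    laimax_opt, yield_max = vertex(YIELD_VS_LAIMAX)
    w_vertex, _ = vertex(LAIMAX_VS_W)
    target = laimax_opt if laimax_decimals is None else round(laimax_opt, laimax_decimals)
    w_required = irrigation_for_laimax(target, Branch.ASCENDING)
    return {
        "laimax_optimal": laimax_opt,
        "yield_max_kg_ha": yield_max,
        "w_required_mm": w_required,
        "w_vertex_mm": w_vertex,
        "iwue_as_printed": iwue(w_required, IwueMode.AS_PRINTED).iwue,
        "iwue_composed": iwue(w_required, IwueMode.COMPOSED).iwue,
        "branch": Branch.ASCENDING.value,
    }
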