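"""Duplex (two-residue) metrics and ternary multi-metrics.

A *multi-metric* ``T_XYZ`` scores the relationship among three residue
points; it fills the all-distinct-index entries of the three-tuple tensor.
Its *duplex* companion ``D`` (an ordinary two-point metric) fills the
repeated-index entries in complete mode.  Four multi-metric families are
provided:

geometric
    triangle area (Heron), incircle area, side summation, bond angle;
cluster
    linkage-style rules (nearest/furthest neighbour, average, median,
    Ward-like, Mahalanobis-Ward, adjusted, join);
operator
    data-fusion operators on the three sides (sum/perimeter, product,
    quadratic and cubic power means, range, topological-degree average);
agreement
    covariance/correlation agreement coefficients among the three
    coordinate triples.

Each multi-metric carries a pair of even/odd software IDs (M33-M76) treated
as aliases, and a symmetry flag: ``S`` measures are invariant under all six
permutations of (X, Y, Z); ``A`` measures depend on the (i, j, l) ordering
of the tensor positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class UnknownMetricError(KeyError):
    pass


class UndefinedAngleError(ValueError):
    """Bond angle requested with a zero-length side."""


# --------------------------------------------------------------------------
# duplex metrics
# --------------------------------------------------------------------------

def _euclidean(u: np.ndarray, v: np.ndarray, p=None) -> float:
    return float(np.linalg.norm(u - v))


def _manhattan(u, v, p=None) -> float:
    return float(np.abs(u - v).sum())


def _chebyshev(u, v, p=None) -> float:
    return float(np.abs(u - v).max())


def _minkowski(u, v, p=3.0) -> float:
    if math.isinf(p):
        return _chebyshev(u, v)
    return float((np.abs(u - v) ** p).sum() ** (1.0 / p))


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    mask = den != 0
    out[mask] = num[mask] / den[mask]
    return out


def _canberra(u, v, p=None) -> float:
    return float(_safe_div(np.abs(u - v), np.abs(u) + np.abs(v)).sum())


def _wave_hedges(u, v, p=None) -> float:
    return float(_safe_div(np.abs(u - v),
                           np.maximum(np.abs(u), np.abs(v))).sum())


def _soergel(u, v, p=None) -> float:
    den = np.maximum(np.abs(u), np.abs(v)).sum()
    return float(np.abs(u - v).sum() / den) if den else 0.0


def _lance_williams(u, v, p=None) -> float:
    den = (np.abs(u) + np.abs(v)).sum()
    return float(np.abs(u - v).sum() / den) if den else 0.0


@dataclass(frozen=True)
class MetricSpec:
    ids: tuple[str, str]
    name: str
    fn: Callable[..., float]
    param: float | None = None  # Minkowski order

    def __call__(self, u: np.ndarray, v: np.ndarray) -> float:
        if self.param is not None:
            return self.fn(u, v, self.param)
        return self.fn(u, v)


_DUPLEX_LIST = [
    MetricSpec(("M1", "M2"), "euclidean", _euclidean),
    MetricSpec(("M3", "M4"), "manhattan", _manhattan),
    MetricSpec(("M5", "M6"), "chebyshev", _chebyshev),
    MetricSpec(("M7", "M8"), "minkowski", _minkowski, 3.0),
    MetricSpec(("M9", "M10"), "canberra", _canberra),
    MetricSpec(("M11", "M12"), "wave-edge", _wave_hedges),
    MetricSpec(("M13", "M14"), "soergel", _soergel),
    MetricSpec(("M15", "M16"), "lance-williams", _lance_williams),
]

DUPLEX_METRICS: dict[str, MetricSpec] = {}
for _m in _DUPLEX_LIST:
    DUPLEX_METRICS[_m.name] = _m
    for _id in _m.ids:
        DUPLEX_METRICS[_id] = _m


def get_duplex(metric: str | MetricSpec, param: float | None = None) -> MetricSpec:
    if isinstance(metric, MetricSpec):
        return metric
    try:
        spec = DUPLEX_METRICS[metric]
    except KeyError:
        raise UnknownMetricError(
            f"unknown duplex metric {metric!r}; known: "
            f"{sorted(m.name for m in _DUPLEX_LIST)} / M1-M16") from None
    if param is not None:
        spec = MetricSpec(spec.ids, spec.name, spec.fn, param)
    return spec


def duplex_distance(p1, p2, metric: str | MetricSpec = "euclidean",
                    param: float | None = None) -> float:
    """Two-point (dis)similarity under a registered duplex metric."""
    spec = get_duplex(metric, param)
    return spec(np.asarray(p1, dtype=float), np.asarray(p2, dtype=float))


# --------------------------------------------------------------------------
# triple context
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TripleContext:
    """Everything a ternary measure may consume for one (X, Y, Z) triple."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    d_XY: float
    d_YZ: float
    d_ZX: float
    # sequence-separation topological distances; inf across chain breaks
    p_XY: float = 1.0
    p_YZ: float = 1.0
    p_ZX: float = 1.0
    mass_center: np.ndarray | None = None
    metric: MetricSpec | None = None

    @property
    def sides(self) -> tuple[float, float, float]:
        return (self.d_XY, self.d_YZ, self.d_ZX)

    @property
    def semiperimeter(self) -> float:
        return 0.5 * sum(self.sides)


def make_context(X, Y, Z, metric: str | MetricSpec = "euclidean",
                 positions: Sequence[int] | None = None,
                 chains: Sequence[str] | None = None,
                 mass_center=None) -> TripleContext:
    """Build a :class:`TripleContext` from three points.

    ``positions`` are the 1-based sequence positions of the residues holding
    X, Y, Z; ``chains`` their chain identifiers (chain breaks make the
    topological distance infinite).
    """
    X, Y, Z = (np.asarray(a, dtype=float) for a in (X, Y, Z))
    spec = get_duplex(metric)

    def topo(a: int, b: int) -> float:
        if chains is not None and chains[a] != chains[b]:
            return math.inf
        if positions is None:
            return 1.0
        return float(abs(positions[a] - positions[b]))

    return TripleContext(
        X=X, Y=Y, Z=Z,
        d_XY=spec(X, Y), d_YZ=spec(Y, Z), d_ZX=spec(Z, X),
        p_XY=topo(0, 1), p_YZ=topo(1, 2), p_ZX=topo(2, 0),
        mass_center=None if mass_center is None else np.asarray(mass_center),
        metric=spec,
    )


# --------------------------------------------------------------------------
# ternary measures
# --------------------------------------------------------------------------

def _heron(a: float, b: float, c: float) -> float:
    s = 0.5 * (a + b + c)
    return math.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))


def _mm_area(ctx: TripleContext) -> float:
    return _heron(*ctx.sides)


def _mm_incircle(ctx: TripleContext) -> float:
    per = sum(ctx.sides)
    if per == 0.0:
        return 0.0
    return math.pi * (2.0 * _heron(*ctx.sides) / per) ** 2


def _mm_sum_sides(ctx: TripleContext) -> float:
    return ctx.d_XY + ctx.d_YZ


def _mm_bond_angle(ctx: TripleContext) -> float:
    u = ctx.X - ctx.Y
    v = ctx.Z - ctx.Y
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedAngleError("bond angle undefined: zero-length side")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.acos(min(1.0, max(-1.0, cosang)))


def _mm_min(ctx: TripleContext) -> float:
    return min(ctx.d_ZX, ctx.d_YZ)


def _mm_join(ctx: TripleContext) -> float:
    return sorted(ctx.sides)[1]  # the side strictly between min and max


def _mm_max(ctx: TripleContext) -> float:
    return max(ctx.d_ZX, ctx.d_YZ)


def _mm_ave(ctx: TripleContext) -> float:
    return 0.5 * (ctx.d_ZX + ctx.d_YZ)


def _mm_med(ctx: TripleContext) -> float:
    return 0.5 * (ctx.d_ZX + ctx.d_YZ) - 0.25 * ctx.d_XY


def _centroid_terms(ctx: TripleContext,
                    dist: Callable[[np.ndarray, np.ndarray], float]) -> float:
    c3 = (ctx.X + ctx.Y + ctx.Z) / 3.0
    c2 = (ctx.X + ctx.Y) / 2.0
    return (dist(ctx.X, c3) ** 2 + dist(ctx.Y, c3) ** 2 + dist(ctx.Z, c3) ** 2
            - dist(ctx.X, c2) ** 2 - dist(ctx.Y, c2) ** 2)


def _mm_war(ctx: TripleContext) -> float:
    dist = ctx.metric or get_duplex("euclidean")
    return _centroid_terms(ctx, dist)


def _mm_adj(ctx: TripleContext) -> float:
    return max(ctx.sides) - ctx.d_XY


def _mm_mah(ctx: TripleContext) -> float:
    pts = np.stack([ctx.X, ctx.Y, ctx.Z])
    cov = np.cov(pts, rowvar=False, bias=True)
    # three centered points span at most rank 2, so the 3x3 covariance is
    # singular by construction: regularize the spectrum unconditionally
    # (eigh keeps the 1/eps amplification out of the data directions)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 0.0) + 1e-8

    def maha(u: np.ndarray, v: np.ndarray) -> float:
        proj = evecs.T @ (u - v)
        return math.sqrt(float((proj ** 2 / evals).sum()))

    return _centroid_terms(ctx, maha)


def _mm_add(ctx: TripleContext) -> float:
    total = 0.0
    for d, p in ((ctx.d_XY, ctx.p_XY), (ctx.d_YZ, ctx.p_YZ),
                 (ctx.d_ZX, ctx.p_ZX)):
        if math.isfinite(p) and p > 0:
            total += d / p
    return total / 3.0


def _mm_sum(ctx: TripleContext) -> float:
    return sum(ctx.sides)


def _mm_pro(ctx: TripleContext) -> float:
    return ctx.d_XY * ctx.d_YZ * ctx.d_ZX


def _mm_qua(ctx: TripleContext) -> float:
    return math.sqrt(sum(d * d for d in ctx.sides) / 3.0)


def _mm_geo(ctx: TripleContext) -> float:
    return (sum(d ** 3 for d in ctx.sides) / 3.0) ** (1.0 / 3.0)


def _mm_ran(ctx: TripleContext) -> float:
    return max(ctx.sides) - min(ctx.sides)


def _cov(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.mean((u - u.mean()) * (v - v.mean())))


def _mm_ic(ctx: TripleContext) -> float:
    sxy = _cov(ctx.X, ctx.Y)
    sxz = _cov(ctx.X, ctx.Z)
    syz = _cov(ctx.Y, ctx.Z)
    vx, vy, vz = (_cov(a, a) for a in (ctx.X, ctx.Y, ctx.Z))
    mx, my, mz = (float(a.mean()) for a in (ctx.X, ctx.Y, ctx.Z))
    den = (2.0 * (vx + vy + vz)
           + (mx - my) ** 2 + (mx - mz) ** 2 + (my - mz) ** 2)
    if den == 0.0:
        logger.warning("IC-RULE: zero denominator, returning 0")
        return 0.0
    return 2.0 * (sxy + sxz + syz) / den


def _mm_ac(ctx: TripleContext) -> float:
    num = _cov(ctx.X, ctx.Y) + _cov(ctx.X, ctx.Z) + _cov(ctx.Y, ctx.Z)
    den = _cov(ctx.X, ctx.X) + _cov(ctx.Y, ctx.Y) + _cov(ctx.Z, ctx.Z)
    if den == 0.0:
        logger.warning("AC-RULE: zero variance, returning 0")
        return 0.0
    return num / den


def _mm_pc(ctx: TripleContext) -> float:
    U = np.stack([ctx.X, ctx.Y, ctx.Z])  # rows: atoms, cols: coordinates
    n = U.shape[1]  # dimension (3)
    pairs = [(0, 1), (0, 2), (1, 2)]
    k = len(pairs)
    num = 0.0
    den_sum = 0.0
    for i, j in pairs:
        a = math.sqrt(float((U[i] ** 2).sum() * (U[j] ** 2).sum()))
        if a == 0.0:
            logger.warning("PC-RULE: zero-norm coordinate row, term set to 0")
            continue
        num += (float(U[i] @ U[j]) - n * U[i].mean() * U[j].mean()) / a
        den_sum += U[i].mean() * U[j].mean() / a
    den = 0.5 * k * (k - 1) - n * den_sum
    if den == 0.0:
        logger.warning("PC-RULE: zero denominator, returning 0")
        return 0.0
    return num / den


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su = _cov(u, u)
    sv = _cov(v, v)
    if su == 0.0 or sv == 0.0:
        logger.warning("LC-RULE: zero variance, correlation term set to 0")
        return 0.0
    return _cov(u, v) / math.sqrt(su * sv)


def _mm_lc(ctx: TripleContext) -> float:
    return (_pearson(ctx.X, ctx.Y) + _pearson(ctx.Y, ctx.Z)
            + _pearson(ctx.Z, ctx.X)) / 3.0


# --- vectorised side-only forms (arrays a=d_XY, b=d_YZ, c=d_ZX) ------------

def _v_heron(a, b, c):
    s = 0.5 * (a + b + c)
    return np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))


def _v_incircle(a, b, c):
    per = a + b + c
    area = _v_heron(a, b, c)
    out = np.zeros_like(per)
    mask = per > 0
    out[mask] = math.pi * (2.0 * area[mask] / per[mask]) ** 2
    return out


_SIDE_FORMULAS: dict[str, Callable] = {
    "AREA": _v_heron,
    "INCIRCLE": _v_incircle,
    "SUMSIDES": lambda a, b, c: a + b,
    "MIN": lambda a, b, c: np.minimum(c, b),
    "JOIN": lambda a, b, c: np.sort(np.stack([a, b, c]), axis=0)[1],
    "MAX": lambda a, b, c: np.maximum(c, b),
    "AVE": lambda a, b, c: 0.5 * (c + b),
    "MED": lambda a, b, c: 0.5 * (c + b) - 0.25 * a,
    "ADJ": lambda a, b, c: np.maximum(np.maximum(a, b), c) - a,
    "SUM": lambda a, b, c: a + b + c,
    "PRO": lambda a, b, c: a * b * c,
    "QUA": lambda a, b, c: np.sqrt((a * a + b * b + c * c) / 3.0),
    "GEO": lambda a, b, c: np.cbrt((a ** 3 + b ** 3 + c ** 3) / 3.0),
    "RAN": lambda a, b, c: (np.maximum(np.maximum(a, b), c)
                            - np.minimum(np.minimum(a, b), c)),
}


@dataclass(frozen=True)
class MultiMetricSpec:
    ids: tuple[str, str]
    name: str
    label: str
    family: str  # geometric | cluster | operator | agreement
    symmetry: str  # 'S' or 'A', as tabulated
    fn: Callable[[TripleContext], float]
    needs_duplex: bool = True
    uses_topology: bool = False

    @property
    def sides_fn(self) -> Callable | None:
        """Vectorised evaluator over side arrays, when the measure is a pure
        function of the three pairwise (dis)similarities."""
        return _SIDE_FORMULAS.get(self.name)


_MULTI_LIST = [
    MultiMetricSpec(("M33", "M34"), "AREA", "Triangle Area", "geometric", "S", _mm_area),
    MultiMetricSpec(("M35", "M36"), "INCIRCLE", "Triangle's Incircle Area", "geometric", "S", _mm_incircle),
    MultiMetricSpec(("M37", "M38"), "SUMSIDES", "Summation Sides", "geometric", "A", _mm_sum_sides),
    MultiMetricSpec(("M39", "M40"), "ANGLE", "Bond Angle", "geometric", "A", _mm_bond_angle,
                    needs_duplex=False),
    MultiMetricSpec(("M41", "M42"), "MIN", "MIN-RULE (1-NN)", "cluster", "A", _mm_min),
    MultiMetricSpec(("M43", "M44"), "JOIN", "JOIN-RULE (2-NN)", "cluster", "S", _mm_join),
    MultiMetricSpec(("M45", "M46"), "MAX", "MAX-RULE (furthest neighbour)", "cluster", "A", _mm_max),
    MultiMetricSpec(("M47", "M48"), "AVE", "AVE-RULE (average link)", "cluster", "A", _mm_ave),
    MultiMetricSpec(("M49", "M50"), "MED", "MED-RULE", "cluster", "A", _mm_med),
    MultiMetricSpec(("M51", "M52"), "WAR", "WAR-RULE (Ward)", "cluster", "A", _mm_war),
    MultiMetricSpec(("M53", "M54"), "ADJ", "ADJ-RULE", "cluster", "A", _mm_adj),
    MultiMetricSpec(("M55", "M56"), "MAH", "MAH-RULE (Mahalanobis-Ward)", "cluster", "A", _mm_mah),
    MultiMetricSpec(("M57", "M58"), "ADD", "ADD-RULE (average D/D degree)", "operator", "S", _mm_add,
                    uses_topology=True),
    MultiMetricSpec(("M59", "M60"), "SUM", "SUM-RULE (Wiener)", "operator", "S", _mm_sum),
    MultiMetricSpec(("M61", "M62"), "PRO", "PRO-RULE", "operator", "S", _mm_pro),
    MultiMetricSpec(("M63", "M64"), "QUA", "QUA-RULE", "operator", "S", _mm_qua),
    MultiMetricSpec(("M65", "M66"), "GEO", "GEO-RULE", "operator", "S", _mm_geo),
    MultiMetricSpec(("M67", "M68"), "RAN", "RAN-RULE", "operator", "S", _mm_ran),
    MultiMetricSpec(("M69", "M70"), "IC", "IC-RULE (additivity corrected)", "agreement", "A", _mm_ic),
    MultiMetricSpec(("M71", "M72"), "AC", "AC-RULE (additivity corrected)", "agreement", "S", _mm_ac),
    MultiMetricSpec(("M73", "M74"), "PC", "PC-RULE (proportionality corrected)", "agreement", "S", _mm_pc),
    MultiMetricSpec(("M75", "M76"), "LC", "LC-RULE (linearity corrected)", "agreement", "S", _mm_lc),
]

MULTI_METRICS: dict[str, MultiMetricSpec] = {}
for _s in _MULTI_LIST:
    MULTI_METRICS[_s.name] = _s
    for _id in _s.ids:
        MULTI_METRICS[_id] = _s


def get_multi(mm: str | MultiMetricSpec) -> MultiMetricSpec:
    if isinstance(mm, MultiMetricSpec):
        return mm
    try:
        return MULTI_METRICS[mm]
    except KeyError:
        raise UnknownMetricError(
            f"unknown multi-metric {mm!r}; known: "
            f"{sorted(s.name for s in _MULTI_LIST)} / M33-M76") from None


def multi_metric(ctx: TripleContext, mm: str | MultiMetricSpec) -> float:
    """Evaluate a ternary measure T_XYZ on one triple context."""
    return get_multi(mm).fn(ctx)


def duplex_for_tensor(points: np.ndarray, indices: tuple[int, int, int],
                      metric: MetricSpec, reference_mode: str,
                      mass_center: np.ndarray | None) -> float:
    """Duplex value for a repeated-index tensor entry (i, j, l), 0-based.

    Amino-acid mode: the metric between the two distinct residue points,
    and exactly 0 when i = j = l.  Center mode: the metric from the repeated
    residue's point to the protein mass center (so the tensor diagonal
    becomes non-zero).
    """
    i, j, l = indices
    distinct = set(indices)
    if len(distinct) == 3:
        raise ValueError("duplex_for_tensor needs a repeated index")
    if reference_mode == "aa":
        if len(distinct) == 1:
            return 0.0
        a, b = sorted(distinct)
        return metric(points[a], points[b])
    if reference_mode == "center":
        if mass_center is None:
            raise ValueError("center reference mode requires a mass center")
        if len(distinct) == 1:
            rep = i
        else:
            # the repeated residue: the index occurring twice
            rep = i if indices.count(i) == 2 else (j if indices.count(j) == 2 else l)
        return metric(points[rep], mass_center)
    raise ValueError(f"unknown reference mode {reference_mode!r}")


def list_duplex_metrics() -> list[MetricSpec]:
    return list(_DUPLEX_LIST)


def list_multi_metrics() -> list[MultiMetricSpec]:
    return list(_MULTI_LIST)
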