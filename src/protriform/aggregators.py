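"""Aggregation operators: fuse a LAI vector into one scalar descriptor.

Four families are provided, mirroring the descriptor engine's invariant
vocabulary:

norms
    N1 (plain summation — the classical additive total), N2 and N3
    (Minkowski norms of order 2 and 3);
means
    geometric G, arithmetic M, quadratic P2, cubic P3, harmonic A;
statistics
    population moments (V, SD, CV, S, K) and order statistics (R, Q1, Q2,
    Q3, I50, MX, MN; quantiles by linear interpolation);
classical
    autocorrelation AC(w), gravitational GV(w), information contents
    TIC/MIC/SIC (Shannon entropy over value equivalence classes), total
    sum over sliding windows TS(w), and Kier-Hall-style connectivity KH.

Windowed invariants carry their window in brackets in descriptor codes,
e.g. ``TS[7]`` or ``GV[5]``; the default window is 1.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .structure_io import ProteinGeometry

logger = logging.getLogger(__name__)

NORM_CODES = ("N1", "N2", "N3")
MEAN_CODES = ("G", "M", "P2", "P3", "A")
STAT_CODES = ("V", "S", "K", "SD", "CV", "R", "Q1", "Q2", "Q3", "I50",
              "MX", "MN")
CLASSICAL_CODES = ("AC", "GV", "TIC", "MIC", "SIC", "TS", "KH")
INVARIANT_CODES = NORM_CODES + MEAN_CODES + STAT_CODES + CLASSICAL_CODES
WINDOWED_CODES = ("AC", "GV", "TS")

#: invariants whose value depends on sequence/spatial context, not only on
#: the multiset of values
SEQUENCE_DEPENDENT = ("AC", "GV", "TS", "KH")

_KH_EPS = 1e-12
#: rounding quantum for information-content equivalence classes
IC_ROUND = 1e-4

FAMILY = {**{c: "norm" for c in NORM_CODES},
          **{c: "mean" for c in MEAN_CODES},
          **{c: "statistical" for c in STAT_CODES},
          **{c: "classical" for c in CLASSICAL_CODES}}


class UndefinedInvariantError(ValueError):
    """The invariant is undefined for this input (logged, not fatal)."""


class EmptyGroupError(ValueError):
    """A group filter selected no residue; the descriptor is undefined."""


_TOKEN_RE = re.compile(r"^([A-Z0-9]+?)(?:\[(\d+)\])?$")


@dataclass(frozen=True)
class InvariantSpec:
    code: str
    window: int | None = None

    def __post_init__(self) -> None:
        if self.code not in INVARIANT_CODES:
            raise ValueError(f"unknown invariant code {self.code!r}")
        if self.window is not None:
            if self.code not in WINDOWED_CODES:
                raise ValueError(
                    f"invariant {self.code} does not take a window")
            if self.window < 1:
                raise ValueError("window must be a positive integer")

    @property
    def w(self) -> int:
        return 1 if self.window is None else self.window

    def token(self) -> str:
        return self.code if self.window is None else f"{self.code}[{self.window}]"

    @classmethod
    def from_token(cls, token: str) -> "InvariantSpec":
        m = _TOKEN_RE.match(token)
        if not m or m.group(1) not in INVARIANT_CODES:
            raise ValueError(f"not an invariant token: {token!r}")
        win = m.group(2)
        return cls(m.group(1), None if win is None else int(win))


@dataclass(frozen=True)
class AggregationContext:
    """Spatial/sequence context for the distance-dependent invariants.

    ``positions`` are the 1-based residue positions of the aggregated
    values within the geometry (after any group filtering).
    """

    geometry: ProteinGeometry | None = None
    positions: tuple[int, ...] | None = None


def filter_group(values: np.ndarray, idx) -> np.ndarray:
    """Restrict a LAI vector to the (1-based) residue positions ``idx``."""
    idx = tuple(idx)
    if not idx:
        raise EmptyGroupError("group filter selected no residue")
    arr = np.asarray(values)
    if max(idx) > len(arr) or min(idx) < 1:
        raise IndexError("group index out of range")
    return arr[[i - 1 for i in idx]]


def _moments(v: np.ndarray):
    mean = float(v.mean())
    d = v - mean
    return mean, float((d ** 2).mean()), float((d ** 3).mean()), \
        float((d ** 4).mean())


def _entropy_bits(v: np.ndarray) -> float:
    classes = Counter(int(round(x / IC_ROUND)) for x in v)
    m = len(v)
    return -sum((c / m) * math.log2(c / m) for c in classes.values())


def aggregate(values, spec: InvariantSpec | str,
              ctx: AggregationContext | None = None) -> float:
    """Apply one aggregation operator to a value vector."""
    if isinstance(spec, str):
        spec = InvariantSpec.from_token(spec)
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("aggregate expects a non-empty 1-D vector")
    m = v.size
    code = spec.code

    if code == "N1":
        return float(v.sum())
    if code == "N2":
        return float(np.sqrt((v ** 2).sum()))
    if code == "N3":
        return float(np.cbrt((np.abs(v) ** 3).sum()))

    if code in ("G", "A") and np.any(v <= 0):
        raise UndefinedInvariantError(
            f"{code}: power mean undefined for non-positive entries")
    if code == "G":
        return float(np.exp(np.mean(np.log(v))))
    if code == "M":
        return float(v.mean())
    if code == "P2":
        return float(np.sqrt((v ** 2).mean()))
    if code == "P3":
        return float(np.cbrt((v ** 3).mean()))
    if code == "A":
        return float(m / (1.0 / v).sum())

    if code in ("V", "SD", "CV", "S", "K"):
        if m == 1:
            logger.warning("%s on a single value: returning 0 by convention",
                           code)
            return 0.0
        mean, m2, m3, m4 = _moments(v)
        if code == "V":
            return m2
        if code == "SD":
            return math.sqrt(m2)
        if code == "CV":
            if mean == 0.0:
                logger.warning("CV with zero mean: returning 0")
                return 0.0
            return math.sqrt(m2) / mean
        if m2 == 0.0:
            logger.warning("%s with zero variance: returning 0", code)
            return 0.0
        if code == "S":
            return m3 / m2 ** 1.5
        return m4 / m2 ** 2  # K, Pearson (non-excess) kurtosis

    if code == "R":
        return float(v.max() - v.min())
    if code in ("Q1", "Q2", "Q3"):
        q = {"Q1": 25, "Q2": 50, "Q3": 75}[code]
        return float(np.percentile(v, q, method="linear"))
    if code == "I50":
        return float(np.percentile(v, 75, method="linear")
                     - np.percentile(v, 25, method="linear"))
    if code == "MX":
        return float(v.max())
    if code == "MN":
        return float(v.min())

    if code in ("AC", "GV", "TS"):
        w = spec.w
        if w >= m:
            raise UndefinedInvariantError(
                f"{code}[{w}] undefined on a vector of length {m}")
    if code == "AC":
        w = spec.w
        return float((v[:-w] * v[w:]).sum() / (m - w))
    if code == "GV":
        w = spec.w
        if ctx is None or ctx.geometry is None:
            raise UndefinedInvariantError("GV requires a geometry context")
        pos = ctx.positions or tuple(range(1, m + 1))
        pts = ctx.geometry.points
        total = 0.0
        for a in range(m):
            for b in range(a + 1, m):
                if abs(pos[a] - pos[b]) > w:
                    continue
                d2 = float(((pts[pos[a] - 1] - pts[pos[b] - 1]) ** 2).sum())
                if d2 == 0.0:
                    logger.warning("GV: coincident points, pair skipped")
                    continue
                total += v[a] * v[b] / d2
        return total
    if code == "TS":
        w = spec.w
        return float(sum(v[s:s + w].sum() for s in range(m - w + 1)))

    if code == "MIC":
        return _entropy_bits(v)
    if code == "TIC":
        return m * _entropy_bits(v)
    if code == "SIC":
        if m == 1:
            logger.warning("SIC on a single value: returning 0")
            return 0.0
        return _entropy_bits(v) / math.log2(m)
    if code == "KH":
        if m == 1:
            return 0.0
        return float(sum((abs(v[i] * v[i + 1]) + _KH_EPS) ** -0.5
                         for i in range(m - 1)))
    raise ValueError(f"unhandled invariant {code!r}")  # pragma: no cover


def list_invariants() -> list[dict]:
    return [{"code": c, "family": FAMILY[c],
             "windowed": c in WINDOWED_CODES} for c in INVARIANT_CODES]
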