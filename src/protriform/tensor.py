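"""Three-tuple (dis)similarity tensors: assembly, powers, normalizations.

The total tensor Z holds, at entry (i, j, l):

* the ternary multi-metric value when i, j, l are pairwise distinct;
* the duplex metric value when exactly two indices coincide (*complete*
  tensors) or 0 (*non-complete* tensors);
* on the diagonal (i = j = l): 0 in amino-acid reference mode, or the
  duplex distance from residue i to the protein mass center in
  mass-center reference mode.

The raw (non-stochastic, NS) tensor can then be raised to an element-wise
Hadamard power k in [-12, 12] (negative k takes reciprocal powers; zeros are
fixed points) and normalized either per first-index slice (simple
stochastic, SS) or by the grand total (mutual probability, MP) — always in
that order: build, power, normalize.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .metrics import (MetricSpec, MultiMetricSpec, TripleContext,
                      duplex_for_tensor, get_duplex, get_multi, make_context)
from .structure_io import ProteinGeometry

logger = logging.getLogger(__name__)

COMPLETENESS = ("complete", "non-complete")
REFERENCE_MODES = ("aa", "center")
NORMALIZATIONS = ("NS", "SS", "MP")

#: dense-storage guardrail; n**3 float64 beyond this needs allow_large=True
MAX_DENSE_N = 400


class MissingMetricError(ValueError):
    """A duplex metric is required but none was configured."""


class DegenerateTensorError(ValueError):
    """Mutual-probability normalization of an all-zero tensor."""


class HadamardDomainError(ValueError):
    """Non-integer power of a tensor with negative entries."""


@dataclass(frozen=True)
class TensorMeta:
    representation: str = ""
    multi_metric: str = ""
    duplex_metric: str | None = None
    completeness: str = "complete"
    reference_mode: str = "aa"
    power: float = 1.0
    normalization: str = "NS"


@dataclass(frozen=True)
class TDSM:
    """Order-3 n x n x n (dis)similarity tensor with its recipe metadata."""

    values: np.ndarray
    meta: TensorMeta = TensorMeta()

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError(f"tensor must be cubic, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("tensor entries must be finite")


@dataclass(frozen=True)
class AaLevelTDSM:
    """The additive per-residue component of a total tensor (1-based aa)."""

    aa_index: int
    values: np.ndarray


def aa_weight_array(n: int, aa: int) -> np.ndarray:
    """Weight tensor w[i,j,l] = (#indices equal to aa)/3, for 1-based aa."""
    eq = (np.arange(n) == (aa - 1)).astype(float)
    return (eq[:, None, None] + eq[None, :, None] + eq[None, None, :]) / 3.0


def _topology_matrix(g: ProteinGeometry) -> np.ndarray:
    """|i - j| in sequence positions; inf across chain breaks."""
    n = g.n
    pos = np.arange(n, dtype=float)
    P = np.abs(pos[:, None] - pos[None, :])
    if g.chain_ids:
        ch = np.asarray(g.chain_ids)
        P[ch[:, None] != ch[None, :]] = np.inf
    return P


def _distance_matrix(g: ProteinGeometry, metric: MetricSpec) -> np.ndarray:
    n = g.n
    D = np.zeros((n, n))
    if metric.name == "euclidean":
        diff = g.points[:, None, :] - g.points[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = metric(g.points[i], g.points[j])
    return D


def _distinct_mask(n: int) -> np.ndarray:
    idx = np.arange(n)
    i = idx[:, None, None]
    j = idx[None, :, None]
    l = idx[None, None, :]
    return (i != j) & (j != l) & (i != l)


def _fill_distinct(g: ProteinGeometry, mm: MultiMetricSpec,
                   side_metric: MetricSpec, D: np.ndarray,
                   P: np.ndarray) -> np.ndarray:
    """Multi-metric values for all ordered triples (garbage elsewhere)."""
    n = g.n
    sides_fn = mm.sides_fn
    if sides_fn is not None:
        a = D[:, :, None]  # d(i, j)
        b = D[None, :, :]  # d(j, l)
        c = D[:, None, :]  # d(l, i) == d(i, l)
        return np.asarray(np.broadcast_to(sides_fn(a, b, c), (n, n, n)),
                          dtype=float).copy()
    if mm.name == "ADD":
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = np.where(np.isfinite(P) & (P > 0), D / P, 0.0)[:, :, None]
            tb = np.where(np.isfinite(P) & (P > 0), D / P, 0.0)[None, :, :]
            tc = np.where(np.isfinite(P) & (P > 0), D / P, 0.0)[:, None, :]
        return (ta + tb + tc) / 3.0
    if mm.name == "ANGLE":
        diff = g.points[:, None, :] - g.points[None, :, :]   # [a,b] = p_a - p_b
        norm = np.linalg.norm(diff, axis=2)
        num = np.einsum("ijt,ljt->ijl", diff, diff)
        den = norm[:, :, None] * norm.T[None, :, :]
        mask = _distinct_mask(n)
        if np.any((den == 0) & mask):
            from .metrics import UndefinedAngleError
            raise UndefinedAngleError(
                "bond angle undefined: coincident residue points")
        with np.errstate(divide="ignore", invalid="ignore"):
            cos = np.where(den > 0, num / np.where(den == 0, 1.0, den), 0.0)
        return np.arccos(np.clip(cos, -1.0, 1.0))
    # generic per-triple path (Mahalanobis, agreement coefficients, ...)
    out = np.zeros((n, n, n))
    pts = g.points
    pos = list(range(1, n + 1))
    chains = g.chain_ids or tuple("A" * n)
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            for l in range(n):
                if l == i or l == j:
                    continue
                ctx = TripleContext(
                    X=pts[i], Y=pts[j], Z=pts[l],
                    d_XY=D[i, j], d_YZ=D[j, l], d_ZX=D[l, i],
                    p_XY=P[i, j], p_YZ=P[j, l], p_ZX=P[l, i],
                    metric=side_metric,
                )
                out[i, j, l] = mm.fn(ctx)
    return out


def build_tdsm(g: ProteinGeometry, mm, metric=None,
               completeness: str = "complete", reference_mode: str = "aa",
               *, allow_large: bool = False) -> TDSM:
    """Assemble the raw (NS, k=1) three-tuple tensor for a geometry."""
    mm_spec = get_multi(mm)
    if completeness not in COMPLETENESS:
        raise ValueError(f"unknown completeness {completeness!r}")
    if reference_mode not in REFERENCE_MODES:
        raise ValueError(f"unknown reference mode {reference_mode!r}")
    if g.n < 3:
        raise ValueError("trilinear tensors need at least 3 residues")
    if g.n > MAX_DENSE_N and not allow_large:
        raise ValueError(
            f"n={g.n} exceeds the dense-storage guardrail ({MAX_DENSE_N}); "
            "pass allow_large=True to override")
    if metric is None and completeness == "complete" and mm_spec.needs_duplex:
        raise MissingMetricError(
            f"complete tensors with {mm_spec.name} require a duplex metric")
    if metric is None and reference_mode == "center":
        raise MissingMetricError(
            "mass-center reference mode requires a duplex metric")
    metric_spec = get_duplex(metric) if metric is not None else None
    side_metric = metric_spec or get_duplex("euclidean")

    D = _distance_matrix(g, side_metric)
    P = _topology_matrix(g)
    Z = _fill_distinct(g, mm_spec, side_metric, D, P)
    mask = _distinct_mask(g.n)
    Z[~mask] = 0.0

    n = g.n
    if completeness == "complete" and metric_spec is not None:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if reference_mode == "aa":
                    # the metric between the two distinct residues
                    Z[i, i, j] = Z[i, j, i] = Z[j, i, i] = D[i, j]
                else:
                    # the repeated residue (i) measured against the center
                    dcenter_i = metric_spec(g.points[i], g.mass_center)
                    Z[i, i, j] = Z[i, j, i] = Z[j, i, i] = dcenter_i
    if reference_mode == "center" and metric_spec is not None:
        for i in range(n):
            Z[i, i, i] = metric_spec(g.points[i], g.mass_center)

    meta = TensorMeta(
        representation=g.representation,
        multi_metric=mm_spec.name,
        duplex_metric=None if metric_spec is None else metric_spec.name,
        completeness=completeness,
        reference_mode=reference_mode,
        power=1.0,
        normalization="NS",
    )
    return TDSM(values=Z, meta=meta)


def hadamard_power(t: TDSM, k: float) -> TDSM:
    """Element-wise power with zero entries as fixed points.

    Negative k takes reciprocal powers on the non-zero support; non-integer
    k on tensors with negative entries is a domain error.
    """
    if not -12.0 <= k <= 12.0:
        raise ValueError(f"Hadamard power k={k} outside [-12, 12]")
    if t.meta.normalization != "NS":
        raise ValueError("Hadamard power applies to the non-stochastic tensor")
    v = t.values
    out = np.zeros_like(v)
    nz = v != 0.0
    if float(k).is_integer():
        out[nz] = v[nz] ** k
    else:
        if np.any(v[nz] < 0):
            raise HadamardDomainError(
                f"non-integer power k={k} of a tensor with negative entries")
        out[nz] = v[nz] ** k
    if not np.all(np.isfinite(out)):
        raise HadamardDomainError(f"Hadamard power k={k} overflowed")
    return TDSM(values=out, meta=replace(t.meta, power=float(k)))


def normalize_ss(t: TDSM) -> TDSM:
    """Simple-stochastic: divide each entry by its first-index slice sum."""
    if t.meta.normalization != "NS":
        raise ValueError("normalization applies to the non-stochastic tensor")
    v = t.values.copy()
    sums = v.sum(axis=(1, 2))
    for i, s in enumerate(sums):
        if s == 0.0:
            if np.any(v[i] != 0.0):
                logger.warning("SS: slice %d sums to zero, left unchanged", i)
            continue
        v[i] /= s
    return TDSM(values=v, meta=replace(t.meta, normalization="SS"))


def normalize_mp(t: TDSM) -> TDSM:
    """Mutual-probability: divide every entry by the grand total."""
    if t.meta.normalization != "NS":
        raise ValueError("normalization applies to the non-stochastic tensor")
    total = t.values.sum()
    if total == 0.0:
        raise DegenerateTensorError("tensor grand total is zero")
    return TDSM(values=t.values / total,
                meta=replace(t.meta, normalization="MP"))


def apply_normalization(t: TDSM, normalization: str) -> TDSM:
    if normalization == "NS":
        return t
    if normalization == "SS":
        return normalize_ss(t)
    if normalization == "MP":
        return normalize_mp(t)
    raise ValueError(f"unknown normalization {normalization!r}")


def aa_tensor(t: TDSM, aa: int) -> AaLevelTDSM:
    """Amino-acid-level tensor for 1-based residue ``aa``.

    Entries keep weight 1 when all three indices equal ``aa``, 2/3 when
    exactly two do, 1/3 when exactly one does, and 0 otherwise; summing the
    n amino-acid-level tensors reconstructs the total tensor exactly.
    """
    if not 1 <= aa <= t.n:
        raise IndexError(f"aa index {aa} out of range 1..{t.n}")
    w = aa_weight_array(t.n, aa)
    return AaLevelTDSM(aa_index=aa, values=t.values * w)


def dump_tsv(t: TDSM, path) -> None:
    """Flat (i, j, l, value) TSV dump with a metadata header; round-trips."""
    m = t.meta
    with open(path, "w") as fh:
        fh.write(f"#n\t{t.n}\n")
        fh.write(f"#representation\t{m.representation}\n")
        fh.write(f"#multi_metric\t{m.multi_metric}\n")
        fh.write(f"#duplex_metric\t{m.duplex_metric or ''}\n")
        fh.write(f"#completeness\t{m.completeness}\n")
        fh.write(f"#reference_mode\t{m.reference_mode}\n")
        fh.write(f"#power\t{m.power!r}\n")
        fh.write(f"#normalization\t{m.normalization}\n")
        fh.write("i\tj\tl\tvalue\n")
        n = t.n
        for i in range(n):
            for j in range(n):
                for l in range(n):
                    fh.write(f"{i + 1}\t{j + 1}\t{l + 1}\t"
                             f"{float(t.values[i, j, l])!r}\n")


def load_tsv(path) -> TDSM:
    meta_kv: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                meta_kv[key] = val
            elif line and not line.startswith("i\t"):
                rows.append(line.split("\t"))
    n = int(meta_kv["n"])
    v = np.zeros((n, n, n))
    for i, j, l, value in rows:
        v[int(i) - 1, int(j) - 1, int(l) - 1] = float(value)
    meta = TensorMeta(
        representation=meta_kv.get("representation", ""),
        multi_metric=meta_kv.get("multi_metric", ""),
        duplex_metric=meta_kv.get("duplex_metric") or None,
        completeness=meta_kv.get("completeness", "complete"),
        reference_mode=meta_kv.get("reference_mode", "aa"),
        power=float(meta_kv.get("power", "1.0")),
        normalization=meta_kv.get("normalization", "NS"),
    )
    return TDSM(values=v, meta=meta)
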