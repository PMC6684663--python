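"""Synthetic peptide structures and a brute-force oracle suite.

The generator emits a self-avoiding random walk of alpha carbons with a
fixed 3.8 A virtual-bond spacing and idealized local atoms (backbone N, C,
O, a beta carbon, and a small three-atom side-chain blob rotated by residue
index) so all four residue representations are derivable and mutually
distinct.  Everything is deterministic for a fixed seed.

The oracle suite recomputes tensors, powers, normalizations, amino-acid
decompositions and trilinear contractions with naive per-entry loops,
straight from the definitions, for use as an independent reference in
tests.  It is intentionally slow and limited to small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import metrics as _metrics
from .properties import CANONICAL, MacroVectors
from .structure_io import (AtomRecord, ONE_TO_THREE, ProteinGeometry,
                           RawStructure, Residue)
from .tensor import TDSM, TensorMeta

CA_SPACING = 3.8
_CLASH_CUTOFF = 3.2


class WalkFailedError(RuntimeError):
    """Self-avoiding walk failed within the retry budget for this seed."""


@dataclass(frozen=True)
class PeptideSpec:
    n: int
    seed: int = 0
    sequence: str | None = None
    ca_spacing: float = CA_SPACING

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("peptides need at least 3 residues")
        if self.sequence is not None and len(self.sequence) != self.n:
            raise ValueError("sequence length must equal n")


def _walk(rng: np.random.Generator, n: int, spacing: float) -> np.ndarray:
    for _attempt in range(64):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            for _retry in range(256):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = pts[-1] + spacing * d
                dists = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1) \
                    if len(pts) > 1 else np.array([np.inf])
                if dists.min() > _CLASH_CUTOFF:
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise WalkFailedError("self-avoiding walk failed; try another seed")


def _rot_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# local offsets from the alpha carbon (Angstrom); rotated per residue so
# AVG geometry genuinely differs residue-to-residue from CA/CB
_OFFSETS = {
    "N": np.array([-1.20, 0.80, 0.20]),
    "C": np.array([0.55, 1.42, -0.30]),
    "O": np.array([0.60, 2.60, -0.35]),
    "CB": np.array([0.64, -1.02, 1.53 * 0.66]),
    "CG": np.array([1.00, -1.60, 2.20]),
    "CD": np.array([1.80, -2.40, 2.60]),
    "CE": np.array([2.70, -2.70, 3.40]),
}


def synthetic_peptide(spec: PeptideSpec) -> RawStructure:
    """Deterministic synthetic peptide with all representations derivable."""
    rng = np.random.default_rng(spec.seed)
    ca = _walk(rng, spec.n, spec.ca_spacing)
    if spec.sequence is not None:
        seq = spec.sequence.upper()
        if any(aa not in CANONICAL for aa in seq):
            raise ValueError("sequence contains non-canonical codes")
    else:
        seq = "".join(rng.choice(list(CANONICAL), size=spec.n))
    residues = []
    serial = 1
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for i in range(spec.n):
        R = _rot_z(golden * i)
        atoms = []

        def add(name: str, pos: np.ndarray, element: str = "C"):
            nonlocal serial
            atoms.append(AtomRecord(
                serial=serial, atom_name=name,
                residue_name=ONE_TO_THREE[seq[i]], chain_id="A",
                residue_number=i + 1, position=pos, element=element))
            serial += 1

        add("N", ca[i] + R @ _OFFSETS["N"], "N")
        add("CA", ca[i])
        add("C", ca[i] + R @ _OFFSETS["C"])
        add("O", ca[i] + R @ _OFFSETS["O"], "O")
        if seq[i] != "G":
            add("CB", ca[i] + R @ _OFFSETS["CB"])
            for blob in ("CG", "CD", "CE"):
                add(blob, ca[i] + R @ _OFFSETS[blob])
        residues.append(Residue("A", i + 1, seq[i], tuple(atoms)))
    return RawStructure(tuple(residues))


def write_pdb(s: RawStructure, path=None) -> str:
    """Serialize a structure as fixed-column PDB ATOM records."""
    lines = []
    for res in s.residues:
        for a in res.atoms:
            name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
            x, y, z = a.position
            lines.append(
                f"ATOM  {a.serial:5d} {name}"
                f" {a.residue_name:>3s} {a.chain_id}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# --------------------------------------------------------------------------
# brute-force oracle (naive loops straight from the definitions)
# --------------------------------------------------------------------------

_MAX_ORACLE_N = 8


def _oracle_guard(n: int) -> None:
    if n > _MAX_ORACLE_N:
        raise ValueError(f"oracle limited to n <= {_MAX_ORACLE_N}")


def oracle_tdsm(g: ProteinGeometry, mm, metric=None,
                completeness: str = "complete",
                reference_mode: str = "aa") -> np.ndarray:
    """Per-entry tensor assembly by explicit case analysis."""
    _oracle_guard(g.n)
    mm_spec = _metrics.get_multi(mm)
    mspec = _metrics.get_duplex(metric) if metric is not None else None
    side = mspec or _metrics.get_duplex("euclidean")
    n = g.n
    Z = np.zeros((n, n, n))
    positions = list(range(1, n + 1))
    chains = list(g.chain_ids) if g.chain_ids else ["A"] * n
    for i in range(n):
        for j in range(n):
            for l in range(n):
                distinct = len({i, j, l})
                if distinct == 3:
                    ctx = _metrics.make_context(
                        g.points[i], g.points[j], g.points[l], metric=side,
                        positions=[positions[i], positions[j], positions[l]],
                        chains=[chains[i], chains[j], chains[l]],
                        mass_center=g.mass_center)
                    Z[i, j, l] = mm_spec.fn(ctx)
                elif distinct == 2:
                    if completeness == "complete" and mspec is not None:
                        Z[i, j, l] = _metrics.duplex_for_tensor(
                            g.points, (i, j, l), mspec, reference_mode,
                            g.mass_center)
                else:  # diagonal
                    if reference_mode == "center" and mspec is not None:
                        Z[i, j, l] = mspec(g.points[i], g.mass_center)
    return Z


def oracle_hadamard(Z: np.ndarray, k: float) -> np.ndarray:
    out = np.zeros_like(Z)
    it = np.nditer(Z, flags=["multi_index"])
    for val in it:
        v = float(val)
        out[it.multi_index] = 0.0 if v == 0.0 else v ** k
    return out


def oracle_ss(Z: np.ndarray) -> np.ndarray:
    n = Z.shape[0]
    out = Z.copy()
    for i in range(n):
        s = 0.0
        for j in range(n):
            for l in range(n):
                s += Z[i, j, l]
        if s != 0.0:
            for j in range(n):
                for l in range(n):
                    out[i, j, l] = Z[i, j, l] / s
    return out


def oracle_mp(Z: np.ndarray) -> np.ndarray:
    total = 0.0
    n = Z.shape[0]
    for i in range(n):
        for j in range(n):
            for l in range(n):
                total += Z[i, j, l]
    return Z / total


def oracle_aa_tensor(Z: np.ndarray, aa: int) -> np.ndarray:
    n = Z.shape[0]
    a = aa - 1
    out = np.zeros_like(Z)
    for i in range(n):
        for j in range(n):
            for l in range(n):
                matches = (i == a) + (j == a) + (l == a)
                if matches == 3:
                    out[i, j, l] = Z[i, j, l]
                elif matches == 2:
                    out[i, j, l] = 2.0 / 3.0 * Z[i, j, l]
                elif matches == 1:
                    out[i, j, l] = Z[i, j, l] / 3.0
    return out


def oracle_trilinear(Z: np.ndarray, v: MacroVectors) -> float:
    n = Z.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            for l in range(n):
                total += Z[i, j, l] * v.x[i] * v.y[j] * v.p[l]
    return total


def oracle_lai(Z: np.ndarray, v: MacroVectors) -> np.ndarray:
    n = Z.shape[0]
    return np.array([oracle_trilinear(oracle_aa_tensor(Z, aa), v)
                     for aa in range(1, n + 1)])


def oracle_normalized(Z: np.ndarray, k: float, normalization: str) -> np.ndarray:
    """Power then normalization, both by naive loops."""
    Zk = oracle_hadamard(Z, k)
    if normalization == "SS":
        return oracle_ss(Zk)
    if normalization == "MP":
        return oracle_mp(Zk)
    return Zk
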