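"""Trilinear contractions: the total index and the per-residue LAI vector.

The total trilinear index is the triple contraction

    L = sum_i sum_j sum_l  z_ijl * x_i * y_j * p_l

of the tensor with the three macro-molecular vectors.  The Local Amino
Acidic Invariant (LAI) splits this total additively over residues: entry
``aa`` is the same contraction applied to the amino-acid-level tensor of
``aa`` (weights 1, 2/3, 1/3, 0 by index-match count), so the LAI entries sum
exactly to the total index.

``compute_lai`` streams the weights instead of materializing n full
tensors: with slot sums A_i = x_i * (Z y p)_i, B_j = y_j * (x Z p)_j and
C_l = p_l * (x y Z)_l, the entry-weight m/3 (m = number of index slots
equal to aa) makes LAI = (A + B + C) / 3 — one O(n^3) pass in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .properties import MacroVectors
from .tensor import TDSM, aa_tensor


@dataclass(frozen=True)
class LAI:
    """Per-residue trilinear index vector with its provenance."""

    values: np.ndarray
    provenance: object | None = None

    @property
    def n(self) -> int:
        return len(self.values)


def _check(t: TDSM, v: MacroVectors) -> None:
    if v.n != t.n:
        raise ValueError(f"macro-vector length {v.n} != tensor size {t.n}")


def trilinear(t: TDSM, v: MacroVectors) -> float:
    """Total trilinear index: the full triple contraction."""
    _check(t, v)
    return float(np.einsum("ijl,i,j,l->", t.values, v.x, v.y, v.p))


def compute_lai(t: TDSM, v: MacroVectors, provenance=None) -> LAI:
    """Per-residue decomposition of the trilinear index (streamed)."""
    _check(t, v)
    Z = t.values
    A = v.x * np.einsum("ijl,j,l->i", Z, v.y, v.p)
    B = v.y * np.einsum("ijl,i,l->j", Z, v.x, v.p)
    C = v.p * np.einsum("ijl,i,j->l", Z, v.x, v.y)
    return LAI(values=(A + B + C) / 3.0, provenance=provenance)


def compute_lai_materialized(t: TDSM, v: MacroVectors) -> LAI:
    """Definitional route: one materialized aa-level tensor per residue.

    Kept as the slow reference the streamed version is tested against.
    """
    _check(t, v)
    out = np.empty(t.n)
    for aa in range(1, t.n + 1):
        part = aa_tensor(t, aa).values
        out[aa - 1] = float(np.einsum("ijl,i,j,l->", part, v.x, v.y, v.p))
    return LAI(values=out)


def export_lai(l: LAI, sequence: str, path) -> None:
    """TSV export (residue index, aa code, value) for residue-level work."""
    if len(sequence) != l.n:
        raise ValueError("sequence length does not match LAI length")
    with open(path, "w") as fh:
        fh.write("index\taa\tvalue\n")
        for i, (aa, val) in enumerate(zip(sequence, l.values), start=1):
            fh.write(f"{i}\t{aa}\t{val!r}\n")
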