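"""Read PDB structures and reduce them to one-point-per-residue geometries.

The descriptor engine treats a protein as an ordered set of pseudo-vertices,
one per amino acid, placed at a configurable representative point:

``CA``
    the alpha carbon — the classical coarse representation;
``CB``
    the beta carbon, falling back to the alpha carbon for glycine (or any
    residue whose CB is missing from the file);
``AB``
    the backbone carbonyl carbon (PDB atom name ``C``);
``AVG``
    the unweighted mean of all heavy-atom coordinates of the residue.

The protein mass center (atomic-mass-weighted centroid over all heavy atoms)
is carried alongside, because mass-center-referenced tensors measure every
residue against it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

REPRESENTATIONS = ("CA", "CB", "AB", "AVG")

#: 3-letter -> 1-letter codes of the 20 canonical amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class EmptyStructureError(ValueError):
    """No parseable standard-amino-acid ATOM record in the input."""


class PDBParseError(ValueError):
    """A malformed fixed-column record; the message names the line."""


class TooSmallStructureError(ValueError):
    """Fewer than 3 residues with a derivable representation point."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # shape (3,), Angstrom
    element: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_number: int
    code: str  # 1-letter
    atoms: tuple[AtomRecord, ...]


@dataclass(frozen=True)
class RawStructure:
    """Ordered residues (file order) with their ATOM records."""

    residues: tuple[Residue, ...]

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)


@dataclass(frozen=True)
class ProteinGeometry:
    """One 3D point per residue under a chosen representation.

    ``chain_ids`` is retained so sequence-topological distances can treat
    chain breaks as infinite separation.
    """

    representation: str
    codes: str                       # 1-letter codes, length n
    points: np.ndarray               # (n, 3) Angstrom
    mass_center: np.ndarray          # (3,)
    chain_ids: tuple[str, ...] = ()
    residue_numbers: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def sequence(self) -> str:
        return self.codes

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.points.shape != (len(self.codes), 3):
            raise ValueError("points shape does not match residue count")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite representation point")
        if not np.all(np.isfinite(self.mass_center)):
            raise ValueError("non-finite mass center")


def parse_pdb(text: str) -> RawStructure:
    """Parse PDB-format content into an ordered residue list.

    Only ``ATOM`` records of the 20 standard amino acids are kept; alternate
    locations other than blank/"A" are dropped; only the first MODEL is read.
    """
    if not isinstance(text, str):
        raise TypeError("parse_pdb expects PDB text")
    _check_fixed_columns(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    residues: list[Residue] = []
    if len(st) > 0:
        model = st[0]  # first MODEL only
        for chain in model:
            for res in chain:
                if res.het_flag != "A":  # ATOM records only
                    continue
                code = THREE_TO_ONE.get(res.name.upper())
                if code is None:
                    logger.warning("dropping non-canonical residue %s %s%d",
                                   res.name, chain.name, res.seqid.num)
                    continue
                atoms = []
                for atom in res:
                    if atom.altloc not in ("", "A", "\0"):
                        continue
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    atoms.append(AtomRecord(
                        serial=atom.serial,
                        atom_name=atom.name,
                        residue_name=res.name.upper(),
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        position=pos,
                        element=atom.element.name,
                    ))
                if atoms:
                    residues.append(Residue(chain.name, res.seqid.num, code,
                                            tuple(atoms)))
    if not residues:
        raise EmptyStructureError(
            "no standard-amino-acid ATOM record found in input")
    return RawStructure(tuple(residues))


def _check_fixed_columns(text: str) -> None:
    """Reject ATOM lines whose fixed coordinate columns do not parse."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {fieldtxt!r}"
                ) from None


def _heavy(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if a.element.upper() != "H"]


def mass_center(s: RawStructure, *, weighted: bool = True) -> np.ndarray:
    """Atomic-mass-weighted centroid over all heavy atoms.

    ``weighted=False`` switches to the plain unweighted centroid.
    """
    pts, masses = [], []
    for res in s.residues:
        for a in _heavy(res.atoms):
            pts.append(a.position)
            masses.append(gemmi.Element(a.element or "C").weight if weighted else 1.0)
    if not pts:
        raise EmptyStructureError("structure has no heavy atom")
    pts_arr = np.asarray(pts)
    w = np.asarray(masses)
    return (pts_arr * w[:, None]).sum(axis=0) / w.sum()


def _residue_point(res: Residue, rep: str) -> np.ndarray | None:
    by_name = {a.atom_name: a for a in res.atoms}
    if rep == "CA":
        a = by_name.get("CA")
        return None if a is None else a.position
    if rep == "CB":
        a = by_name.get("CB") or by_name.get("CA")  # glycine / missing CB
        return None if a is None else a.position
    if rep == "AB":
        a = by_name.get("C")  # backbone carbonyl carbon
        return None if a is None else a.position
    if rep == "AVG":
        heavy = _heavy(res.atoms)
        if not heavy:
            return None
        return np.mean([a.position for a in heavy], axis=0)
    raise ValueError(f"unknown representation {rep!r}")


def derive_geometry(s: RawStructure, rep: str,
                    *, weighted_center: bool = True) -> ProteinGeometry:
    """Reduce a parsed structure to one point per residue under ``rep``.

    Residues for which no point can be derived are dropped with a warning;
    fewer than 3 derivable residues is an error (no trilinear relation can
    be formed).
    """
    if rep not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {rep!r}; "
                         f"expected one of {REPRESENTATIONS}")
    codes: list[str] = []
    points: list[np.ndarray] = []
    chains: list[str] = []
    numbers: list[int] = []
    for res in s.residues:
        p = _residue_point(res, rep)
        if p is None:
            logger.warning("dropping residue %s%d (%s): no %s point derivable",
                           res.chain_id, res.residue_number, res.code, rep)
            continue
        codes.append(res.code)
        points.append(p)
        chains.append(res.chain_id)
        numbers.append(res.residue_number)
    if len(codes) < 3:
        raise TooSmallStructureError(
            f"only {len(codes)} residue(s) with a derivable {rep} point; "
            "need at least 3")
    return ProteinGeometry(
        representation=rep,
        codes="".join(codes),
        points=np.asarray(points, dtype=float),
        mass_center=mass_center(s, weighted=weighted_center),
        chain_ids=tuple(chains),
        residue_numbers=tuple(numbers),
    )


def write_representation(g: ProteinGeometry, path) -> None:
    """Export the geometry as a TSV 'representation file' (6 decimals)."""
    with open(path, "w") as fh:
        fh.write("index\tchain\tresidue_number\taa\tx\ty\tz\trepresentation\n")
        chains = g.chain_ids or ("A",) * g.n
        numbers = g.residue_numbers or tuple(range(1, g.n + 1))
        for i in range(g.n):
            x, y, z = g.points[i]
            fh.write(f"{i + 1}\t{chains[i]}\t{numbers[i]}\t{g.codes[i]}\t"
                     f"{x:.6f}\t{y:.6f}\t{z:.6f}\t{g.representation}\n")
        mc = g.mass_center
        fh.write(f"#mass_center\t{mc[0]:.6f}\t{mc[1]:.6f}\t{mc[2]:.6f}\n")


def read_representation(path) -> ProteinGeometry:
    """Re-read a representation TSV written by :func:`write_representation`."""
    codes, points, chains, numbers = [], [], [], []
    rep = None
    center = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("index\t"):
            raise PDBParseError("not a representation file (bad header)")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#mass_center"):
                _, x, y, z = line.split("\t")
                center = np.array([float(x), float(y), float(z)])
                continue
            _, chain, num, aa, x, y, z, rep = line.split("\t")
            codes.append(aa)
            chains.append(chain)
            numbers.append(int(num))
            points.append([float(x), float(y), float(z)])
    if center is None or rep is None:
        raise PDBParseError("representation file missing mass center line")
    return ProteinGeometry(
        representation=rep,
        codes="".join(codes),
        points=np.asarray(points),
        mass_center=center,
        chain_ids=tuple(chains),
        residue_numbers=tuple(numbers),
    )
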