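"""Amino-acid property scales, macro-molecular vectors and residue groups.

The trilinear form contracts an order-3 tensor with three length-n vectors
[X], [Y], [P] built from per-residue physicochemical properties.  How the
three vectors are populated defines the *form type*:

========  =====================================================  =========
code      vectors                                                #props
========  =====================================================  =========
``Tr``    three distinct property vectors (canonical)            3
``TrL``   one property vector + two identity (all-ones) vectors  1
``TrB``   one property vector twice + one identity vector        1
``TrQB``  one property vector twice + a second property once     2
``TrC``   the same property vector three times (cubic)           1
========  =====================================================  =========

Property values come from a bundled CSV of standard literature scales
(swappable by configuration); residue groups (helix/sheet formers, aromatic,
charged, ...) restrict the per-residue index vector to a subset of positions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

FORM_TYPES = ("Tr", "TrL", "TrB", "TrQB", "TrC")
FORM_ARITY = {"Tr": 3, "TrL": 1, "TrB": 1, "TrQB": 2, "TrC": 1}

#: identity pseudo-property: the all-ones vector.
IDENTITY_CODE = "1"

PROPERTY_SOURCES = {
    "PAH": "Chou-Fasman alpha-helix propensity P(a)",
    "PBS": "Chou-Fasman beta-sheet propensity P(b)",
    "ISA": "isotropic surface area (Collantes & Dunn)",
    "ECI": "electronic charge index (Collantes & Dunn)",
    "KDS": "Kyte-Doolittle hydropathy",
    "Z3": "third z-scale, electronic character (approximate rounded values)",
    "HWS": "Hopp-Woods hydrophilicity",
    "MM": "average side-chain mass, Da (approximate)",
}


class UnknownPropertyError(KeyError):
    pass


class NonCanonicalResidueError(ValueError):
    pass


@dataclass(frozen=True)
class PropertyTable:
    code: str
    values: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        missing = [aa for aa in CANONICAL if aa not in self.values]
        if missing:
            raise ValueError(f"property {self.code}: missing values for {missing}")
        bad = [aa for aa, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"property {self.code}: non-finite values for {bad}")


class PropertyRegistry:
    """Registry of property scales keyed by short code (PAH, KDS, ...)."""

    def __init__(self) -> None:
        self._tables: dict[str, PropertyTable] = {}

    def register(self, table: PropertyTable, *, overwrite: bool = False) -> None:
        if table.code in self._tables and not overwrite:
            raise ValueError(f"property code {table.code} already registered")
        self._tables[table.code] = table

    def __contains__(self, code: str) -> bool:
        return code == IDENTITY_CODE or code in self._tables

    def get(self, code: str) -> PropertyTable:
        try:
            return self._tables[code]
        except KeyError:
            raise UnknownPropertyError(
                f"unknown property code {code!r}; known: {sorted(self._tables)}"
            ) from None

    def codes(self) -> list[str]:
        return sorted(self._tables)

    @classmethod
    def from_csv(cls, fh) -> "PropertyRegistry":
        """Load a registry from CSV with header ``aa,code1,code2,...``."""
        reg = cls()
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[0] != "aa":
            raise ValueError("property CSV must start with an 'aa' column")
        codes = reader.fieldnames[1:]
        cols: dict[str, dict[str, float]] = {c: {} for c in codes}
        for row in reader:
            aa = row["aa"].strip().upper()
            for c in codes:
                cols[c][aa] = float(row[c])
        for c in codes:
            reg.register(PropertyTable(c, cols[c], PROPERTY_SOURCES.get(c, "")))
        return reg


def default_registry() -> PropertyRegistry:
    """The bundled literature-scale registry."""
    ref = resources.files("protriform.data").joinpath("aa_properties.csv")
    with ref.open() as fh:
        return PropertyRegistry.from_csv(fh)


_DEFAULT: PropertyRegistry | None = None


def _registry(reg: PropertyRegistry | None) -> PropertyRegistry:
    global _DEFAULT
    if reg is not None:
        return reg
    if _DEFAULT is None:
        _DEFAULT = default_registry()
    return _DEFAULT


def property_vector(sequence: str, code: str,
                    registry: PropertyRegistry | None = None,
                    *, minmax: bool = False) -> np.ndarray:
    """Per-residue property values for ``sequence`` (1-letter codes).

    ``code == "1"`` yields the identity (all-ones) vector.  ``minmax``
    rescales the 20-value table to [0, 1] before lookup (off by default:
    properties are used raw).
    """
    if code == IDENTITY_CODE:
        return np.ones(len(sequence))
    table = _registry(registry).get(code)
    vals = dict(table.values)
    if minmax:
        lo = min(vals.values())
        hi = max(vals.values())
        span = hi - lo or 1.0
        vals = {aa: (v - lo) / span for aa, v in vals.items()}
    out = np.empty(len(sequence))
    for i, aa in enumerate(sequence):
        if aa not in vals:
            raise NonCanonicalResidueError(
                f"non-canonical residue {aa!r} at position {i + 1}")
        out[i] = vals[aa]
    return out


@dataclass(frozen=True)
class MacroVectors:
    """The three contraction vectors [X], [Y], [P] plus their provenance."""

    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    form_type: str
    property_codes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.x)

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.p)):
            raise ValueError("macro-vectors must share one length")
        if self.form_type not in FORM_TYPES:
            raise ValueError(f"unknown form type {self.form_type!r}")


def macro_vectors(sequence: str, form_type: str, codes,
                  registry: PropertyRegistry | None = None,
                  *, minmax: bool = False) -> MacroVectors:
    """Populate [X], [Y], [P] for a form type from property codes."""
    codes = tuple(codes)
    if form_type not in FORM_TYPES:
        raise ValueError(f"unknown form type {form_type!r}; "
                         f"expected one of {FORM_TYPES}")
    arity = FORM_ARITY[form_type]
    if len(codes) != arity:
        raise ValueError(f"form {form_type} needs {arity} property code(s), "
                         f"got {len(codes)}: {codes}")
    pv = lambda c: property_vector(sequence, c, registry, minmax=minmax)
    ones = np.ones(len(sequence))
    if form_type == "Tr":
        if len(set(codes)) != 3:
            raise ValueError(f"Tr form needs 3 distinct properties, got {codes}")
        x, y, p = (pv(c) for c in codes)
    elif form_type == "TrL":
        x, y, p = pv(codes[0]), ones, ones
    elif form_type == "TrB":
        v = pv(codes[0])
        x, y, p = v, v.copy(), ones
    elif form_type == "TrQB":
        v = pv(codes[0])
        x, y, p = v, v.copy(), pv(codes[1])
    else:  # TrC
        v = pv(codes[0])
        x, y, p = v, v.copy(), v.copy()
    return MacroVectors(x=x, y=y, p=p, form_type=form_type,
                        property_codes=codes)


# --- amino-acid groups -------------------------------------------------------

@dataclass(frozen=True)
class GroupDefinition:
    code: str
    members: frozenset[str]
    description: str = ""


def _g(code: str, aas: str, desc: str) -> GroupDefinition:
    return GroupDefinition(code, frozenset(aas), desc)


#: Residue groups for group-filtered (local) descriptors.  ``T`` is the
#: total group (every residue).
GROUPS: dict[str, GroupDefinition] = {g.code: g for g in [
    _g("FAH", "ACLMEQHK", "alpha-helix favouring"),
    _g("FBS", "VIFYWT", "beta-sheet favouring"),
    _g("UFG", "GP", "unfolding"),
    _g("AFT", "GSDNP", "beta-turn favouring"),
    _g("ALG", "GAPVLIM", "aliphatic"),
    _g("ARO", "FYW", "aromatic"),
    _g("RPC", "KHR", "polar positively charged"),
    _g("RNC", "DE", "polar negatively charged"),
    _g("RAP", "PIAVLFWM", "apolar"),
    _g("RPU", "NCGSTYQ", "polar uncharged"),
    _g("T", CANONICAL, "total (all residues)"),
]}


def group_indices(sequence: str, group: str | GroupDefinition) -> tuple[int, ...]:
    """1-based positions of residues belonging to ``group``."""
    if isinstance(group, str):
        try:
            group = GROUPS[group]
        except KeyError:
            raise KeyError(f"unknown group code {group!r}; "
                           f"known: {sorted(GROUPS)}") from None
    return tuple(i + 1 for i, aa in enumerate(sequence) if aa in group.members)
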