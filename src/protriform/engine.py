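"""Descriptor configurations, the code-string grammar, and batch computation.

A fully specified descriptor is serialized as an underscore-separated code,
read positionally:

    REP _ INV1 [_ INV2] _ FORM _ MM(Mm) _ NORMk _ FLAG [_ GROUP]
        [_ OPAQUE ...] _ PROPS _ MCoMPAs

with ``REP`` the residue representation (CA/CB/AB/AVG); one or two
aggregation invariants (windowed ones carry ``[w]``); ``FORM`` the trilinear
form type (Tr, TrL — also written TrF — TrB, TrQB, TrC); ``MM`` the
multi-metric ID with its optional duplex metric in parentheses (presence of
the duplex metric makes the tensor *complete*); ``NORMk`` the normalization
and Hadamard power fused into one token (e.g. ``NS1``, ``SS-2``, ``MP7``);
``FLAG`` the reference mode (``o`` = mass-center based, ``T`` = amino-acid
based); an optional residue group; any opaque legacy tokens carried
verbatim; and the hyphen-joined property codes.  Example::

    AVG_Q1_TrC_M58(M15)_SS0_T_KA_PAH_MCoMPAs

The full pipeline for one descriptor is: build tensor -> Hadamard power ->
normalization -> trilinear LAI -> group filter -> aggregation.  Everything
is deterministic; batch computation never aborts on a bad cell.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .aggregators import (AggregationContext, EmptyGroupError, InvariantSpec,
                          UndefinedInvariantError, aggregate, filter_group)
from .forms import compute_lai, trilinear
from .metrics import UnknownMetricError, get_duplex, get_multi
from .properties import (FORM_ARITY, GROUPS, PropertyRegistry,
                         default_registry, group_indices, macro_vectors)
from .structure_io import (REPRESENTATIONS, ProteinGeometry, derive_geometry,
                           parse_pdb)
from .tensor import (NORMALIZATIONS, TDSM, apply_normalization, build_tdsm,
                     hadamard_power)

logger = logging.getLogger(__name__)

SUFFIX = "MCoMPAs"
FORM_TOKENS = ("Tr", "TrL", "TrB", "TrQB", "TrC", "TrF")
#: legacy alias: TrF codes denote the trilinear-linear form
FORM_ALIASES = {"TrF": "TrL"}
#: token fragments that identify bilinear/quadratic legacy descriptors,
#: which are outside the trilinear engine
BILINEAR_FORM_TOKENS = ("B", "Q")
BILINEAR_PREFIXES = ("LGP[", "LGL[")

_MM_RE = re.compile(r"^(M\d+)(?:\((M\d+)\))?$")
_NORM_RE = re.compile(r"^(NS|SS|MP)(-?\d+(?:\.\d+)?)$")


class DescriptorCodeError(ValueError):
    """A descriptor code failed to parse; the message names the token."""


class OutOfScopeError(DescriptorCodeError):
    """The code uses bilinear-only tokens outside this engine's scope."""


@dataclass(frozen=True)
class MissingValue:
    """Explicit marker for an undefined descriptor cell."""

    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"NA({self.reason})"


@dataclass(frozen=True)
class DescriptorConfig:
    representation: str
    invariants: tuple[InvariantSpec, ...]
    form_token: str
    multi_metric: str
    duplex_metric: str | None
    normalization: str
    k: float
    reference_token: str  # 'o' (mass-center) | 'T' (amino-acid based)
    group: str = "T"
    group_explicit: bool = False
    opaque: tuple[str, ...] = ()
    properties: tuple[str, ...] = ()
    suffix: str = SUFFIX
    two_stage: bool = False

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise DescriptorCodeError(
                f"unknown representation {self.representation!r}")
        if not 1 <= len(self.invariants) <= 2:
            raise DescriptorCodeError("need one or two invariants")
        if self.form_token not in FORM_TOKENS:
            raise DescriptorCodeError(f"unknown form type {self.form_token!r}")
        get_multi(self.multi_metric)
        if self.duplex_metric is not None:
            get_duplex(self.duplex_metric)
        if self.normalization not in NORMALIZATIONS:
            raise DescriptorCodeError(
                f"unknown normalization {self.normalization!r}")
        if not -12.0 <= self.k <= 12.0:
            raise DescriptorCodeError(f"power k={self.k} outside [-12, 12]")
        if self.reference_token not in ("o", "T"):
            raise DescriptorCodeError(
                f"unknown reference flag {self.reference_token!r}")
        if self.group not in GROUPS:
            raise DescriptorCodeError(f"unknown group {self.group!r}")
        arity = FORM_ARITY[self.form_type]
        if len(self.properties) != arity:
            raise DescriptorCodeError(
                f"form {self.form_token} needs {arity} property code(s), "
                f"got {self.properties}")

    @property
    def form_type(self) -> str:
        return FORM_ALIASES.get(self.form_token, self.form_token)

    @property
    def reference_mode(self) -> str:
        return "center" if self.reference_token == "o" else "aa"

    @property
    def completeness(self) -> str:
        return "complete" if self.duplex_metric is not None else "non-complete"


def _is_invariant(token: str) -> bool:
    try:
        InvariantSpec.from_token(token)
        return True
    except ValueError:
        return False


def parse_code(code: str,
               registry: PropertyRegistry | None = None) -> DescriptorConfig:
    """Parse a descriptor code string into a configuration."""
    tokens = code.split("_")
    for t in tokens:
        if t.startswith(BILINEAR_PREFIXES):
            raise OutOfScopeError(
                f"token {t!r}: bilinear local-fragment descriptors are "
                "outside the trilinear engine")
    if len(tokens) < 6:
        raise DescriptorCodeError(f"too few tokens in {code!r}")
    if tokens[-1] != SUFFIX:
        raise DescriptorCodeError(
            f"code must end in the {SUFFIX!r} suffix, got {tokens[-1]!r}")

    def fail(i: int, what: str):
        raise DescriptorCodeError(
            f"token {i + 1} ({tokens[i]!r}): {what}")

    idx = 0
    rep = tokens[idx]
    if rep not in REPRESENTATIONS:
        fail(idx, f"unknown representation; expected one of {REPRESENTATIONS}")
    idx += 1

    invariants: list[InvariantSpec] = []
    while idx < len(tokens) - 1 and len(invariants) < 2 \
            and _is_invariant(tokens[idx]):
        invariants.append(InvariantSpec.from_token(tokens[idx]))
        idx += 1
    if not invariants:
        fail(idx, "expected an aggregation invariant")

    form = tokens[idx]
    if form in BILINEAR_FORM_TOKENS:
        raise OutOfScopeError(
            f"token {form!r}: bilinear/quadratic forms are outside the "
            "trilinear engine")
    if form not in FORM_TOKENS:
        fail(idx, f"unknown form type; expected one of {FORM_TOKENS}")
    idx += 1

    m = _MM_RE.match(tokens[idx])
    if not m:
        fail(idx, "expected a multi-metric token like M59 or M59(M1)")
    mm_id, metric_id = m.group(1), m.group(2)
    try:
        get_multi(mm_id)
    except UnknownMetricError as exc:
        fail(idx, str(exc))
    if metric_id is not None:
        try:
            get_duplex(metric_id)
        except UnknownMetricError as exc:
            fail(idx, str(exc))
    idx += 1

    m = _NORM_RE.match(tokens[idx])
    if not m:
        fail(idx, "expected a normalization+power token like NS1 or SS-2")
    norm, k = m.group(1), float(m.group(2))
    idx += 1

    flag = tokens[idx]
    if flag not in ("o", "T"):
        fail(idx, "expected the reference flag 'o' or 'T'")
    idx += 1

    group, group_explicit = "T", False
    if idx < len(tokens) - 2 and tokens[idx] in GROUPS:
        group, group_explicit = tokens[idx], True
        idx += 1

    rest = tokens[idx:-1]
    if not rest:
        raise DescriptorCodeError(f"missing property token in {code!r}")
    props_token = rest[-1]
    opaque = tuple(rest[:-1])
    if opaque:
        logger.warning("opaque tokens carried verbatim: %s", opaque)
    reg = registry if registry is not None else default_registry()
    props = tuple(props_token.split("-"))
    for p in props:
        if p not in reg:
            raise DescriptorCodeError(
                f"unknown property code {p!r} in token {props_token!r}")
    return DescriptorConfig(
        representation=rep, invariants=tuple(invariants), form_token=form,
        multi_metric=mm_id, duplex_metric=metric_id, normalization=norm,
        k=k, reference_token=flag, group=group, group_explicit=group_explicit,
        opaque=opaque, properties=props)


def _fmt_k(k: float) -> str:
    return str(int(k)) if float(k).is_integer() else repr(k)


def format_code(c: DescriptorConfig) -> str:
    """Canonical serialization; inverse of :func:`parse_code`."""
    mm = c.multi_metric
    if c.duplex_metric is not None:
        mm = f"{mm}({c.duplex_metric})"
    tokens = [c.representation]
    tokens += [inv.token() for inv in c.invariants]
    tokens += [c.form_token, mm, f"{c.normalization}{_fmt_k(c.k)}",
               c.reference_token]
    if c.group_explicit:
        tokens.append(c.group)
    tokens += list(c.opaque)
    tokens.append("-".join(c.properties))
    tokens.append(c.suffix)
    return "_".join(tokens)


# --------------------------------------------------------------------------
# single-descriptor computation
# --------------------------------------------------------------------------

def build_config_tensor(g: ProteinGeometry, c: DescriptorConfig) -> TDSM:
    """The raw (NS, k=1) tensor a configuration asks for."""
    return build_tdsm(g, c.multi_metric, c.duplex_metric,
                      completeness=c.completeness,
                      reference_mode=c.reference_mode)


def compute_descriptor(g: ProteinGeometry, c: DescriptorConfig,
                       registry: PropertyRegistry | None = None,
                       base_tensor: TDSM | None = None):
    """Run the full pipeline for one descriptor; float or MissingValue.

    ``base_tensor`` may supply a pre-built raw tensor for the config's
    recipe (callers batching many configs share it); it must match the
    config's representation/metric/completeness/reference fields.
    """
    if g.representation != c.representation:
        raise ValueError(
            f"geometry is {g.representation}, config wants {c.representation}")
    t = base_tensor if base_tensor is not None else build_config_tensor(g, c)
    t = hadamard_power(t, c.k)
    t = apply_normalization(t, c.normalization)
    v = macro_vectors(g.sequence, c.form_type, c.properties, registry)
    lai = compute_lai(t, v, provenance=c)
    try:
        idx = group_indices(g.sequence, c.group)
        vals = filter_group(lai.values, idx)
        ctx = AggregationContext(geometry=g, positions=tuple(idx))
        if c.two_stage and len(c.invariants) == 2:
            first, second = c.invariants
            w = first.w
            if w > len(vals):
                raise UndefinedInvariantError(
                    f"window {w} exceeds {len(vals)} group residues")
            stage1 = np.array([
                aggregate(vals[s:s + w], replace(first, window=None)
                          if first.window is not None else first, ctx)
                for s in range(len(vals) - w + 1)])
            return float(aggregate(stage1, second, ctx))
        return float(aggregate(vals, c.invariants[0], ctx))
    except (EmptyGroupError, UndefinedInvariantError) as exc:
        logger.warning("descriptor %s undefined: %s", format_code(c), exc)
        return MissingValue(str(exc))


# --------------------------------------------------------------------------
# projects and batch matrices
# --------------------------------------------------------------------------

_EXPAND_FIELDS = ("representation", "invariants", "form", "multi_metric",
                  "duplex_metric", "normalization", "k", "reference",
                  "group", "properties")


def _listify(x) -> list:
    if x is None:
        return [None]
    if isinstance(x, (list, tuple)):
        return list(x)
    return [x]


def _config_from_fields(rep, inv, form, mm, metric, norm, k, refflag,
                        group, props) -> DescriptorConfig:
    inv_tokens = inv.split("_") if isinstance(inv, str) else list(inv)
    props_t = tuple(props.split("-")) if isinstance(props, str) else tuple(props)
    group = group or "T"
    return DescriptorConfig(
        representation=rep,
        invariants=tuple(InvariantSpec.from_token(t) for t in inv_tokens),
        form_token=form, multi_metric=mm, duplex_metric=metric,
        normalization=norm, k=float(k), reference_token=refflag,
        group=group, group_explicit=(group != "T"), properties=props_t)


def expand_project(project: dict,
                   registry: PropertyRegistry | None = None
                   ) -> list[DescriptorConfig]:
    """Expand a project mapping into an ordered list of configurations.

    A project holds explicit ``descriptors`` (code strings) and/or
    ``expand`` blocks whose list-valued fields are crossed Cartesianly.
    """
    configs: list[DescriptorConfig] = []
    for code in project.get("descriptors", []) or []:
        configs.append(parse_code(code, registry))
    for block in project.get("expand", []) or []:
        unknown = set(block) - set(_EXPAND_FIELDS)
        if unknown:
            raise ValueError(f"unknown project fields: {sorted(unknown)}")
        axes = [_listify(block.get(f)) for f in _EXPAND_FIELDS]
        defaults = {"representation": "CA", "invariants": "N1", "form": "TrL",
                    "multi_metric": "M59", "normalization": "NS", "k": 1,
                    "reference": "T", "properties": "PAH"}
        for f, ax in zip(_EXPAND_FIELDS, axes):
            if ax == [None] and f in defaults:
                ax[0] = defaults[f]
        for combo in itertools.product(*axes):
            configs.append(_config_from_fields(*combo))
    if not configs:
        raise ValueError("project defines no descriptors")
    return configs


def load_project(path) -> dict:
    import yaml
    with open(path) as fh:
        project = yaml.safe_load(fh)
    if not isinstance(project, dict):
        raise ValueError("project file must hold a mapping")
    return project


@dataclass
class DescriptorMatrix:
    """Structures x descriptor-codes matrix of computed values."""

    row_ids: list[str]
    columns: list[str]
    cells: list[list[float | MissingValue]]
    provenance: dict = field(default_factory=dict)

    def to_csv(self, path=None) -> str:
        lines = [f"# protriform {self.provenance.get('engine', __version__)}",
                 f"# properties {self.provenance.get('properties', 'bundled')}"]
        header = ",".join(["structure"] + [_csv_quote(c) for c in self.columns])
        lines.append(header)
        for rid, row in zip(self.row_ids, self.cells):
            cells = [_csv_quote(rid)]
            for v in row:
                cells.append("NA" if isinstance(v, MissingValue)
                             else f"{v:.12g}")
            lines.append(",".join(cells))
        text = "\r\n".join(lines) + "\r\n"
        if path is not None:
            with open(path, "w", newline="") as fh:
                fh.write(text)
        return text


def _csv_quote(s: str) -> str:
    if any(ch in s for ch in ',"\r\n'):
        return '"' + s.replace('"', '""') + '"'
    return s


def compute_matrix(structures, project,
                   registry: PropertyRegistry | None = None,
                   out_csv=None) -> DescriptorMatrix:
    """Batch-compute a descriptor matrix over PDB files.

    ``structures`` is a list of PDB paths; ``project`` a mapping or a YAML
    path.  Per-cell failures become explicit NA markers; unreadable
    structures flag the whole row; the batch never aborts.
    """
    if not isinstance(project, dict):
        project = load_project(project)
    reg = registry if registry is not None else default_registry()
    configs = expand_project(project, reg)
    columns = [format_code(c) for c in configs]

    row_ids: list[str] = []
    cells: list[list[float | MissingValue]] = []
    reasons: list[tuple[str, str, str]] = []
    for path in structures:
        import os
        rid = os.path.splitext(os.path.basename(str(path)))[0]
        row_ids.append(rid)
        try:
            with open(path) as fh:
                raw = parse_pdb(fh.read())
        except (OSError, ValueError) as exc:
            logger.warning("structure %s unreadable: %s", path, exc)
            row = [MissingValue(f"unreadable structure: {exc}")] * len(configs)
            cells.append(row)
            reasons.extend((rid, col, f"unreadable structure: {exc}")
                           for col in columns)
            continue
        geoms: dict[str, ProteinGeometry] = {}
        tensors: dict[tuple, TDSM] = {}
        row = []
        for c, col in zip(configs, columns):
            try:
                if c.representation not in geoms:
                    geoms[c.representation] = derive_geometry(
                        raw, c.representation)
                g = geoms[c.representation]
                tkey = (c.representation, c.multi_metric, c.duplex_metric,
                        c.completeness, c.reference_mode)
                if tkey not in tensors:
                    tensors[tkey] = build_config_tensor(g, c)
                val = compute_descriptor(g, c, reg, base_tensor=tensors[tkey])
            except (ValueError, ArithmeticError) as exc:
                logger.warning("cell (%s, %s) failed: %s", rid, col, exc)
                val = MissingValue(str(exc))
            if isinstance(val, MissingValue):
                reasons.append((rid, col, val.reason))
            row.append(val)
        cells.append(row)
        logger.info("computed %d descriptors for %s", len(configs), rid)

    mat = DescriptorMatrix(
        row_ids=row_ids, columns=columns, cells=cells,
        provenance={"engine": __version__,
                    "properties": "bundled:" + "/".join(reg.codes())})
    if out_csv is not None:
        mat.to_csv(out_csv)
        with open(str(out_csv) + ".log", "w") as fh:
            for rid, col, why in reasons:
                fh.write(f"{rid}\t{col}\t{why}\n")
    return mat
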