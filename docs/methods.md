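# Methods

This note records how `protriform` defines its model, the conventions chosen
where the design was genuinely open, and what the test battery does and does
not establish. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Model and pipeline

A structure is reduced to one point per residue (a *representation*), a
ternary measure over residue triples fills an order-3 tensor, the tensor is
powered and normalized, contracted with per-residue property vectors into a
per-residue index vector (LAI), and an aggregation operator fuses the LAI
into one scalar. The pipeline order is fixed and load-bearing:

    build tensor -> Hadamard power -> normalization -> LAI -> group filter -> aggregate

Power-before-normalization matters because the two operations do not
commute (dividing by slice sums changes the base the power would act on);
the engine applies the power to the raw non-stochastic tensor and
normalizes the result, and a test asserts the two orders genuinely differ.

## Representations

* **CA** — the alpha carbon; the classical coarse-grained choice.
* **CB** — the beta carbon, a side-chain-aware single point. Glycine (and
  any residue with a missing CB) falls back to the alpha carbon; dropping
  such residues would silently change n and shift every downstream index.
* **AB** — interpreted as the backbone carbonyl carbon (PDB atom name
  `C`). The alternative reading (backbone amide nitrogen) is defensible;
  the carbonyl-carbon convention is documented here and applied uniformly.
* **AVG** — the unweighted mean of the residue's heavy-atom coordinates.
  Hydrogens are excluded because deposited crystal structures mostly lack
  them; including them when present would make the representation depend on
  refinement protocol rather than structure.

The protein **mass center** is the atomic-mass-weighted centroid over all
heavy atoms (masses from gemmi's element table); a flag switches to the
unweighted centroid. Multi-chain files are concatenated in file order into
a single residue sequence; chain boundaries are retained so that
sequence-topological distances treat cross-chain pairs as infinitely
separated (their ADD-RULE terms vanish). Residues keep file order even with
insertion codes.

## Tensor conventions

* **Completeness.** A tensor is *complete* when repeated-index entries
  (i,i,l) carry the duplex metric between the two distinct residues and
  *non-complete* when they are 0. In descriptor codes, completeness is
  implied by the presence of the duplex-metric token: `M59(M1)` is
  complete, `M59` alone is non-complete.
* **Reference mode.** Amino-acid-based tensors have a zero diagonal.
  Mass-center-based tensors measure the repeated residue against the
  protein mass center, so every repeated-index entry — including the
  diagonal — becomes non-zero. Fully distinct triples are identical in
  both modes (the minimal interpretation consistent with a non-zero
  diagonal). Center mode therefore needs a duplex metric even for
  non-complete tensors.
* **Bond angle** (and other coordinate-only measures) can run without any
  duplex metric; repeated-index entries are then 0 even in complete mode,
  since no two-point measure exists to fill them.
* **Hadamard powers.** Zero entries are fixed points of every power,
  including k = 0 and negative k (0^0 := 0, 0^(-k) := 0). This preserves
  the sparsity semantics of non-complete tensors — a structurally absent
  relationship must not become 1 or infinity. Non-integer powers of
  tensors with negative entries (possible under correlation-type measures)
  raise a domain error rather than producing complex values.
* **Normalizations.** SS divides each first-index slice by its own sum
  (per-residue probability semantics: slice i describes residue i's
  relational distribution); a slice summing to zero is left unchanged with
  a warning. MP divides by the grand total; an all-zero tensor is a hard
  error. Both require non-stochastic input — renormalizing a normalized
  tensor is rejected.
* **Storage.** Tensors are dense float64; n = 400 (512 MB) is the guardrail
  beyond which an explicit override is required.

## Multi-metric registry

The 22 ternary measures carry consecutive even/odd ID pairs M33–M76
treated as aliases of one formula; the even/odd distinction in the original
numbering is presumed to encode a configuration variant, so the engine
controls reference mode by an explicit flag instead. Conventions worth
recording:

* Asymmetric (A-flagged) measures read (X, Y, Z) as the residues at tensor
  positions (i, j, l) in that order; the tensor is then genuinely
  asymmetric, which the trilinear form supports.
* MIN-RULE implements min(d_XZ, d_YZ); JOIN-RULE returns the middle of the
  three sides (ties return the shared value); Summation Sides is
  d_XY + d_YZ exactly as tabulated (two sides, not the perimeter);
  GEO-RULE is the cubic power mean of the sides despite its name.
* WAR-RULE reads d_XC̄XY as the distance from X to the centroid of the
  pair (X, Y); centroid distances use the active duplex metric so the rule
  stays consistent with the side distances.
* MAH-RULE is the WAR combination under the Mahalanobis metric of the
  triple's own 3x3 coordinate covariance. Three centered points span at
  most rank 2, so that covariance is always singular; the spectrum is
  regularized by adding 1e-8 to every eigenvalue. The regularized distance
  is evaluated through the eigendecomposition (projection per
  eigendirection) rather than a matrix inverse: the 1/1e-8 amplification
  then only touches the numerically tiny null-space projection, which
  keeps the rule rigid-motion invariant to ~1e-11 instead of ~1e-7.
* Agreement coefficients (IC/AC/PC/LC) operate on the three coordinate
  triples as 3-vectors with population covariances; zero-variance
  degeneracies set the affected correlation terms to 0 with a logged
  warning. PC-RULE normalizes each pair's term by
  A_ij = sqrt(Σ U_i² · Σ U_j²) inside both the numerator and denominator
  sums.
* Topological distance p = |i − j| in sequence positions (infinite across
  chain breaks, whose ADD-RULE terms drop out).

Duplex metrics are registered as odd/even alias pairs M1–M16 in the order
Euclidean, Manhattan, Chebyshev, Minkowski(p, default 3), Canberra,
wave-edge (Wave–Hedges), Soergel, Lance–Williams. The last four are
textbook-defined on non-negative data; on signed Cartesian coordinates they
use absolute-value forms (e.g. Canberra terms |u−v|/(|u|+|v|)) so they stay
finite, non-negative, symmetric, and zero exactly at coincident points.

## Properties, forms, groups

The bundled table maps the engine's property codes to standard literature
scales: PAH/PBS (Chou–Fasman helix/sheet propensities), ISA/ECI
(Collantes–Dunn isotropic surface area and electronic charge index), KDS
(Kyte–Doolittle hydropathy), HWS (Hopp–Woods hydrophilicity), MM (average
side-chain mass), and Z3 (a third z-scale-style electronic property;
values rounded). The engine is table-agnostic — any CSV with header
`aa,code1,code2,…` can replace it — because descriptor semantics must not
depend on one scale edition. Values are used raw; min–max scaling exists
behind a flag but is off by default.

Residue groups (helix/sheet-favouring, unfolding, turn-favouring,
aliphatic, aromatic, charged/polar classes, and the total group T) restrict
the LAI before aggregation; an empty selection makes the descriptor
undefined (explicit NA), not zero. The four polarity classes partition all
20 residues disjointly.

## Aggregation operators

N1 is plain summation — it reproduces the total trilinear index exactly,
which is the engine's central cross-module identity (asserted to 1e-9
relative). Conventions for operators whose exact historical formulas are
not fixed by the code-string vocabulary alone:

* Moments are population moments; kurtosis is Pearson (non-excess);
  quantiles use linear interpolation. Single-element vectors return 0 for
  V/SD/CV/S/K with a warning.
* G and A (geometric/harmonic means) are undefined on non-positive entries
  and raise, surfacing as NA cells; KH guards with |v_i·v_{i+1}| + 1e-12.
* AC(w) = Σ v_i·v_{i+w} / (m−w); TS(w) sums sliding windows of length w
  (w = 1 degenerates to N1); GV(w) sums v_a·v_b / d² over residue pairs
  within sequence window w, with d the Euclidean distance between their
  representation points.
* Information contents bin values after rounding to 1e-4 (configurable
  constant), then MIC is the Shannon entropy (bits), TIC = m·MIC,
  SIC = MIC / log2 m.
* Each of these is a documented convention version-pinned in one place, so
  an exact match to another formula edition is a table swap, not a code
  change.

Descriptor codes may stack two invariant tokens (e.g. `TS[7]_N1`). Both are
parsed and round-tripped; by default only the first is applied. An optional
two-stage mode (first invariant over sliding windows, second over the
window results) sits behind `DescriptorConfig.two_stage`.

## Code-string grammar

Tokens are positional:
`REP _ INV1 [_ INV2] _ FORM _ MM(Mm) _ NORMk _ FLAG [_ GROUP] [_ OPAQUE…] _ PROPS _ MCoMPAs`.
`TrF` is accepted as an alias of the trilinear-linear form. The flag maps
`o` to mass-center reference and `T` to amino-acid reference; a following
group token is optional (absent group ≡ total group, and serialization
preserves whether it was explicit, so observed codes round-trip
byte-identically). Unrecognized legacy tokens (e.g. `KA`) are carried
verbatim with a warning and do not affect computation. Codes containing
bilinear/quadratic-only vocabulary (`B`/`Q` form tokens, `LGP[`/`LGL[`
fragments) are rejected with an out-of-scope diagnostic naming the token —
bilinear two-tuple descriptors are a different engine.

## Synthetic fixtures and what the tests show

The generator emits a self-avoiding random walk of alpha carbons at the
canonical 3.8 Å virtual-bond spacing (clash cutoff 3.2 Å), with idealized
backbone atoms and a three-atom side-chain blob rotated per residue by the
golden angle — enough to make CA/CB/AB/AVG mutually distinct and all
derivable. It is deterministic per seed; fixtures for n ∈ {5, 12, 30} are
shipped and a test regenerates them bit-identically.

These peptides emulate the *geometry plumbing* of real proteins (chain
connectivity, realistic inter-residue distance scales, distinct
representations), not their physics: no secondary structure, no
Ramachandran validity, no rotamers, no packing. Passing tests therefore
establish that the algebra — tensor assembly, powers, normalizations,
decomposition, contraction, aggregation, serialization — is implemented
exactly as defined, for any point cloud; they say nothing about predictive
performance on real structures, which depends on external datasets and
modelling machinery outside this package's scope.

The oracle suite recomputes every stage with naive per-entry loops straight
from the definitions (capped at n ≤ 8), and the engine is checked against
it across the full grid of 4 representations × 8 multi-metrics (all four
families) × completeness × reference mode × k ∈ {−2, 0, 1, 2} ×
{NS, SS, MP} × 5 form types — 7680 pipeline states per peptide — at 1e-9
relative tolerance. Problem sizes throughout (n ∈ {5, 8} for the oracle
grid, n ≤ 20 for decomposition checks, n ∈ {12, 30} for batch determinism)
are chosen as the smallest sizes that exercise every code path, keeping
the whole battery at desk scale.

## Numerical notes

* The LAI is streamed: with slot sums A, B, C (one contraction per index
  position), the entry weight m/3 for m matching indices gives
  LAI = (A+B+C)/3 in one O(n³) pass; equivalence to the materialized
  per-residue tensors is a standing test at 1e-12 (scaled).
* Heron's formula is clamped at 0 under the square root, so collinear
  triples give area (and incircle area) exactly 0 instead of NaN.
* Bond angle cosines are clipped to [−1, 1]; a zero-length side is an
  undefined-angle error.
* CSV output uses 12 significant digits, CRLF line endings, `NA` for
  undefined cells, and a provenance header; reruns are byte-identical
  because nothing in the pipeline draws randomness or reads clocks.

## Known limitations

* mmCIF input, hydrogen handling, missing-residue reconstruction and
  NMR-ensemble averaging are out of scope; only the first MODEL is read.
* The supplementary formula sheet of the original software is not public;
  duplex-metric ID numbering and the classical-invariant formulas follow
  the documented conventions above and may differ token-for-token from
  that software.
* Sparse tensors, distance cutoffs and four-tuple measures are not
  implemented; dense n³ storage bounds practical protein size.
* "Volume" and "Dihedral Angle" ternary measures are named in the source
  vocabulary but have no published formula and are deliberately absent.
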