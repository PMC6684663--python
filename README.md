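# protriform

Trilinear tensor-algebraic 3D descriptors for protein structures.

`protriform` turns a PDB structure into numeric features for QSAR/QSPR-style
modelling (folding-rate regression, structural-class prediction, residue-level
analysis). Instead of the usual pairwise contact or distance matrices, it
encodes *ternary* spatial relationships: for every triple of residues
(i, j, l) it evaluates a configurable three-point measure (triangle area,
bond angle, linkage rules, agreement coefficients, …), assembles the values
into an order-3 tensor, and contracts that tensor with amino-acid
physicochemical property vectors.

## The model

A protein with *n* residues is reduced to one pseudo-vertex per residue under
a chosen **representation**: Cα, Cβ (falling back to Cα for glycine), the
backbone carbonyl carbon (AB), or the mean of all heavy atoms (AVG).

The **three-tuple (dis)similarity tensor** Z ∈ ℝ^(n×n×n) holds

- `z_ijl = T_ijl` — a ternary *multi-metric* of the three residue points,
  when i, j, l are pairwise distinct;
- `z_ijl = D_ijl` — the companion *duplex metric* (Euclidean, Manhattan,
  Minkowski, Canberra, wave-edge, Soergel, Lance–Williams, Chebyshev) between
  the two distinct residues, when exactly two indices coincide (*complete*
  tensors; *non-complete* tensors set these entries to 0);
- on the diagonal, 0 (amino-acid reference) or the distance from residue i to
  the protein mass center (mass-center reference).

The raw tensor is raised to an element-wise **Hadamard power** k ∈ [−12, 12]
(negative k takes reciprocals on the non-zero support; k = −1, −2 mimic
gravitational/Coulomb-like decay) and optionally normalized: **SS** (simple
stochastic — each first-index slice divided by its sum) or **MP** (mutual
probability — the grand total scaled to 1).

The **trilinear form** contracts the tensor with three length-n
*macro-molecular vectors* [X], [Y], [P] of per-residue property values:

    L = Σᵢ Σⱼ Σₗ  z_ijl · xⁱ · yʲ · pˡ

Form types fix how the vectors are populated: `Tr` (three distinct
properties), `TrL` (one property, two identity vectors), `TrB` (one property
twice + identity), `TrQB` (one property twice + a second), `TrC` (the same
property three times). Splitting the tensor per residue with weights
1, 2/3, 1/3, 0 by index-match count yields the **LAI** (Local Amino Acidic
Invariant) — a length-n vector of residue contributions that sums *exactly*
to L. Aggregation operators (Minkowski norms, power means, statistical
moments, order statistics, autocorrelation, information contents, …) fuse
the LAI — optionally restricted to a residue group such as aromatic or
helix-favouring — into one scalar descriptor.

Every fully specified descriptor serializes as a code string, e.g.

    AVG_Q1_TrC_M58(M15)_SS0_T_KA_PAH_MCoMPAs

(AVG representation, Q1 = 25th percentile of the LAI, cubic form on the
helix-propensity scale PAH, ADD-RULE multi-metric M58 with Lance–Williams
duplex metric M15, simple-stochastic normalization at k = 0, amino-acid
reference).

## Worked example

```python
import protriform as pf
from protriform.fixtures import PeptideSpec, synthetic_peptide

raw = synthetic_peptide(PeptideSpec(n=12, seed=7))   # sequence MGYVEMWTRPAR
g = pf.derive_geometry(raw, "CB")

t = pf.build_tdsm(g, "M59", "M1")                    # SUM-RULE + Euclidean
t = pf.normalize_ss(pf.hadamard_power(t, -2))        # k = -2, then SS
mv = pf.macro_vectors(g.sequence, "TrC", ["PAH"])    # cubic form, PAH scale
lai = pf.compute_lai(t, mv)

print([round(float(x), 6) for x in lai.values[:4]])
print(round(pf.aggregate(lai.values, "N1"), 6))      # additive total
print(round(pf.aggregate(lai.values, "Q1"), 6))      # 25th percentile
```

prints

```
[1.130273, 0.529572, 0.656352, 1.05713]
14.012282
0.768301
```

The first line is the per-residue LAI head: each entry is that residue's
additive share of the whole-protein trilinear index under the inverse-square
(Coulomb-like) stochastic tensor. `N1` recovers the additive total (the sum
of all twelve LAI entries); `Q1` is the alternative aggregation used by the
equivalent one-shot descriptor

```python
c = pf.parse_code("CB_Q1_TrC_M59(M1)_SS-2_T_PAH_MCoMPAs")
pf.compute_descriptor(g, c)                          # -> 0.7683010585230664
```

Batch computation over a directory of PDB files uses the CLI:

```sh
protriform fixtures make --n 12 --seed 7 --out toy.pdb
protriform describe "AVG_Q1_TrC_M58(M15)_SS0_T_KA_PAH_MCoMPAs"
protriform compute --pdb-dir structures/ --project project.yml --out matrix.csv
protriform list-multimetrics
```

A project YAML lists explicit descriptor codes and/or Cartesian `expand`
blocks; the output CSV carries one row per structure, one column per
descriptor code, 12 significant digits, with undefined cells marked `NA`
and a sidecar `.log` naming the reason.

## Layout

- `src/protriform/structure_io.py` — PDB parsing (via gemmi), residue
  representations, mass center, representation-file TSV round-trip
- `src/protriform/properties.py` — property scales, macro-vectors, groups
- `src/protriform/metrics.py` — duplex metrics (M1–M16) and the 22 ternary
  multi-metrics (M33–M76) in four families
- `src/protriform/tensor.py` — tensor assembly, Hadamard powers, SS/MP
  normalizations, amino-acid-level decomposition
- `src/protriform/forms.py` — trilinear contraction and the LAI
- `src/protriform/aggregators.py` — the invariant (aggregation) vocabulary
- `src/protriform/engine.py` — descriptor-code grammar, pipeline, batches
- `src/protriform/fixtures.py` — synthetic peptide generator + brute-force
  oracle suite
- `docs/methods.md` — modelling choices, conventions and limitations
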