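# phylosupport

Tools for interrogating the support for a contested internal branch of a
phylogeny — specifically the branch separating the deuterostome animals
(Chordata + Xenambulacraria) from the protostomes (Lophotrochozoa +
Ecdysozoa) — and for diagnosing whether that support could be a
long-branch-attraction (LBA) artifact of model misspecification.

The package is aimed at molecular phylogeneticists who want desk-scale,
fully scripted versions of the analyses used in phylogenomic studies of
deep animal relationships: stem-branch lengths, likelihood costs of
collapsing a branch, per-gene three-topology tests, and
simulation–reinference experiments, all runnable on synthetic data with no
downloads.

## What it computes

Let `B` be the most recent common ancestor (MRCA) of Bilateria on a tree
rooted with the outgroup clan, and let `D` and `P` be the MRCAs of
Deuterostomia and Protostomia. For an alignment `X` and substitution model
`M`:

* **Stem branch length** — the path length `B→D` (or `B→P`) in expected
  substitutions per site, after ML branch-length optimization on a fixed
  topology.
* **ΔlnL collapse statistic** —
  `ΔlnL = lnL(T | X, M) − lnL(T_collapsed | X, M)`, where `T_collapsed`
  pins the focal stem at zero length (likelihood-equivalent to a polytomy
  for reversible models) and re-optimizes all other branch lengths. Nested
  optimization guarantees `ΔlnL ≥ 0`.
* **Per-gene topology weights** — for the three resolutions of the
  clan-level trichotomy (DM: monophyletic deuterostomes; D1:
  Xenambulacraria sister to Protostomia; D2: Chordata sister to
  Protostomia; analogously PM/P1/P2 for protostomes), each gene's
  optimized log-likelihoods `(lnL₁, lnL₂, lnL₃)` are mapped to likelihood
  weights `wᵢ = exp(lnLᵢ − max) / Σⱼ exp(lnLⱼ − max)` — ternary-plot
  coordinates. A gene supports topology `i` when `wᵢ > 2/3`.
* **LBA experiment** — simulate replicate alignments under DM, D1 and D2
  with a site-heterogeneous profile-mixture model on a tree with long
  outgroup/protostome and short deuterostome branches, then reinfer the
  topology (argmax-lnL among the three candidates) under a matched
  heterogeneous model (Het), a site-homogeneous LG+F+G model (Hom), and
  Hom after removing the longest- (HomNL) or shortest-branch (HomNS) half
  of the protostome+outgroup taxa. The tally of selected topologies
  exposes the artifact: under model violation plus rate heterogeneity,
  paraphyletic-deuterostome data are pulled toward DM.

The likelihood engine is self-contained: LG exchangeabilities, +F
frequencies, discrete-gamma rates (mean-of-category discretization), and
finite profile mixtures (the ML analogue of CAT/C60 site heterogeneity),
with Felsenstein pruning vectorized over mixture components and site
patterns, and coordinate-ascent branch-length optimization using exact
single-edge likelihood curves from the spectral decomposition.

## Worked example

```python
from phylosupport import CladeTreeConfig, make_clade_tree, simulate_alignment
from phylosupport.branch_support import delta_lnl_collapse, measured_stem
from phylosupport.model import SubstitutionModel
from phylosupport.synthetic_data import default_heterogeneous_model

tree, clademap = make_clade_tree(CladeTreeConfig(seed=0))
gen = default_heterogeneous_model(seed=0)          # 10-profile mixture + gamma
aln = simulate_alignment(tree, gen, 5000, seed=1)  # 20 taxa x 5000 sites

hom = SubstitutionModel.lg(gamma_alpha=0.7)        # site-homogeneous LG+G
for name, model in [("LG+G (homogeneous)", hom), ("matched mixture", gen)]:
    print(name)
    for clade in ("Protostomia", "Deuterostomia"):
        delta, res, _ = delta_lnl_collapse(aln, tree, clademap, clade, model)
        stem = measured_stem(res, clademap, clade)
        print(f"  {clade:15s} stem={stem:.4f}  collapse dlnL={delta:8.2f}")
```

prints

```
LG+G (homogeneous)
  Protostomia     stem=0.0277  collapse dlnL=   47.52
  Deuterostomia   stem=0.0301  collapse dlnL=   60.18
matched mixture
  Protostomia     stem=0.0429  collapse dlnL=   18.22
  Deuterostomia   stem=0.0196  collapse dlnL=    6.32
```

The alignment was generated with a protostome stem of 0.05 and a
deuterostome stem of 0.01. Under the misspecified homogeneous model the
contested deuterostome branch looks as long as — and better supported
than — the protostome branch (its length is inflated threefold); under
the matched site-heterogeneous model the estimates move back toward the
truth and protostome support dominates. This is the model-misspecification
effect the package is built to dissect: poorly fitting site-homogeneous
models manufacture support for the short contested branch.

A command-line interface mirrors the library
(`phylosupport simulate|branch-support|topotest|lba-run|cv|report`); see
`phylosupport --help`.

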