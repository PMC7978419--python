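# Methods

## Substitution model

All likelihood computations use reversible amino-acid models built from a
symmetric exchangeability matrix `S` (the LG matrix, embedded as
constants) and one or more equilibrium-frequency profiles `π`. Each
profile defines `Q_ij = S_ij π_j` (i ≠ j), with the diagonal set so rows
sum to zero and the matrix rescaled so the expected rate at stationarity,
`−Σᵢ πᵢ Q_ii`, is 1; branch lengths are therefore expected substitutions
per site under that profile.

Site heterogeneity enters in two ways:

* **Rates**: discrete-gamma with shape `α` and `K` equal-weight
  categories; category rates are the conditional means of the
  Gamma(α, 1/α) quantile bins (mean-of-category discretization),
  renormalized to mean exactly 1. Default `K = 4`.
* **Profiles**: a finite mixture of `K_p` frequency profiles with weights
  on the simplex. `K_p = 1` recovers the classical site-homogeneous +F
  model; larger libraries are the maximum-likelihood analogue of the
  Bayesian CAT and the fixed C60 site-heterogeneity models. Mixing is at
  the site level: the per-site likelihood is the weight-average over
  profiles (and the equal-weight average over rate categories).

Missing data (`-`, `X`) contribute all-ones partial vectors — the
standard missing-at-random treatment.

### Likelihood engine

Felsenstein pruning is vectorized over mixture components (profile × rate
category) and over compressed site patterns. Transition matrices come from
the symmetric spectral decomposition of each profile's rate matrix
(`diag(√π) Q diag(1/√π)` is symmetric), which gives
`P(t) = S⁻¹U e^{Λt} Uᵀ S` and, importantly, an exact closed form for the
likelihood of the data as a function of a *single* edge length:
`L_site(t) = Σ_l g_l h_l e^{λ_l t}`, where `g, h` are the eigenbasis
projections of the conditional likelihoods on the two sides of the edge.

Branch lengths are optimized by coordinate ascent over edges. The tree is
traversed depth-first; the conditional likelihood of everything outside
the current subtree is propagated top-down (using the reverse transition
`P_ji`, required by reversibility), subtree conditionals are recombined on
the way back up, so every single-edge optimization sees exactly current
partials and the total lnL is non-decreasing. Each edge maximizes the
closed-form curve by safeguarded Newton (analytic first and second
derivatives) with a bounded-Brent fallback; flat or monotone-decreasing
curves resolve to the lower bound. Bounds are [1e-8, 20]
substitutions/site. A pass-level convergence tolerance of 1e-4 nats
(default) or the caller's choice stops the sweeps; edges that moved less
than 1e-5 in the previous pass are skipped, with a full sweep every third
pass to prevent premature convergence. Numerical underflow is handled by
per-node rescaling with log accumulation on the bottom-up path; the
top-down path is left unscaled, which is safe for the tens-of-taxa trees
this package targets (float64 underflows only beyond hundreds of taxa) —
the edge curves need only relative lnL values.

### Model fitting

`fit_model` implements a three-rung ladder: `LG` (single profile, +F
frequencies, single rate), `LG+G` (adds gamma), `MIX+LG+G` (profile
library + gamma). +F frequencies are observed proportions with a
pseudocount of 1 and are not iterated. For the mixture, the +F profile is
appended to the supplied library so each rung properly nests the previous
one. The gamma shape is fit by bounded search on log α ∈ [log 0.05,
log 20]; mixture weights by EM (concave in the weights, tolerance 1e-6
nats) at fixed branch lengths; branch lengths, α and weights alternate in
outer iterations until the joint lnL improves by less than the outer
tolerance. The fitted lnL is non-decreasing across outer iterations.

### Simulation

The forward simulator draws, per site, a profile by weight and a rate
category uniformly, draws the root state from the profile, and evolves
states down every edge with `exp(Q t · rate)`, vectorized over sites.
Everything is deterministic given the seed; replicate `r` of an
experiment uses `base_seed + r` within its topology block.

## Synthetic data generator

The generator emulates the statistical regime of the published bilaterian
phylogenomic supermatrices, not any particular taxon sample:

* **Five clans** (Outgroup, Lophotrochozoa, Ecdysozoa, Chordata,
  Xenambulacraria), default 4 taxa each (a 36-taxon preset mirrors the
  taxon-reduced matrices used for the simulation studies).
* **Focal stems**: deuterostome-side stem `d = 0.01`, protostome stem
  `p = 0.05` — the "very short contested branch next to a longer
  well-supported branch" contrast. Generating topology DM places them as
  ((L,E):p, (C,X):d); D1/D2 nest the protostomes beside Xenambulacraria
  or Chordata with `d` subtending the pair.
* **Depth contrast**: within-clan subtrees are random-coalescent shaped,
  scaled to base depth 0.9 × clan multiplier (Outgroup 1.2, protostome
  clans 1.0, deuterostome clans 0.35): long outgroup and protostome
  branches against short deuterostome branches, the precondition for LBA.
* **Within-clan rate spread**: terminal branches are jittered by
  lognormal factors with σ = 0.5, giving a ~3.6-fold spread between fast
  and slow taxa of a clan. This matches the fast/slow contrast within the
  empirical protostome and outgroup samples (fast flatworms and
  gastrotrichs against slow molluscs and annelids) and is what makes
  "remove the longest/shortest half" experiments meaningful: the removed
  and retained halves genuinely differ in rate. Larger spreads (σ ≈ 1)
  were considered and rejected — they imply >10-fold ratios and
  saturated tips outside the empirical range.
* **Profiles**: site profiles drawn from a symmetric Dirichlet(0.2) —
  sparse, CAT-like; default library size 10; gamma shape 0.7.
* **Gene sets**: lognormal lengths (median 300, minimum 50), lognormal
  per-gene rate multipliers, per-gene uniform taxon deletion to the
  configured occupancy (default 0.8) while never emptying a clan when
  avoidable.

What the generator does **not** emulate: real amino-acid composition of
particular lineages, structured (non-uniform) missingness, indels, or
among-gene linked models. Passing tests on this data therefore show the
statistics and the artifact mechanism behave correctly in a controlled
regime; they are not evidence about any particular empirical matrix.

## Clade statistics

Trees are treated as rooted data structures; for clan statistics the tree
is (re)rooted on the edge separating the outgroup clan. All quantities
are measured from the Bilateria MRCA and are invariant to the exact root
position along the outgroup path. Stem lengths are path sums from the
Bilateria MRCA to the clade MRCA; a clade left unresolved in a polytomy
(as after collapsing its stem) is accepted when every child subtree of
the MRCA is entirely inside or outside the clade, while genuine intruders
raise an error naming them. Collapse is implemented by pinning the stem
at the optimizer's lower bound and re-optimizing all other branch
lengths, which is likelihood-equivalent to a true multifurcation for
reversible models.

Per-gene analyses crop the *reference* topology to each gene's taxa
(degree-2 nodes fused, path lengths preserved) rather than inferring
per-gene topologies; genes need ≥ 2 taxa in each focal clan-union and
≥ 1 outgroup taxon for branch-support rows, and ≥ 1 taxon per clan for
three-topology tests (otherwise the hypotheses are indistinguishable
after cropping). The monophyly score of an inferred gene tree is the
fraction of reference clades, restricted to taxa present with ≥ 2
present, that appear as unrooted splits. Likelihood weights use the
normalized-exponential (softmax) construction — shift-invariant,
order-preserving, summing to 1 — with strict `> 2/3` classification and
boundary cases unresolved.

## LBA experiment

For each generating topology the experiment simulates `n_replicates`
alignments and reinfers each by a constrained choice: optimize branch
lengths on the three clan-level hypothesis trees (within-clan topology
fixed to truth; the two rearranged scaffold edges initialized at 0.05)
and select the argmax lnL, ties (< 1e-6 nats) resolving to DM < D1 < D2
with a logged flag. A full tree search is deliberately out of scope: the
scientific question is which of three resolutions wins.

Conditions: **Het** uses the generating mixture model unchanged (the
matched-model control; optional weight re-fitting is available);
**Hom** uses LG+F+G with per-replicate observed frequencies and a
re-estimated gamma shape; **HomNL** / **HomNS** first remove the
longest- / shortest-branch half of the protostome+outgroup taxa (ranked
by distance from the Bilateria MRCA on the generating tree, ties by
name, never emptying a clan) from both alignments and hypothesis trees.
Within a condition, each replicate's optimization warm-starts from the
previous replicate's optimized lengths — the optimum is unchanged, only
passes are saved.

Cross-validation of the model ladder samples disjoint train/test site
sets per fold, fits each model on the training sites and scores the test
sites at the fitted parameters, reporting per-model mean ± SD held-out
lnL.

## Scale and statistical power

Default experiment scale is 20 replicates × 2,000 sites × 20 taxa per
generating topology (configurable up to the published scale of 100 ×
50,000 × 36). This choice keeps the full suite around ten minutes on one
CPU. It has a real statistical consequence: the expected number of
substitutions on the contested stem is `d × n_sites = 20`, of which only
a fraction survive the long terminal branches as observable signal, so
the three-topology lnL margins are typically 1–5 nats — against which
replicate-to-replicate sampling noise produces occasional flips in every
condition. At the published scale the margins are ~25× larger and the
recovery outcomes are deterministic (100%). Desk-scale recovery
percentages should therefore be read as noisy estimates of the artifact's
direction and strength, not as exact reproductions of the deterministic
large-sample outcomes; the direction (paraphyletic data pulled toward DM
under model violation, corrected by longest-branch removal, exaggerated
by shortest-branch removal) is the scientifically meaningful content.

## Known limitations

* No MCMC or posterior sampling; the Bayesian infinite mixture is
  represented by its finite-mixture ML analogue throughout.
* Reinference is constrained to the three clan-level resolutions, not a
  full topology search.
* The gene-tree inference used for monophyly scores is a light
  NJ + NNI hill-climber, adequate for small gene alignments only.
* Branch-length coordinate ascent can need many passes on trees with
  strongly correlated adjacent short edges; the convergence flag on
  results reports this honestly.
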