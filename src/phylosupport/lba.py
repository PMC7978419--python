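"""Long-branch-attraction simulation experiments and model cross-validation.

The core experiment: simulate replicate alignments under each of the three
clan-level topologies (DM, D1, D2) with a site-heterogeneous mixture model
on a tree with long outgroup/protostome and short deuterostome branches,
then reinfer the topology by constrained three-way likelihood comparison
under four conditions —

* ``Het``:  the matched site-heterogeneous mixture model, full taxon set;
* ``Hom``:  a site-homogeneous LG+F+G model (the model violation);
* ``HomNL``: LG+F+G after removing the longest-branch protostome and
  outgroup taxa (reducing LBA);
* ``HomNS``: LG+F+G after removing the shortest-branch protostome and
  outgroup taxa (enhancing LBA) —

and tally which topology wins.  Under model violation plus branch-length
heterogeneity, data generated under paraphyletic-deuterostome topologies
are expected to be misassigned to DM (the LBA artifact), never to the other
paraphyly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .alignment import Alignment
from .likelihood import (SubstitutionModel, compute_lnl, fit_gamma_shape,
                         fit_model, optimize_branch_lengths,
                         simulate_alignment)
from .model import observed_frequencies
from .synthetic_data import (CladeTreeConfig, GENERATING_TOPOLOGIES,
                             default_heterogeneous_model, make_clade_tree)
from .topology_tests import HypothesisSet, hypothesis_trees
from .treeops import CladeMap, root_to_tip_lengths, tip_labels

logger = logging.getLogger(__name__)

CONDITIONS = ("Het", "Hom", "HomNL", "HomNS")
TIE_TOL = 1e-6


class LbaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topology selection

@dataclass
class Selection:
    """Outcome of a constrained three-topology reinference."""

    label: str
    lnls: dict[str, float]
    tie: bool = False
    trees: dict | None = None


def select_topology(aln: Alignment, hypotheses: HypothesisSet,
                    model: SubstitutionModel,
                    tol: float = 1e-3, max_passes: int = 15,
                    warm: dict | None = None) -> Selection:
    """Argmax-lnL choice among the three hypothesis trees.

    Branch lengths are optimized independently on each hypothesis; ties
    (|ΔlnL| < 1e-6) resolve to the earliest label in the set's fixed order
    and are flagged.  ``warm`` optionally maps labels to same-topology trees
    whose lengths seed the optimizer (the optimum does not depend on the
    start point; this only saves passes).
    """
    lnls = {}
    trees = {}
    for label in hypotheses.labels:
        start = warm[label] if warm and label in warm else hypotheses[label]
        res = optimize_branch_lengths(aln, start, model,
                                      tol=tol, max_passes=max_passes)
        lnls[label] = res.lnl
        trees[label] = res.tree
    best = max(hypotheses.labels, key=lambda lab: lnls[lab])
    tie = any(lab != best and abs(lnls[lab] - lnls[best]) < TIE_TOL
              for lab in hypotheses.labels)
    if tie:
        best = next(lab for lab in hypotheses.labels
                    if abs(lnls[lab] - lnls[best]) < TIE_TOL)
        logger.info("topology selection tie; resolved to %s by label order", best)
    return Selection(best, lnls, tie, trees)


# ---------------------------------------------------------------------------
# taxon removal

def taxon_removal_sets(tree: dendropy.Tree, clademap: CladeMap, k: int,
                       mode: str = "longest") -> set[str]:
    """The k longest- or shortest-branch protostome and outgroup taxa.

    Taxa are ranked by distance from the Bilateria MRCA (outgroup taxa by
    distance to the same node); ties break by taxon name.  A taxon is
    skipped (and the next rank taken) if removing it would empty a clan.
    """
    if mode not in ("longest", "shortest"):
        raise LbaError(f"mode must be longest|shortest, got {mode!r}")
    pool = (clademap.protostomia | clademap.outgroup) & tip_labels(tree)
    if k > len(pool) - 2:
        raise LbaError(f"k={k} too large for {len(pool)} protostome+outgroup taxa")
    if k < 0:
        raise LbaError("k must be nonnegative")
    depths = root_to_tip_lengths(tree, clademap, reference="Bilateria")
    reverse = mode == "longest"
    ranked = sorted(pool, key=lambda t: ((-depths[t]) if reverse else depths[t], t))
    removed: set[str] = set()
    remaining = {clan: set(taxa) & tip_labels(tree)
                 for clan, taxa in clademap.clans.items()}
    for taxon in ranked:
        if len(removed) == k:
            break
        clan = clademap.clan_of(taxon)
        if clan is not None and len(remaining[clan]) <= 1:
            continue  # never empty a clan when avoidable
        removed.add(taxon)
        if clan is not None:
            remaining[clan].discard(taxon)
    if len(removed) < k:
        raise LbaError(f"could only remove {len(removed)} of {k} taxa "
                       "without emptying a clan")
    return removed


# ---------------------------------------------------------------------------
# experiment configuration and tally

@dataclass
class LbaConfig:
    """Configuration of the simulation-reinference experiment.

    Defaults are the desk-scale study conditions: 20 replicates of 2,000
    sites on the default 20-taxon clan tree, generating model a 10-profile
    Dirichlet(0.2) mixture with gamma shape 0.7, replicate seeds
    ``base_seed + 100 * topology_index + r``.
    """

    generating_topologies: tuple = GENERATING_TOPOLOGIES
    n_replicates: int = 20
    n_sites: int = 2000
    tree_config: CladeTreeConfig = field(default_factory=CladeTreeConfig)
    model: SubstitutionModel | None = None
    conditions: tuple = CONDITIONS
    removal_k: int | None = None
    base_seed: int = 100
    het_refit_weights: bool = False
    opt_tol: float = 1e-3
    opt_max_passes: int = 15

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise LbaError("need at least one replicate")
        if not self.conditions:
            raise LbaError("need at least one reinference condition")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise LbaError(f"unknown conditions: {sorted(unknown)}")
        unknown = set(self.generating_topologies) - set(GENERATING_TOPOLOGIES)
        if unknown:
            raise LbaError(f"unknown generating topologies: {sorted(unknown)}")

    def replicate_seed(self, topology: str, r: int) -> int:
        return self.base_seed + 100 * GENERATING_TOPOLOGIES.index(topology) + r


@dataclass
class RecoveryTally:
    """counts[generating][condition][selected] with conservation invariant."""

    counts: dict
    n_replicates: int
    log: pd.DataFrame

    def check_conservation(self) -> None:
        for gen, by_cond in self.counts.items():
            for cond, by_sel in by_cond.items():
                total = sum(by_sel.values())
                if total != self.n_replicates:
                    raise LbaError(
                        f"tally row ({gen}, {cond}) sums to {total}, "
                        f"expected {self.n_replicates}")

    def percent(self, generating: str, condition: str, selected: str) -> float:
        row = self.counts[generating][condition]
        return 100.0 * row.get(selected, 0) / max(sum(row.values()), 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gen, by_cond in self.counts.items():
            for cond, by_sel in by_cond.items():
                row = {"generating": gen, "condition": cond}
                for lab in GENERATING_TOPOLOGIES:
                    row[f"n_{lab}"] = by_sel.get(lab, 0)
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-condition reinference models

def homogeneous_model(aln: Alignment, start_tree: dendropy.Tree,
                      tol: float = 0.5, max_passes: int = 5,
                      ) -> SubstitutionModel:
    """LG+F+G with +F from the alignment and gamma shape re-estimated."""
    freqs = observed_frequencies(aln.residue_counts())
    model = SubstitutionModel.lg(gamma_alpha=1.0, frequencies=freqs)
    res = optimize_branch_lengths(aln, start_tree, model,
                                  tol=tol, max_passes=max_passes)
    return fit_gamma_shape(aln, res.tree, model).with_(name="LG+F+G")


def run_lba_experiment(config: LbaConfig) -> RecoveryTally:
    """Simulate -> reinfer -> tally topology recovery for every condition."""
    model = config.model or default_heterogeneous_model(
        seed=config.tree_config.seed)
    counts: dict = {}
    log_rows = []

    # reference hypotheses come from the DM variant of the same tree config;
    # within-clan subtrees are seed-determined and thus shared with truth
    ref_tree, clademap = make_clade_tree(
        replace(config.tree_config, generating_topology="DM"))
    hypotheses = hypothesis_trees(ref_tree, clademap, focus="deuterostome")
    pool = clademap.protostomia | clademap.outgroup
    k = config.removal_k if config.removal_k is not None else len(pool) // 2

    removal_conditions = [c for c in config.conditions if c in ("HomNL", "HomNS")]

    for topo in config.generating_topologies:
        gen_tree, _ = make_clade_tree(
            replace(config.tree_config, generating_topology=topo))
        removals = {}
        for cond in removal_conditions:
            mode = "longest" if cond == "HomNL" else "shortest"
            removals[cond] = taxon_removal_sets(gen_tree, clademap, k, mode)
        counts[topo] = {cond: {} for cond in config.conditions}
        warm_cache: dict = {}
        for r in range(config.n_replicates):
            seed = config.replicate_seed(topo, r)
            aln = simulate_alignment(gen_tree, model, config.n_sites,
                                     seed=seed, name=f"{topo}_rep{r}")
            for cond in config.conditions:
                try:
                    sel = _reinfer(aln, hypotheses, model, cond,
                                   removals.get(cond), config,
                                   warm=warm_cache.get(cond))
                    warm_cache[cond] = sel.trees
                except Exception as exc:  # keep the tally going
                    logger.error("replicate %s/%s/%s failed: %s",
                                 topo, cond, r, exc)
                    counts[topo][cond]["failed"] = \
                        counts[topo][cond].get("failed", 0) + 1
                    continue
                counts[topo][cond][sel.label] = \
                    counts[topo][cond].get(sel.label, 0) + 1
                row = {"generating": topo, "condition": cond, "replicate": r,
                       "seed": seed, "selected": sel.label, "tie": sel.tie}
                row.update({f"lnl_{lab}": sel.lnls[lab]
                            for lab in hypotheses.labels})
                log_rows.append(row)
    tally = RecoveryTally(counts=counts, n_replicates=config.n_replicates,
                          log=pd.DataFrame(log_rows))
    tally.check_conservation()
    return tally


def _reinfer(aln: Alignment, hypotheses: HypothesisSet,
             gen_model: SubstitutionModel, condition: str,
             removal: set | None, config: LbaConfig,
             warm: dict | None = None) -> Selection:
    if condition == "Het":
        model = gen_model
        hyp = hypotheses
        if config.het_refit_weights:
            from .likelihood import _fit_weights

            start = optimize_branch_lengths(
                aln, hyp[hyp.labels[0]], model,
                tol=config.opt_tol, max_passes=config.opt_max_passes)
            model = _fit_weights(aln, start.tree, model)
    else:
        if removal is not None:
            keep = aln.taxon_set() - removal
            aln = aln.subset_taxa(keep)
            hyp = hypotheses.cropped(keep)
        else:
            hyp = hypotheses
        start = warm[hyp.labels[0]] if warm else hyp[hyp.labels[0]]
        model = homogeneous_model(aln, start)
    return select_topology(aln, hyp, model, warm=warm,
                           tol=config.opt_tol, max_passes=config.opt_max_passes)


# ---------------------------------------------------------------------------
# cross-validation

def cross_validation(aln: Alignment, topology: dendropy.Tree,
                     ladder=("LG", "LG+G", "MIX+LG+G"),
                     profile_library: np.ndarray | None = None,
                     n_folds: int = 10, n_train: int | None = None,
                     n_test: int | None = None, seed: int = 0,
                     train_fraction: float = 0.8) -> pd.DataFrame:
    """Site-subsampling cross-validation of the model ladder.

    Per fold, disjoint train and test site sets are drawn; each model is fit
    on the training sites (branch lengths and free parameters) and scored by
    log-likelihood on the held-out sites at the fitted parameters.  Returns
    per-model mean and SD of the held-out score plus per-fold values.
    """
    if n_train is None:
        n_train = int(aln.n_sites * train_fraction * 0.8)
    if n_test is None:
        n_test = max(1, int(n_train * 0.2))
    if n_train + n_test > aln.n_sites:
        raise LbaError(f"train ({n_train}) + test ({n_test}) sites exceed "
                       f"alignment length {aln.n_sites}")
    rng = np.random.default_rng(seed)
    rows = []
    for fold in range(n_folds):
        sites = rng.permutation(aln.n_sites)
        train = aln.subset_sites(np.sort(sites[:n_train]))
        test = aln.subset_sites(np.sort(sites[n_train:n_train + n_test]))
        for spec in ladder:
            fitted = fit_model(train, topology, spec,
                               profile_library=profile_library)
            score = compute_lnl(test, fitted.tree, fitted.model).lnl
            rows.append({"fold": fold, "model": spec, "heldout_lnl": score})
    frame = pd.DataFrame(rows)
    summary = frame.groupby("model", sort=False)["heldout_lnl"] \
        .agg(["mean", "std"]).reset_index()
    return summary.merge(frame.groupby("model", sort=False)["heldout_lnl"]
                         .apply(list).rename("per_fold"), on="model")
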