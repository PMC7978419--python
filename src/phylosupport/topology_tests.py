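"""Per-gene three-topology likelihood tests and gene-quality contrasts.

For a focal clade (Deuterostomia or Protostomia) the three resolutions of
the clan-level trichotomy are built from a reference tree, each gene is
scored by optimized log-likelihood under all three, and the lnL triple is
mapped to likelihood weights (normalized exponentials) serving as ternary
coordinates.  A gene supports a topology when its weight exceeds 2/3;
otherwise it is unresolved.  Gene informativeness is contrasted between
support classes by alignment length and monophyly score using Welch's t.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment
from .likelihood import (SubstitutionModel, optimize_branch_lengths,
                         pairwise_ml_distance)
from .treeops import (CladeMap, CLAN_NAMES, _clade_node, crop_tree,
                      parse_newick, root_on_outgroup, tip_labels)

logger = logging.getLogger(__name__)

DEUTEROSTOME_LABELS = ("DM", "D1", "D2")
PROTOSTOME_LABELS = ("PM", "P1", "P2")

#: initial length for the rearranged clan-scaffold edges
SCAFFOLD_INIT = 0.05

CLASSIFY_THRESHOLD = 2.0 / 3.0


class TopologyTestError(ValueError):
    pass


@dataclass
class HypothesisSet:
    """Three constraint trees resolving the clan-level trichotomy."""

    labels: tuple[str, str, str]
    trees: dict[str, dendropy.Tree]
    focus: str

    def __post_init__(self) -> None:
        tipsets = {frozenset(tip_labels(t)) for t in self.trees.values()}
        if len(tipsets) != 1:
            raise TopologyTestError("hypothesis trees must share one tip set")

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, label: str) -> dendropy.Tree:
        return self.trees[label]

    def cropped(self, keep) -> "HypothesisSet":
        return HypothesisSet(
            self.labels,
            {lab: crop_tree(t, keep) for lab, t in self.trees.items()},
            self.focus)


def _fragment(node, with_length: bool = True) -> str:
    """Newick fragment for the subtree below ``node``."""
    if node.is_leaf():
        body = node.taxon.label
    else:
        body = "(" + ",".join(_fragment(c) for c in node.child_nodes()) + ")"
    if with_length:
        return f"{body}:{node.edge.length or 0.0:.10g}"
    return body


def hypothesis_trees(reference_tree: dendropy.Tree, clademap: CladeMap,
                     focus: str = "deuterostome") -> HypothesisSet:
    """Build the three clan-level resolutions from a reference tree.

    All within-clan subtrees (topology and lengths) and clan stem lengths
    are preserved; only the two internal scaffold edges joining the four
    clans are rearranged, initialized at 0.05 substitutions/site.  Requires
    all four clans (and the outgroup) monophyletic in the reference.
    """
    if focus not in ("deuterostome", "protostome"):
        raise TopologyTestError(f"focus must be deuterostome|protostome, got {focus!r}")
    rooted = root_on_outgroup(reference_tree, clademap)
    tips = tip_labels(rooted)
    unmapped = tips - set().union(*(clademap.clans[c] for c in clademap.clans))
    if unmapped:
        raise TopologyTestError(
            f"taxa not assigned to any clan: {sorted(unmapped)}")
    frag: dict[str, str] = {}
    stem: dict[str, float] = {}
    for clan in CLAN_NAMES:
        taxa = clademap[clan] & tips
        if not taxa:
            raise TopologyTestError(f"clan {clan} absent from tree")
        node = _clade_node(rooted, taxa, clan)
        frag[clan] = _fragment(node, with_length=False) if not node.is_leaf() \
            else node.taxon.label
        stem[clan] = node.edge.length or 0.0

    out = f"{frag['Outgroup']}:{stem['Outgroup']:.10g}"
    s = SCAFFOLD_INIT
    sub = {c: f"{frag[c]}:{stem[c]:.10g}" for c in CLAN_NAMES}
    L, E, C, X = (sub[c] for c in
                  ("Lophotrochozoa", "Ecdysozoa", "Chordata", "Xenambulacraria"))
    if focus == "deuterostome":
        labels = DEUTEROSTOME_LABELS
        proto = f"({L},{E}):{s}"
        shapes = {
            "DM": f"({proto},({C},{X}):{s})",
            "D1": f"({C},({X},{proto}):{s})",
            "D2": f"({X},({C},{proto}):{s})",
        }
    else:
        labels = PROTOSTOME_LABELS
        deut = f"({C},{X}):{s}"
        shapes = {
            "PM": f"(({L},{E}):{s},{deut})",
            "P1": f"({E},({L},{deut}):{s})",
            "P2": f"({L},({E},{deut}):{s})",
        }
    trees = {lab: parse_newick(f"({out},{shape}:{SCAFFOLD_INIT:.10g});")
             for lab, shape in shapes.items()}
    return HypothesisSet(labels, trees, focus)


def gene_clan_filter(gene: Alignment, clademap: CladeMap) -> str | None:
    """Reason the gene fails the per-clan representation filter, or None.

    Requires >= 1 taxon in each of the four focal clans and >= 1 outgroup
    taxon, so that all three hypothesis trees remain distinguishable after
    cropping.
    """
    taxa = gene.taxon_set()
    for clan in CLAN_NAMES:
        if not clademap[clan] & taxa:
            return f"no taxa of clan {clan}"
    return None


def per_gene_topology_lnls(gene: Alignment, hypotheses: HypothesisSet,
                           model: SubstitutionModel,
                           tol: float = 1e-3, max_passes: int = 8,
                           ) -> np.ndarray:
    """Optimized lnL of the gene under each hypothesis, in label order."""
    keep = gene.taxon_set() & tip_labels(hypotheses[hypotheses.labels[0]])
    cropped = hypotheses.cropped(keep)
    lnls = []
    for label in cropped.labels:
        res = optimize_branch_lengths(gene, cropped[label], model,
                                      tol=tol, max_passes=max_passes)
        lnls.append(res.lnl)
    return np.array(lnls)


# ---------------------------------------------------------------------------
# ternary scaling and classification

@dataclass
class TernaryPoint:
    """Scaled supports for the three topologies (sum to 1)."""

    weights: np.ndarray
    labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (3,) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise TopologyTestError("ternary weights must be 3 values summing to 1")

    @property
    def category(self) -> str:
        return classify_gene(self)


def scale_likelihoods(lnls, labels=DEUTEROSTOME_LABELS) -> TernaryPoint:
    """Likelihood weights: normalized exponentials of lnL differences.

    Shift-invariant (adding a constant to all lnLs changes nothing) and
    order-preserving; the weights lie in [0, 1] and sum to 1, serving as
    ternary-plot coordinates.
    """
    lnls = np.asarray(lnls, dtype=float)
    if lnls.shape != (3,) or not np.all(np.isfinite(lnls)):
        raise TopologyTestError(f"need three finite lnL values, got {lnls}")
    shifted = lnls - lnls.max()
    w = np.exp(shifted)
    return TernaryPoint(w / w.sum(), tuple(labels))


def classify_gene(point: TernaryPoint,
                  threshold: float = CLASSIFY_THRESHOLD) -> str:
    """Label of the unique weight strictly above threshold, else 'unresolved'."""
    idx = np.nonzero(point.weights > threshold)[0]
    if len(idx) == 1:
        return point.labels[int(idx[0])]
    return "unresolved"


def classify_geneset(genes: list[Alignment], hypotheses: HypothesisSet,
                     model: SubstitutionModel, clademap: CladeMap,
                     tol: float = 1e-3, max_passes: int = 8) -> pd.DataFrame:
    """Per-gene lnLs, likelihood weights and support category.

    Genes failing the clan filter are skipped with a logged reason; the
    returned frame has one row per scored gene.
    """
    rows = []
    for gene in genes:
        reason = gene_clan_filter(gene, clademap)
        if reason is not None:
            logger.info("skipping gene %s: %s", gene.name, reason)
            continue
        lnls = per_gene_topology_lnls(gene, hypotheses, model,
                                      tol=tol, max_passes=max_passes)
        point = scale_likelihoods(lnls, hypotheses.labels)
        row = {"gene": gene.name, "n_sites": gene.n_sites,
               "n_taxa": gene.n_taxa}
        for lab, lnl, w in zip(hypotheses.labels, lnls, point.weights):
            row[f"lnl_{lab}"] = lnl
            row[f"w_{lab}"] = w
        row["category"] = classify_gene(point)
        rows.append(row)
    return pd.DataFrame(rows)


def triangle_summary(classified: pd.DataFrame,
                     labels=DEUTEROSTOME_LABELS) -> dict[str, int]:
    """Counts of genes per support category (the triangle-corner tallies)."""
    counts = {lab: 0 for lab in (*labels, "unresolved")}
    if not classified.empty:
        for cat, n in classified["category"].value_counts().items():
            counts[cat] = int(n)
    return counts


# ---------------------------------------------------------------------------
# light gene-tree inference

def _nj_tree(aln: Alignment, model: SubstitutionModel) -> dendropy.Tree:
    """Neighbor-joining start tree from pairwise ML distances."""
    import skbio

    taxa = list(aln.taxon_names)
    n = len(taxa)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_ml_distance(aln, taxa[i], taxa[j], model)
        dm[i, j] = dm[j, i] = d
    nj = skbio.tree.nj(skbio.DistanceMatrix(dm, ids=taxa))
    tree = parse_newick(str(nj))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def _nni_neighbors(tree: dendropy.Tree):
    """Yield trees one nearest-neighbor interchange away (rooted encoding)."""
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        sibs = [c for c in node.parent_node.child_nodes() if c is not node]
        for sib in sibs:
            for kid in kids:
                nbr = tree.clone(depth=1)
                # locate counterparts by object position in preorder
                pairs = dict(zip((id(x) for x in tree.preorder_node_iter()),
                                 nbr.preorder_node_iter()))
                n_node, n_sib, n_kid = pairs[id(node)], pairs[id(sib)], pairs[id(kid)]
                parent = n_node.parent_node
                parent.remove_child(n_sib)
                n_node.remove_child(n_kid)
                parent.add_child(n_kid)
                n_node.add_child(n_sib)
                yield nbr


def infer_gene_tree(aln: Alignment, model: SubstitutionModel,
                    tol: float = 1e-2, max_passes: int = 4,
                    max_rounds: int = 20):
    """ML gene tree: NJ start from ML distances, then NNI hill climbing.

    Accepts the best strictly improving interchange each round until no move
    improves the optimized lnL; deterministic given the input.  Returns
    ``(tree, lnl)``.
    """
    if aln.n_taxa < 4:
        raise TopologyTestError(f"need >= 4 taxa, got {aln.n_taxa}")
    current = _nj_tree(aln, model)
    cur_res = optimize_branch_lengths(aln, current, model,
                                      tol=tol, max_passes=max_passes)
    current, cur_lnl = cur_res.tree, cur_res.lnl
    for _ in range(max_rounds):
        best, best_lnl = None, cur_lnl + 1e-3
        for nbr in _nni_neighbors(current):
            res = optimize_branch_lengths(aln, nbr, model,
                                          tol=tol, max_passes=max_passes)
            if res.lnl > best_lnl:
                best, best_lnl = res.tree, res.lnl
        if best is None:
            break
        current, cur_lnl = best, best_lnl
    return current, cur_lnl


def monophyly_score(tree: dendropy.Tree, reference_clades) -> float | None:
    """Fraction of testable reference clades recovered as unrooted splits.

    A clade is testable when >= 2 of its taxa are in the tree; it is
    recovered when its present taxa form one side of a split.  Returns None
    (score undefined) when no clade is testable.
    """
    tips = tip_labels(tree)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        under = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        splits.add(under)
        splits.add(frozenset(tips - under))
    tested = recovered = 0
    for clade in reference_clades:
        present = frozenset(set(clade) & tips)
        if len(present) < 2:
            continue
        tested += 1
        if present in splits:
            recovered += 1
    if tested == 0:
        return None
    return recovered / tested


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise TopologyTestError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise TopologyTestError("zero variance in both groups")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
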