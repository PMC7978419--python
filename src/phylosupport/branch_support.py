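"""Stem-length and lnL-collapse support statistics for the two focal clades.

Implements the branch-support side of the analysis: how long is the branch
leading to Protostomia or Deuterostomia, and how much does the likelihood
drop when that branch is collapsed into a polytomy — on a concatenated
matrix or gene by gene — plus the per-clan depth averages and the
common-taxon dataset rate used to compare datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .alignment import Alignment, concatenate
from .likelihood import (MIN_BRANCH_LENGTH, LikelihoodResult, SubstitutionModel,
                         optimize_branch_lengths)
from .treeops import (CladeMap, MonophylyError, TreeError, _clade_node,
                      bilateria_mrca, crop_tree, root_on_outgroup, tip_labels)

logger = logging.getLogger(__name__)

#: slack allowed on the nested-optimization inequality delta_lnl >= 0
DELTA_LNL_TOL = 1e-3


@dataclass
class BranchSupportRecord:
    """Support measured for one clade on one unit (dataset or gene)."""

    unit: str
    clade: str
    stem_length: float
    delta_lnl: float


def _stem_path_nodes(rooted_tree: dendropy.Tree, clademap: CladeMap,
                     clade: str) -> list:
    """Head nodes of the edges forming the clade's stem path."""
    broot = bilateria_mrca(rooted_tree, clademap)
    taxa = clademap.group(clade) & tip_labels(rooted_tree)
    cnode = _clade_node(rooted_tree, taxa, clade)
    if cnode is broot:
        raise TreeError(f"{clade!r} MRCA coincides with the Bilateria MRCA")
    nodes = []
    node = cnode
    while node is not broot:
        nodes.append(node)
        node = node.parent_node
    return nodes


def delta_lnl_collapse(aln: Alignment, topology: dendropy.Tree,
                       clademap: CladeMap, clade: str,
                       model: SubstitutionModel,
                       tol: float = 1e-3, max_passes: int = 10,
                       ) -> tuple[float, LikelihoodResult, LikelihoodResult]:
    """Log-likelihood cost of collapsing a clade's stem into a polytomy.

    Both fits start from the topology's given branch lengths: once fully
    resolved, once with the stem pinned at (effectively) zero length and all
    other branch lengths free.  Returns ``(delta_lnl, resolved, collapsed)``.
    Pinning a reversible-model branch at zero is likelihood-equivalent to a
    true multifurcation.
    """
    rooted = root_on_outgroup(topology, clademap)
    stem_nodes = _stem_path_nodes(rooted, clademap, clade)
    resolved = optimize_branch_lengths(aln, rooted, model,
                                       tol=tol, max_passes=max_passes)
    pinned = {node: MIN_BRANCH_LENGTH for node in stem_nodes}
    collapsed = optimize_branch_lengths(aln, rooted, model, fixed_edges=pinned,
                                        tol=tol, max_passes=max_passes)
    return resolved.lnl - collapsed.lnl, resolved, collapsed


def measured_stem(result: LikelihoodResult, clademap: CladeMap,
                  clade: str) -> float:
    """Stem length of a clade on an (already rooted) optimized tree."""
    from .treeops import stem_branch_length

    return stem_branch_length(result.tree, clademap, clade, rooted=True)


def gene_passes_filter(gene: Alignment, clademap: CladeMap) -> str | None:
    """Reason a gene fails the clan-representation filter, or None if it passes.

    Requires >= 2 taxa in each focal clan-union (Protostomia, Deuterostomia)
    and >= 1 outgroup taxon.
    """
    taxa = gene.taxon_set()
    if len(clademap.protostomia & taxa) < 2:
        return "fewer than 2 protostome taxa"
    if len(clademap.deuterostomia & taxa) < 2:
        return "fewer than 2 deuterostome taxa"
    if not clademap.outgroup & taxa:
        return "no outgroup taxon"
    return None


def per_gene_branch_table(genes: list[Alignment],
                          reference_tree: dendropy.Tree,
                          clademap: CladeMap,
                          model: SubstitutionModel,
                          tol: float = 1e-3, max_passes: int = 8,
                          ) -> pd.DataFrame:
    """Per-gene stem lengths and collapse ΔlnL for both focal clades.

    Each gene is analysed on the reference topology cropped to its taxa.
    Genes failing the clan-representation filter are skipped with a logged
    reason.  Rows are sortable by the protostome-minus-deuterostome
    difference, mirroring the per-gene support panels.
    """
    rows = []
    for gene in genes:
        reason = gene_passes_filter(gene, clademap)
        if reason is not None:
            logger.info("skipping gene %s: %s", gene.name, reason)
            continue
        cropped = crop_tree(reference_tree, gene.taxon_set())
        try:
            for clade in ("Protostomia", "Deuterostomia"):
                delta, resolved, _ = delta_lnl_collapse(
                    gene, cropped, clademap, clade, model,
                    tol=tol, max_passes=max_passes)
                rows.append(BranchSupportRecord(
                    unit=gene.name, clade=clade,
                    stem_length=measured_stem(resolved, clademap, clade),
                    delta_lnl=delta))
        except (MonophylyError, TreeError) as exc:
            logger.info("skipping gene %s: %s", gene.name, exc)
            continue
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if frame.empty:
        return pd.DataFrame(columns=["unit", "clade", "stem_length", "delta_lnl"])
    wide = frame.pivot(index="unit", columns="clade", values="stem_length")
    order = (wide["Protostomia"] - wide["Deuterostomia"]).sort_values().index
    frame["unit"] = pd.Categorical(frame["unit"], categories=order, ordered=True)
    return frame.sort_values(["unit", "clade"]).reset_index(drop=True)


def clade_depth_summary(tree: dendropy.Tree, clademap: CladeMap,
                        model_optimized: bool = True) -> pd.DataFrame:
    """Mean root-to-tip distance per clan, measured from the Bilateria MRCA.

    Outgroup taxa are measured to the same node.  Clans with no taxa in the
    tree are omitted with a warning.  Also reports the Protostomia and
    Deuterostomia unions.
    """
    from .treeops import root_to_tip_lengths

    depths = root_to_tip_lengths(tree, clademap, reference="Bilateria")
    rows = []
    groups = list(clademap.clans) + ["Protostomia", "Deuterostomia"]
    for group in groups:
        taxa = sorted(clademap.group(group) & set(depths))
        if not taxa:
            logger.warning("clan %s has no taxa in tree; omitted", group)
            continue
        vals = [depths[t] for t in taxa]
        rows.append({"clan": group, "n_taxa": len(taxa),
                     "mean_depth": float(np.mean(vals))})
    return pd.DataFrame(rows)


def dataset_rate(aln: Alignment, reference_tree: dendropy.Tree,
                 common_taxa, model: SubstitutionModel,
                 tol: float = 1e-3, max_passes: int = 10) -> float:
    """Total tree length on a common-taxon subset (dataset evolutionary rate).

    Crops alignment and reference topology to ``common_taxa``, re-optimizes
    branch lengths under the model and returns the sum of branch lengths in
    expected substitutions per site.
    """
    common = set(common_taxa)
    if len(common) < 4:
        raise TreeError(f"need >= 4 common taxa, got {len(common)}")
    missing = common - (aln.taxon_set() & tip_labels(reference_tree))
    if missing:
        raise TreeError(f"common taxa absent from data: {sorted(missing)}")
    sub_aln = aln.subset_taxa(common)
    sub_tree = crop_tree(reference_tree, common)
    result = optimize_branch_lengths(sub_aln, sub_tree, model,
                                     tol=tol, max_passes=max_passes)
    from .treeops import total_tree_length

    return total_tree_length(result.tree)
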