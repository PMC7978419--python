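"""Newick I/O and topology surgery on dendropy trees.

Trees are plain :class:`dendropy.Tree` objects with branch lengths in
expected substitutions per site.  Clade-level statistics are defined after
rooting the (otherwise unrooted) tree at the midpoint of the edge separating
the outgroup clan from the ingroup.

The :class:`CladeMap` assigns taxa to the five clans structuring all
analyses — Outgroup, Lophotrochozoa, Ecdysozoa, Chordata, Xenambulacraria —
with the derived unions Protostomia (L+E), Deuterostomia (C+X) and Bilateria.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

CLAN_NAMES = ("Outgroup", "Lophotrochozoa", "Ecdysozoa", "Chordata",
              "Xenambulacraria")


class TreeError(ValueError):
    pass


class MonophylyError(TreeError):
    """A clan expected to be monophyletic is not; carries the intruders."""

    def __init__(self, clade: str, intruders):
        self.clade = clade
        self.intruders = sorted(intruders)
        super().__init__(
            f"clade {clade!r} is not monophyletic; intruding taxa: "
            f"{', '.join(self.intruders)}")


# ---------------------------------------------------------------------------
# CladeMap

@dataclass
class CladeMap:
    """Named clans -> taxon sets, with the derived bilaterian unions."""

    clans: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clans = {name: set(taxa) for name, taxa in self.clans.items()}
        seen: dict[str, str] = {}
        for name, taxa in self.clans.items():
            for t in taxa:
                if t in seen:
                    raise TreeError(
                        f"taxon {t!r} assigned to both {seen[t]!r} and {name!r}")
                seen[t] = name

    def __getitem__(self, clan: str) -> set[str]:
        return set(self.clans[clan])

    @property
    def outgroup(self) -> set[str]:
        return set(self.clans.get("Outgroup", set()))

    @property
    def protostomia(self) -> set[str]:
        return self.clans.get("Lophotrochozoa", set()) | self.clans.get("Ecdysozoa", set())

    @property
    def deuterostomia(self) -> set[str]:
        return self.clans.get("Chordata", set()) | self.clans.get("Xenambulacraria", set())

    @property
    def bilateria(self) -> set[str]:
        return self.protostomia | self.deuterostomia

    def group(self, name: str) -> set[str]:
        """Taxa of a clan or derived union (case-sensitive names)."""
        derived = {"Protostomia": self.protostomia,
                   "Deuterostomia": self.deuterostomia,
                   "Bilateria": self.bilateria}
        if name in derived:
            return derived[name]
        if name in self.clans:
            return set(self.clans[name])
        raise TreeError(f"unknown clan or union: {name!r}")

    def clan_of(self, taxon: str) -> str | None:
        for name, taxa in self.clans.items():
            if taxon in taxa:
                return name
        return None

    def restricted(self, taxa) -> "CladeMap":
        taxa = set(taxa)
        return CladeMap({n: s & taxa for n, s in self.clans.items()})

    @classmethod
    def read_tsv(cls, path) -> "CladeMap":
        """Read two-column TSV (taxon <tab> clan); '#' lines are comments."""
        clans: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                taxon, clan = line.split("\t")[:2]
                clans.setdefault(clan, set()).add(taxon)
        return cls(clans)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for clan in sorted(self.clans):
                for taxon in sorted(self.clans[clan]):
                    fh.write(f"{taxon}\t{clan}\n")


# ---------------------------------------------------------------------------
# Newick I/O

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; absent branch lengths become 0 with a warning."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse error: {exc}") from exc
    # treated as a rooted structure throughout; reversible-model
    # likelihoods are invariant to the root position anyway
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dups = {t for t in labels if labels.count(t) > 1}
    if dups:
        raise TreeError(f"duplicate tip labels: {sorted(dups)}")
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
        elif edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    if missing:
        warnings.warn(f"{missing} branch length(s) absent; read as 0",
                      stacklevel=2)
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True,
                          real_value_format_specifier=".10g").strip()


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


# ---------------------------------------------------------------------------
# surgery

def crop_tree(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Restrict to ``keep`` taxa; degree-2 nodes fused with lengths summed."""
    keep = set(keep) & tip_labels(tree)
    if len(keep) < 2:
        raise TreeError(f"cropping would leave {len(keep)} tip(s); need >= 2")
    cropped = tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True)
    # extraction can leave a unifurcating root; fuse it away
    root = cropped.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        cropped.seed_node = child
        child.parent_node = None
        root = child
    cropped.seed_node.edge.length = 0.0
    return cropped


def _clade_node(tree: dendropy.Tree, taxa: set[str], clade_name: str = "clade",
                allow_unresolved: bool = False):
    """MRCA node of ``taxa``; raises MonophylyError if extra tips intrude.

    With ``allow_unresolved`` the clade may sit unresolved in a polytomy:
    every child subtree of the MRCA must still be entirely inside or entirely
    outside the clade (monophyly not contradicted), but the MRCA's leafset
    may be a superset of the clade, as after collapsing the clade's stem.
    """
    present = taxa & tip_labels(tree)
    if not present:
        raise TreeError(f"no taxa of {clade_name!r} present in tree")
    mrca = tree.mrca(taxon_labels=present)
    if mrca is None:
        raise TreeError(f"cannot resolve MRCA of {clade_name!r}")
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if under == present:
        return mrca
    if allow_unresolved:
        intruders = set()
        for child in mrca.child_nodes():
            sub = {leaf.taxon.label for leaf in child.leaf_iter()}
            if sub & present and sub - present:
                intruders |= sub - present
        if not intruders:
            return mrca  # unresolved but compatible with monophyly
        raise MonophylyError(clade_name, intruders)
    raise MonophylyError(clade_name, under - present)


def is_monophyletic(tree: dendropy.Tree, taxa) -> bool:
    try:
        _clade_node(tree, set(taxa))
        return True
    except MonophylyError:
        return False


def root_on_outgroup(tree: dendropy.Tree, clademap: CladeMap) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of the outgroup-ingroup edge."""
    out = clademap.outgroup & tip_labels(tree)
    if not out:
        raise TreeError("no outgroup taxa present in tree")
    rooted = clone(tree)
    ingroup = tip_labels(rooted) - out
    if not ingroup:
        raise TreeError("tree contains only outgroup taxa")
    # find a node whose leafset equals the outgroup or the ingroup
    target = None
    for node in rooted.postorder_node_iter():
        if node.parent_node is None:
            continue
        under = {leaf.taxon.label for leaf in node.leaf_iter()}
        if under == out or under == ingroup:
            target = node
            break
    if target is None:
        raise MonophylyError("Outgroup", _outgroup_intruders(rooted, out))
    edge = target.edge
    length = edge.length or 0.0
    rooted.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0,
                          update_bipartitions=False)
    rooted.seed_node.edge.length = 0.0
    return rooted


def _outgroup_intruders(tree: dendropy.Tree, out: set[str]) -> set[str]:
    try:
        node = tree.mrca(taxon_labels=out)
        under = {leaf.taxon.label for leaf in node.leaf_iter()}
        return under - out
    except Exception:
        return set()


def bilateria_mrca(tree: dendropy.Tree, clademap: CladeMap):
    """MRCA node of all bilaterian taxa on an outgroup-rooted tree."""
    present = clademap.bilateria & tip_labels(tree)
    if len(present) < 2:
        raise TreeError("need >= 2 bilaterian taxa to define the Bilateria MRCA")
    return _clade_node(tree, present, "Bilateria")


def _path_length_up(descendant, ancestor) -> float:
    total = 0.0
    node = descendant
    while node is not ancestor:
        if node.parent_node is None:
            raise TreeError("nodes are not in an ancestor-descendant relation")
        total += node.edge.length or 0.0
        node = node.parent_node
    return total


def stem_branch_length(tree: dendropy.Tree, clademap: CladeMap,
                       clade: str, rooted: bool = False) -> float:
    """Path length from the Bilateria MRCA to a clade's MRCA.

    ``clade`` is a clan name or a derived union ("Protostomia",
    "Deuterostomia", "Chordata", ...).  The tree is rooted internally on the
    outgroup clan unless ``rooted=True`` asserts it already is.
    """
    t = tree if rooted else root_on_outgroup(tree, clademap)
    broot = bilateria_mrca(t, clademap)
    taxa = clademap.group(clade) & tip_labels(t)
    cnode = _clade_node(t, taxa, clade, allow_unresolved=True)
    return _path_length_up(cnode, broot)


def collapse_clade_stem(tree: dendropy.Tree, clademap: CladeMap,
                        clade: str) -> dendropy.Tree:
    """Collapse the stem edge of ``clade`` into a polytomy (rooted copy)."""
    t = root_on_outgroup(tree, clademap)
    broot = bilateria_mrca(t, clademap)
    taxa = clademap.group(clade) & tip_labels(t)
    cnode = _clade_node(t, taxa, clade)
    if cnode is broot:
        raise TreeError(
            f"{clade!r} MRCA coincides with the Bilateria MRCA; nothing to collapse")
    # collapse every edge on the stem path (usually exactly one)
    node = cnode
    while node is not broot:
        parent = node.parent_node
        collapse_edge(t, node.edge)
        node = parent
    return t


def collapse_edge(tree: dendropy.Tree, edge) -> dendropy.Tree:
    """Collapse one internal edge in place, producing a polytomy."""
    if edge.head_node.is_leaf():
        raise TreeError("cannot collapse a terminal edge")
    if edge.head_node.parent_node is None:
        raise TreeError("cannot collapse the root edge")
    edge.collapse()
    return tree


def count_internal_edges(tree: dendropy.Tree) -> int:
    return sum(1 for node in tree.preorder_node_iter()
               if node.parent_node is not None and not node.is_leaf())


def root_to_tip_lengths(tree: dendropy.Tree, clademap: CladeMap,
                        reference: str = "Bilateria") -> dict[str, float]:
    """Distance from a reference MRCA node to every tip, keyed by taxon.

    The default reference is the Bilateria MRCA (outgroup taxa are measured
    to that same node, as in clade-depth comparisons).
    """
    t = root_on_outgroup(tree, clademap)
    if reference == "Bilateria":
        ref = bilateria_mrca(t, clademap)
    else:
        taxa = clademap.group(reference) & tip_labels(t)
        ref = _clade_node(t, taxa, reference)
    # distances on the unrooted node graph from ref
    dist = {ref: 0.0}
    stack = [ref]
    while stack:
        node = stack.pop()
        nbrs = list(node.child_nodes())
        if node.parent_node is not None:
            nbrs.append(node.parent_node)
        for nbr in nbrs:
            if nbr in dist:
                continue
            edge_len = (node.edge.length or 0.0) if nbr is node.parent_node \
                else (nbr.edge.length or 0.0)
            dist[nbr] = dist[node] + edge_len
            stack.append(nbr)
    return {leaf.taxon.label: dist[leaf]
            for leaf in sorted(t.leaf_node_iter(), key=lambda l: l.taxon.label)}


def depth_table(tree: dendropy.Tree, clademap: CladeMap,
                reference: str = "Bilateria"):
    """Per-taxon (taxon, clan, distance) table from the reference MRCA."""
    import pandas as pd

    depths = root_to_tip_lengths(tree, clademap, reference=reference)
    rows = [{"taxon": taxon, "clan": clademap.clan_of(taxon) or "",
             "distance": dist} for taxon, dist in depths.items()]
    return pd.DataFrame(rows)


def tip_to_tip_distances(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """All pairwise path lengths between tips."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum((e.length or 0.0) for e in tree.preorder_edge_iter()
               if e.head_node.parent_node is not None)
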