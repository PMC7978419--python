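"""Synthetic clade-structured trees, profile libraries and multi-gene sets.

The generator emulates the statistical regime of published bilaterian
phylogenomic supermatrices: five clans (Outgroup, Lophotrochozoa, Ecdysozoa,
Chordata, Xenambulacraria), a very short deuterostome stem next to a longer
protostome stem, long outgroup and protostome branches against short
chordate/xenambulacrarian branches, site-heterogeneous amino-acid profiles
and gamma rate variation, and multi-gene sets with variable lengths and
taxon occupancy.  Everything is deterministic given the configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import Alignment
from .likelihood import simulate_alignment
from .model import SubstitutionModel
from .treeops import CladeMap, CLAN_NAMES, parse_newick

GENERATING_TOPOLOGIES = ("DM", "D1", "D2")

#: within-clan depth multipliers emulating the empirical rate contrast:
#: long outgroup and protostome branches, short deuterostome branches
DEFAULT_DEPTH_MULTIPLIERS = {
    "Outgroup": 1.2,
    "Lophotrochozoa": 1.0,
    "Ecdysozoa": 1.0,
    "Chordata": 0.35,
    "Xenambulacraria": 0.35,
}


class SyntheticDataError(ValueError):
    pass


@dataclass
class CladeTreeConfig:
    """Shape of the generated clan tree.

    ``deuterostome_stem`` (d) and ``protostome_stem`` (p) are the two focal
    internal branches; by default d < p, mirroring the empirical contrast of
    a protostome stem about twice the deuterostome stem.  ``generating_topology``
    selects deuterostome monophyly (DM) or one of the two paraphyletic
    resolutions (D1: Xenambulacraria sister to Protostomia; D2: Chordata
    sister to Protostomia).
    """

    taxa_per_clan: int | dict[str, int] = 4
    generating_topology: str = "DM"
    deuterostome_stem: float = 0.01
    protostome_stem: float = 0.05
    base_depth: float = 0.9
    depth_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_MULTIPLIERS))
    clan_stem: float = 0.1
    bilateria_stem: float = 0.15
    outgroup_stem: float = 0.3
    tip_rate_sigma: float = 0.5
    seed: int = 0

    def clan_size(self, clan: str) -> int:
        if isinstance(self.taxa_per_clan, dict):
            return int(self.taxa_per_clan[clan])
        return int(self.taxa_per_clan)


@dataclass
class GeneSetConfig:
    """Per-gene length, rate and occupancy distributions for a gene set."""

    n_genes: int = 200
    median_length: float = 300.0
    length_sigma: float = 0.5
    min_length: int = 50
    rate_sigma: float = 0.4
    occupancy: float = 0.8
    seed: int = 0


def reduced_preset(generating_topology: str = "DM", seed: int = 0) -> CladeTreeConfig:
    """A 36-taxon configuration mirroring taxon-reduced empirical matrices."""
    return CladeTreeConfig(
        taxa_per_clan={"Outgroup": 8, "Lophotrochozoa": 8, "Ecdysozoa": 8,
                       "Chordata": 6, "Xenambulacraria": 6},
        generating_topology=generating_topology, seed=seed)


# ---------------------------------------------------------------------------
# trees

def _coalescent_subtree(labels: list[str], depth: float,
                        rng: np.random.Generator,
                        tip_rate_sigma: float) -> str:
    """Random coalescent-shaped ultrametric subtree, rescaled to ``depth``,
    with lognormal tip-rate jitter; returns a newick fragment."""
    n = len(labels)
    if n == 1:
        length = depth * rng.lognormal(0.0, tip_rate_sigma)
        return f"{labels[0]}:{length:.10g}"
    # sequential coalescence with Exp(k choose 2) waiting times
    heights = {}
    lineages = [(lab, 0.0) for lab in labels]
    frags = {lab: lab for lab in labels}
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (fi, hi), (fj, hj) = lineages[i], lineages[j]
        frag = (f"({frags[fi]}:{t - hi:.10g},{frags[fj]}:{t - hj:.10g})")
        key = f"__{len(frags)}"
        frags[key] = frag
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append((key, t))
    root_key, total = lineages[0]
    # rescale to requested depth
    scale = depth / total
    newick = frags[root_key]
    newick = _scale_newick_lengths(newick, scale)
    # tip-rate jitter on terminal edges
    newick = _jitter_tip_lengths(newick, labels, rng, tip_rate_sigma)
    return newick


def _scale_newick_lengths(fragment: str, scale: float) -> str:
    import re

    def repl(match):
        return f":{float(match.group(1)) * scale:.10g}"

    return re.sub(r":([0-9.eE+-]+)", repl, fragment)


def _jitter_tip_lengths(fragment: str, labels, rng, sigma: float) -> str:
    import re

    if sigma <= 0:
        return fragment
    factors = {lab: rng.lognormal(0.0, sigma) for lab in sorted(labels)}

    def repl(match):
        lab = match.group(1)
        if lab in factors:
            return f"{lab}:{float(match.group(2)) * factors[lab]:.10g}"
        return match.group(0)

    return re.sub(r"([A-Za-z0-9_]+):([0-9.eE+-]+)", repl, fragment)


def make_clade_tree(config: CladeTreeConfig):
    """Generate a clan-structured tree and its CladeMap.

    Returns ``(tree, clademap)``.  The focal short branch (deuterostome-side
    stem ``d``) and the protostome stem ``p`` are placed according to the
    generating topology:

    * DM: ``((L,E):p, (C,X):d)`` beside the outgroup;
    * D1: ``(C, (X, (L,E):p):d)`` — Xenambulacraria sister to Protostomia;
    * D2: ``(X, (C, (L,E):p):d)`` — Chordata sister to Protostomia.
    """
    topo = config.generating_topology
    if topo not in GENERATING_TOPOLOGIES:
        raise SyntheticDataError(
            f"generating topology must be one of {GENERATING_TOPOLOGIES}, got {topo!r}")
    for clan in CLAN_NAMES:
        if config.clan_size(clan) < 2:
            raise SyntheticDataError("need >= 2 taxa per clan (MRCAs undefined)")
    if not (config.deuterostome_stem > 0 and config.protostome_stem > 0):
        raise SyntheticDataError("stem lengths must be positive")

    rng = np.random.default_rng(config.seed)
    clans: dict[str, list[str]] = {}
    prefixes = {"Outgroup": "Out", "Lophotrochozoa": "Lop", "Ecdysozoa": "Ecd",
                "Chordata": "Cho", "Xenambulacraria": "Xen"}
    sub = {}
    for clan in CLAN_NAMES:
        n = config.clan_size(clan)
        labels = [f"{prefixes[clan]}{i + 1}" for i in range(n)]
        clans[clan] = labels
        depth = config.base_depth * config.depth_multipliers.get(clan, 1.0)
        sub[clan] = _coalescent_subtree(labels, depth, rng,
                                        config.tip_rate_sigma)

    d = config.deuterostome_stem
    p = config.protostome_stem
    cs = config.clan_stem
    proto = f"({sub['Lophotrochozoa']}:{cs},{sub['Ecdysozoa']}:{cs}):{p}"
    if topo == "DM":
        bilat = f"({proto},({sub['Chordata']}:{cs},{sub['Xenambulacraria']}:{cs}):{d})"
    elif topo == "D1":
        bilat = f"({sub['Chordata']}:{cs},({sub['Xenambulacraria']}:{cs},{proto}):{d})"
    else:  # D2
        bilat = f"({sub['Xenambulacraria']}:{cs},({sub['Chordata']}:{cs},{proto}):{d})"
    newick = (f"({sub['Outgroup']}:{config.outgroup_stem},"
              f"{bilat}:{config.bilateria_stem});")
    tree = parse_newick(newick)
    clademap = CladeMap({clan: set(labels) for clan, labels in clans.items()})
    return tree, clademap


# ---------------------------------------------------------------------------
# profiles

def make_profile_library(k: int, concentration: float = 0.2,
                         seed: int = 0) -> np.ndarray:
    """K amino-acid frequency profiles from a symmetric Dirichlet.

    A small concentration (default 0.2) yields sparse, CAT-like profiles in
    which a handful of residues dominate each site class.
    """
    if k < 1:
        raise SyntheticDataError(f"need at least one profile, got {k}")
    if not concentration > 0:
        raise SyntheticDataError("concentration must be positive")
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(20, concentration), size=k)
    profiles = np.maximum(profiles, 1e-8)
    return profiles / profiles.sum(axis=1, keepdims=True)


def default_heterogeneous_model(k: int = 10, concentration: float = 0.2,
                                gamma_alpha: float = 0.7,
                                seed: int = 0) -> SubstitutionModel:
    """The default site-heterogeneous generating model (K profiles + gamma)."""
    profiles = make_profile_library(k, concentration, seed)
    return SubstitutionModel.mixture(profiles, gamma_alpha=gamma_alpha)


# ---------------------------------------------------------------------------
# gene sets

def make_geneset(tree, model: SubstitutionModel,
                 config: GeneSetConfig,
                 clademap: CladeMap | None = None) -> list[Alignment]:
    """Simulate a multi-gene set on a tree.

    Per gene: length drawn lognormally around the configured median, a
    lognormal rate multiplier scaling all branch lengths, and random taxon
    deletion to the configured occupancy (when a clade map is given, the
    last taxon of a clan is never deleted if avoidable).
    """
    if not 0 < config.occupancy <= 1:
        raise SyntheticDataError("occupancy must be in (0, 1]")
    rng = np.random.default_rng(config.seed)
    taxa = sorted({leaf.taxon.label for leaf in tree.leaf_node_iter()})
    genes = []
    for g in range(config.n_genes):
        length = max(config.min_length,
                     int(round(rng.lognormal(np.log(config.median_length),
                                             config.length_sigma))))
        rate = rng.lognormal(0.0, config.rate_sigma)
        seed = int(rng.integers(0, 2**31 - 1))
        aln = simulate_alignment(tree, model, length, seed=seed,
                                 rate_multiplier=rate, name=f"gene{g + 1:04d}")
        if config.occupancy < 1:
            keep_mask = rng.random(len(taxa)) < config.occupancy
            keep = {t for t, k in zip(taxa, keep_mask) if k}
            if clademap is not None:
                for clan, members in clademap.clans.items():
                    members = members & set(taxa)
                    if members and not (keep & members):
                        keep.add(sorted(members)[0])
            if len(keep) < 4:
                keep = set(rng.choice(taxa, size=4, replace=False))
            aln = aln.subset_taxa(keep)
        genes.append(aln)
    return genes
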