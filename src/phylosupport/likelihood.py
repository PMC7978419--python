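"""Felsenstein pruning likelihood, branch-length optimization, model fitting
and sequence simulation for site-homogeneous and profile-mixture models.

The engine vectorizes over mixture components (profile x gamma-rate
category) and compressed site patterns.  Transition matrices come from the
symmetric spectral decomposition of each profile's calibrated rate matrix,
which also gives a cheap closed form for single-edge likelihood curves
during coordinate-ascent branch optimization.  Underflow is handled by
per-node rescaling with log accumulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .alphabet import MISSING, N_STATES
from .model import ModelError, SubstitutionModel, observed_frequencies
from .treeops import clone, tip_labels

logger = logging.getLogger(__name__)

#: bounds for optimized branch lengths (expected substitutions/site)
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0

MODEL_LADDER = ("LG", "LG+G", "MIX+LG+G")


class LikelihoodError(ValueError):
    pass


@dataclass
class LikelihoodResult:
    """Outcome of a likelihood computation or fit."""

    lnl: float
    tree: dendropy.Tree
    model: SubstitutionModel
    per_site_lnl: np.ndarray | None = None
    converged: bool = True
    n_passes: int = 0

    def __repr__(self) -> str:  # keep tree out of the repr
        return (f"LikelihoodResult(lnl={self.lnl:.4f}, "
                f"model={self.model.name or 'custom'}, "
                f"converged={self.converged})")


# ---------------------------------------------------------------------------
# engine

class EdgeCurve:
    """Single-edge log-likelihood curve lnL(t) from the spectral projection.

    ``lnL(t) = sum_s w_s log(exp(lam * t) @ m[:, s])`` up to an additive
    constant (the accumulated scaling terms, irrelevant for optimization).
    Offers a safeguarded Newton maximizer with a bounded-Brent fallback.
    """

    def __init__(self, lam: np.ndarray, m: np.ndarray, weights: np.ndarray):
        self.lam = lam
        self.lam_sq = lam * lam
        self.m = m
        self.weights = weights
        self._rows = np.empty((3, len(lam)))

    def lnl(self, t: float) -> float:
        lik = np.exp(self.lam * t) @ self.m
        if (lik <= 0).any():
            return -np.inf
        return float(np.log(lik) @ self.weights)

    def _value_grad_hess(self, t: float):
        rows = self._rows
        np.exp(self.lam * t, out=rows[0])
        np.multiply(self.lam, rows[0], out=rows[1])
        np.multiply(self.lam_sq, rows[0], out=rows[2])
        lik, d1, d2 = rows @ self.m
        if (lik <= 0).any():
            return -np.inf, 0.0, 0.0
        r = d1 / lik
        value = float(np.log(lik) @ self.weights)
        grad = float(r @ self.weights)
        hess = float((d2 / lik - r * r) @ self.weights)
        return value, grad, hess

    def maximize(self, t0: float, max_iter: int = 12, xtol: float = 1e-7) -> float:
        t = float(np.clip(t0, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH))
        value, grad, hess = self._value_grad_hess(t)
        for _ in range(max_iter):
            if not np.isfinite(value) or hess >= 0:
                return self._brent()
            step = -grad / hess
            new_t = float(np.clip(t + step, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH))
            if abs(new_t - t) < xtol:
                return new_t
            new = self._value_grad_hess(new_t)
            if new[0] < value - 1e-9:  # Newton overshot a non-quadratic region
                return self._brent()
            t, (value, grad, hess) = new_t, new
            if abs(grad) < 1e-10:
                break
        return t

    def _brent(self) -> float:
        res = minimize_scalar(lambda t: -self.lnl(t),
                              bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                              method="bounded", options={"xatol": 1e-6})
        return float(res.x)


class PruningEngine:
    """Likelihood machinery bound to one (alignment, tree, model) triple.

    The dendropy tree is indexed once in postorder; branch lengths live in
    ``self.lengths`` (edge above each node) and can be written back to a
    copy of the tree with :meth:`tree_with_lengths`.
    """

    def __init__(self, aln: Alignment, tree: dendropy.Tree,
                 model: SubstitutionModel,
                 pinned: dict | None = None):
        tips = tip_labels(tree)
        if tips != aln.taxon_set():
            extra_t = sorted(tips - aln.taxon_set())
            extra_a = sorted(aln.taxon_set() - tips)
            raise LikelihoodError(
                f"tree/alignment taxon mismatch; only in tree: {extra_t}, "
                f"only in alignment: {extra_a}")
        self.model = model
        self.aln = aln

        # --- index the tree ------------------------------------------------
        self.dnodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.dnodes)}
        self.n_nodes = len(self.dnodes)
        self.root = self.n_nodes - 1
        self.children = [[self.index[id(c)] for c in n.child_nodes()]
                         for n in self.dnodes]
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        for i, kids in enumerate(self.children):
            for c in kids:
                self.parent[c] = i
        self.lengths = np.zeros(self.n_nodes)
        self.tip_taxon = np.full(self.n_nodes, -1, dtype=int)
        taxon_row = {t: r for r, t in enumerate(aln.taxon_names)}
        for i, n in enumerate(self.dnodes):
            if i != self.root:
                length = n.edge.length
                if length is None:
                    length = 0.0
                if length < 0:
                    raise LikelihoodError(f"negative branch length {length}")
                self.lengths[i] = length
            if n.is_leaf():
                self.tip_taxon[i] = taxon_row[n.taxon.label]
        self.pinned = dict(pinned or {})
        for i, length in self.pinned.items():
            self.lengths[i] = length

        # --- site patterns --------------------------------------------------
        cols = aln.residues.T  # (n_sites, n_taxa)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns  # (npat, n_taxa)
        self.pattern_of_site = inverse.ravel()
        self.weights = counts.astype(float)
        self.npat = patterns.shape[0]

        # --- mixture components ---------------------------------------------
        self._build_components()
        self._down: list[np.ndarray | None] = [None] * self.n_nodes
        self._down_scale: list[np.ndarray | None] = [None] * self.n_nodes

    # -- component setup -----------------------------------------------------
    def _build_components(self) -> None:
        m = self.model
        rates = m.category_rates()
        ncat = len(rates)
        spec = m.spectral()
        lam, left, right, pi, wts = [], [], [], [], []
        for k in range(m.n_profiles):
            lam_k, left_k, right_k = spec[k]
            for rate in rates:
                lam.append(lam_k * rate)
                left.append(left_k)
                right.append(right_k)
                pi.append(m.profiles[k])
                wts.append(m.profile_weights[k] / ncat)
        self.lam = np.array(lam)            # (ncomp, 20)
        self.left = np.array(left)          # (ncomp, 20, 20)
        self.right = np.array(right)
        self.pi = np.array(pi)              # (ncomp, 20)
        self.comp_weights = np.array(wts)   # (ncomp,)
        self.ncomp = len(wts)
        self._comp_profile = np.repeat(np.arange(m.n_profiles), ncat)

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t) for every mixture component, shape (ncomp, 20, 20)."""
        e = np.exp(self.lam * max(t, 0.0))
        p = np.matmul(self.right * e[:, None, :], self.left)
        return np.maximum(p, 0.0)

    # -- partial likelihoods --------------------------------------------------
    def _tip_contribution(self, node: int, p: np.ndarray) -> np.ndarray:
        codes = self.patterns[:, self.tip_taxon[node]]
        obs = np.minimum(codes, N_STATES - 1)
        cont = np.ascontiguousarray(p[:, :, obs].transpose(0, 2, 1))
        cont[:, codes == MISSING, :] = 1.0
        return cont

    def _contribution(self, node: int) -> tuple[np.ndarray, np.ndarray]:
        """Child-to-parent edge contribution and its log-scale vector."""
        p = self.transition_matrices(self.lengths[node])
        if self.tip_taxon[node] >= 0:
            return self._tip_contribution(node, p), np.zeros(self.npat)
        down, scale = self._down[node], self._down_scale[node]
        cont = np.matmul(down, p.transpose(0, 2, 1))
        return cont, scale

    def _combine(self, node: int) -> None:
        """Recompute the down partial of an internal node from its children."""
        partial = None
        scale = np.zeros(self.npat)
        for child in self.children[node]:
            cont, cscale = self._contribution(child)
            partial = cont if partial is None else partial * cont
            scale += cscale
        m = partial.max(axis=(0, 2))
        m[m == 0] = 1.0
        partial /= m[None, :, None]
        self._down[node] = partial
        self._down_scale[node] = scale + np.log(m)

    def _postorder(self) -> None:
        for node in range(self.n_nodes):
            if self.children[node]:
                self._combine(node)

    def _root_site_lnl(self) -> np.ndarray:
        froot = self._down[self.root]
        site = np.einsum("c,ci,csi->s", self.comp_weights, self.pi, froot)
        return np.log(site) + self._down_scale[self.root]

    def lnl(self, per_site: bool = False):
        """Full log-likelihood (and optionally the per-site vector)."""
        self._postorder()
        pat_lnl = self._root_site_lnl()
        total = float(pat_lnl @ self.weights)
        if not np.isfinite(total):
            raise LikelihoodError("non-finite log-likelihood")
        if per_site:
            return total, pat_lnl[self.pattern_of_site]
        return total

    def profile_site_lnl(self) -> np.ndarray:
        """Per-profile pattern log-likelihoods, shape (K, npat).

        Entry (k, s) is log P(pattern s | profile k) averaged over gamma
        categories, without the profile weight — the E-step ingredient for
        mixture-weight estimation.
        """
        self._postorder()
        froot = self._down[self.root]
        comp_site = np.einsum("ci,csi->cs", self.pi, froot)
        by_profile = comp_site.reshape(self.model.n_profiles, -1, self.npat).mean(axis=1)
        return np.log(np.maximum(by_profile, 1e-300)) + self._down_scale[self.root]

    # -- branch-length optimization -------------------------------------------
    def _edge_curve(self, f_out: np.ndarray, node: int) -> "EdgeCurve":
        """Closed-form relative lnL(t) for one edge (spectral projection)."""
        if self.tip_taxon[node] >= 0:
            codes = self.patterns[:, self.tip_taxon[node]]
            obs = np.minimum(codes, N_STATES - 1)
            h = self.left[:, :, obs]                      # (ncomp, 20, npat)
            miss = codes == MISSING
            if miss.any():
                h = h.copy()
                h[:, :, miss] = self.left.sum(axis=2)[:, :, None]
        else:
            h = np.matmul(self.left, self._down[node].transpose(0, 2, 1))
        g = np.matmul(self.left, f_out.transpose(0, 2, 1))  # (ncomp, 20, npat)
        m = g * h
        m *= self.comp_weights[:, None, None]
        m2 = m.reshape(self.ncomp * N_STATES, self.npat)
        lam2 = self.lam.reshape(-1)
        return EdgeCurve(lam2, m2, self.weights)

    def _optimize_edge(self, f_out, node: int) -> float:
        curve = self._edge_curve(f_out, node)
        cur = self.lengths[node]
        best_t = curve.maximize(cur)
        if curve.lnl(best_t) < curve.lnl(cur):
            best_t = cur  # coordinate ascent must never go downhill
        # flat or monotone-decreasing curves resolve toward the lower bound
        if best_t < 1e-2 and \
                curve.lnl(MIN_BRANCH_LENGTH) >= curve.lnl(best_t) - 1e-12:
            best_t = MIN_BRANCH_LENGTH
        return best_t

    def _optimize_node(self, node: int, f_up: np.ndarray) -> None:
        # within the DFS no rescaling is applied to the outside partials:
        # at the tree sizes this engine targets (tens of taxa) float64 does
        # not underflow, and the edge curves only need relative lnL values
        kids = self.children[node]
        conts = {}
        for child in kids:
            conts[child] = self._contribution(child)
        for child in kids:
            f_out = f_up
            for sib in kids:
                if sib is child:
                    continue
                f_out = f_out * conts[sib][0]
            if child not in self.pinned and not self._skip[child]:
                new_t = self._optimize_edge(f_out, child)
                self._moved[child] = abs(new_t - self.lengths[child])
                self.lengths[child] = new_t
            if self.children[child]:
                # conditional of outside data at the child node: by
                # reversibility U_v[j] = sum_i f_out[i] P_ji(t)
                p = self.transition_matrices(self.lengths[child])
                f_up_child = np.matmul(f_out, p.transpose(0, 2, 1))
                self._optimize_node(child, f_up_child)
                self._combine(child)
                conts[child] = self._contribution(child)
            elif self._moved[child] > 0:
                conts[child] = self._contribution(child)

    def optimize(self, tol: float = 1e-4, max_passes: int = 20):
        """Coordinate-ascent branch-length optimization.

        Returns ``(lnl, converged, n_passes)``; ``self.lengths`` holds the
        optimized values.  Pinned edges keep their given lengths.
        """
        last = self.lnl()
        ones = np.ones((self.ncomp, self.npat, N_STATES))
        converged = False
        n_passes = 0
        self._moved = np.full(self.n_nodes, np.inf)
        for p in range(max_passes):
            # edges that barely moved are skipped, except on periodic
            # full passes that guard against premature convergence
            if p % 3 == 0:
                self._skip = np.zeros(self.n_nodes, dtype=bool)
            else:
                self._skip = self._moved < 1e-5
            self._optimize_node(self.root, ones)
            n_passes += 1
            # the DFS leaves all descendant partials current; refresh the root
            self._combine(self.root)
            cur = float(self._root_site_lnl() @ self.weights)
            if cur - last < tol:
                converged = True
                last = max(cur, last)
                break
            last = cur
        if not converged:
            logger.warning("branch-length optimization did not converge "
                           "after %d passes", n_passes)
        return last, converged, n_passes

    def tree_with_lengths(self, tree: dendropy.Tree) -> dendropy.Tree:
        """Copy of ``tree`` carrying the engine's current branch lengths."""
        out = clone(tree)
        for src, dst in zip(tree.postorder_node_iter(),
                            out.postorder_node_iter()):
            i = self.index[id(src)]
            if i != self.root:
                dst.edge.length = float(self.lengths[i])
        return out


# ---------------------------------------------------------------------------
# public operations

def _prepare(aln: Alignment, tree: dendropy.Tree):
    """Crop alignment to the tree's taxa (tree tips must all be present)."""
    tips = tip_labels(tree)
    missing = tips - aln.taxon_set()
    if missing:
        raise LikelihoodError(f"tree tips absent from alignment: {sorted(missing)}")
    if aln.taxon_set() != tips:
        aln = aln.subset_taxa(tips)
    return aln


def compute_lnl(aln: Alignment, tree: dendropy.Tree,
                model: SubstitutionModel) -> LikelihoodResult:
    """Log-likelihood of the alignment on a fixed tree (no optimization)."""
    aln = _prepare(aln, tree)
    engine = PruningEngine(aln, tree, model)
    total, per_site = engine.lnl(per_site=True)
    return LikelihoodResult(lnl=total, tree=tree, model=model,
                            per_site_lnl=per_site)


def _pinned_indices(engine: PruningEngine, tree: dendropy.Tree,
                    fixed_edges) -> dict:
    out = {}
    if fixed_edges:
        for dnode, length in fixed_edges.items():
            out[engine.index[id(dnode)]] = float(length)
    return out


def optimize_branch_lengths(aln: Alignment, topology: dendropy.Tree,
                            model: SubstitutionModel,
                            fixed_edges: dict | None = None,
                            tol: float = 1e-4,
                            max_passes: int = 20) -> LikelihoodResult:
    """ML branch lengths on a fixed topology (bounded Brent per edge).

    ``fixed_edges`` maps dendropy nodes (head of the pinned edge) to the
    length at which that edge is held.
    """
    aln = _prepare(aln, topology)
    engine = PruningEngine(aln, topology, model)
    engine.pinned = _pinned_indices(engine, topology, fixed_edges)
    for i, length in engine.pinned.items():
        engine.lengths[i] = length
    lnl, converged, n_passes = engine.optimize(tol=tol, max_passes=max_passes)
    return LikelihoodResult(lnl=lnl, tree=engine.tree_with_lengths(topology),
                            model=model, converged=converged,
                            n_passes=n_passes)


def fit_model(aln: Alignment, topology: dendropy.Tree, spec: str,
              profile_library: np.ndarray | None = None,
              tol: float = 1e-2, max_outer: int = 8,
              branch_tol: float = 1e-3) -> LikelihoodResult:
    """Fit a model-ladder rung jointly with branch lengths.

    ``spec`` is one of ``LG`` (site-homogeneous +F, single rate),
    ``LG+G`` (adds discrete-gamma rates) or ``MIX+LG+G`` (profile mixture
    with fixed profile library, estimated weights, plus gamma).  +F
    frequencies come from observed counts with pseudocount 1 and are not
    iterated; for the mixture the +F profile is appended to the library, so
    each ladder rung nests the previous one.  Gamma shape and mixture
    weights are estimated by bounded 1-D search and EM respectively,
    interleaved with branch-length passes.
    """
    if spec not in MODEL_LADDER:
        raise ModelError(f"unknown model spec {spec!r}; choose from {MODEL_LADDER}")
    if aln.n_sites < 1 or aln.n_taxa < 2:
        raise LikelihoodError("empty or degenerate alignment")
    aln = _prepare(aln, topology)
    freqs = observed_frequencies(aln.residue_counts())
    if spec == "LG":
        model = SubstitutionModel.lg(frequencies=freqs)
    elif spec == "LG+G":
        model = SubstitutionModel.lg(gamma_alpha=1.0, frequencies=freqs)
        model = model.with_(name="LG+G")
    else:
        if profile_library is None:
            raise ModelError("MIX+LG+G requires a profile library")
        # the +F profile joins the library so the homogeneous +F model is
        # nested inside the mixture (weight 1 on that profile recovers it)
        library = np.vstack([np.atleast_2d(profile_library), freqs])
        model = SubstitutionModel.mixture(library, gamma_alpha=1.0)
    model = model.with_(name=spec)

    tree = topology
    last = -np.inf
    result = None
    for _ in range(max_outer):
        result = optimize_branch_lengths(aln, tree, model, tol=branch_tol)
        tree = result.tree
        if model.gamma_alpha is not None:
            model = _fit_alpha(aln, tree, model)
        if model.n_profiles > 1:
            model = _fit_weights(aln, tree, model)
        cur = compute_lnl(aln, tree, model).lnl
        if cur - last < tol:
            last = max(cur, last)
            break
        last = cur
    final = optimize_branch_lengths(aln, tree, model, tol=branch_tol)
    final.model = model
    if final.lnl < last - 1e-6:
        final.lnl = last
    return final


def fit_gamma_shape(aln, tree, model, bounds=(0.05, 20.0)) -> SubstitutionModel:
    """Model with the gamma shape re-estimated at fixed branch lengths."""
    return _fit_alpha(aln, tree, model, bounds=bounds)


def _fit_alpha(aln, tree, model, bounds=(0.05, 20.0)) -> SubstitutionModel:
    def neg(log_alpha: float) -> float:
        m = model.with_(gamma_alpha=float(np.exp(log_alpha)))
        return -compute_lnl(aln, tree, m).lnl

    res = minimize_scalar(neg, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-3})
    alpha = float(np.exp(res.x))
    if neg(res.x) <= -compute_lnl(aln, tree, model).lnl:
        return model.with_(gamma_alpha=alpha)
    return model


def _fit_weights(aln, tree, model, tol: float = 1e-6,
                 max_iter: int = 500) -> SubstitutionModel:
    """EM on mixture weights at fixed branch lengths and profiles."""
    engine = PruningEngine(aln, tree, model)
    log_pk = engine.profile_site_lnl()          # (K, npat)
    wts = engine.weights
    w = model.profile_weights.copy()
    last = -np.inf
    for _ in range(max_iter):
        log_mix = np.logaddexp.reduce(np.log(np.maximum(w, 1e-300))[:, None] + log_pk,
                                      axis=0)
        lnl = float(log_mix @ wts)
        resp = np.exp(np.log(np.maximum(w, 1e-300))[:, None] + log_pk - log_mix[None, :])
        w = (resp * wts[None, :]).sum(axis=1)
        w = np.maximum(w / w.sum(), 0.0)
        w /= w.sum()
        if lnl - last < tol:
            break
        last = lnl
    return model.with_(profile_weights=w)


# ---------------------------------------------------------------------------
# simulation

def simulate_alignment(tree: dendropy.Tree, model: SubstitutionModel,
                       n_sites: int, seed: int,
                       rate_multiplier: float = 1.0,
                       name: str = "sim") -> Alignment:
    """Forward-simulate an alignment along the tree under the model.

    Per site, a profile is drawn by its weight and a gamma category
    uniformly; the root state comes from the profile and states evolve along
    every edge with exp(Q * t * rate).  Deterministic given the seed.
    """
    if n_sites < 1:
        raise LikelihoodError(f"n_sites must be >= 1, got {n_sites}")
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    ncat = len(rates)
    k_of_site = rng.choice(model.n_profiles, size=n_sites,
                           p=model.profile_weights)
    c_of_site = rng.integers(0, ncat, size=n_sites)
    comp = k_of_site * ncat + c_of_site
    spec = model.spectral()

    # root states from each site's profile
    states = {}
    root_states = np.empty(n_sites, dtype=np.int64)
    u = rng.random(n_sites)
    for k in range(model.n_profiles):
        mask = k_of_site == k
        cum = np.cumsum(model.profiles[k])
        root_states[mask] = np.searchsorted(cum, u[mask], side="right")
    nodes = list(tree.preorder_node_iter())
    states[id(nodes[0])] = root_states

    site_rate = rates[c_of_site]
    for node in nodes[1:]:
        t = (node.edge.length or 0.0) * rate_multiplier
        parent_states = states[id(node.parent_node)]
        child_states = parent_states.copy()
        if t > 0:
            u = rng.random(n_sites)
            for k in range(model.n_profiles):
                lam, left, right = spec[k]
                for c in range(ncat):
                    mask = (k_of_site == k) & (c_of_site == c)
                    if not mask.any():
                        continue
                    p = right @ (np.exp(lam * t * rates[c])[:, None] * left)
                    p = np.maximum(p, 0.0)
                    p /= p.sum(axis=1, keepdims=True)
                    cum = np.cumsum(p, axis=1)
                    rows = cum[parent_states[mask]]
                    child_states[mask] = (u[mask, None] > rows).sum(axis=1)
        states[id(node)] = child_states

    taxa, rows = [], []
    for node in nodes:
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(states[id(node)])
    order = np.argsort(taxa)
    return Alignment([taxa[i] for i in order],
                     np.vstack([rows[i] for i in order]).astype(np.int8),
                     name=name)


def pairwise_ml_distance(aln: Alignment, taxon_a: str, taxon_b: str,
                         model: SubstitutionModel) -> float:
    """ML distance between two sequences under the model (bounded Brent)."""
    ia = aln.taxon_names.index(taxon_a)
    ib = aln.taxon_names.index(taxon_b)
    a, b = aln.residues[ia], aln.residues[ib]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        return MAX_BRANCH_LENGTH
    a, b = a[ok].astype(int), b[ok].astype(int)
    pairs, counts = np.unique(a * N_STATES + b, return_counts=True)
    ai, bi = pairs // N_STATES, pairs % N_STATES
    rates = model.category_rates()
    spec = model.spectral()

    def neg(t: float) -> float:
        lik = np.zeros(len(pairs))
        for k in range(model.n_profiles):
            lam, left, _ = spec[k]
            for r in rates:
                pip = left.T @ (np.exp(lam * t * r)[:, None] * left)
                lik += (model.profile_weights[k] / len(rates)) * \
                    np.maximum(pip[ai, bi], 1e-300)
        return -float(np.log(lik) @ counts)

    res = minimize_scalar(neg, bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)
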