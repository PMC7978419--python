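import numpy as np
import pytest

from phylosupport import treeops as T
from phylosupport.alignment import Alignment
from phylosupport.likelihood import (compute_lnl, optimize_branch_lengths,
                                     simulate_alignment)
from phylosupport.model import SubstitutionModel
from phylosupport.synthetic_data import CladeTreeConfig, make_clade_tree
from phylosupport.topology_tests import (TernaryPoint, TopologyTestError,
                                         classify_gene, classify_geneset,
                                         gene_clan_filter, hypothesis_trees,
                                         infer_gene_tree, monophyly_score,
                                         per_gene_topology_lnls,
                                         scale_likelihoods, triangle_summary,
                                         welch_t)


@pytest.fixture(scope="module")
def clan_world():
    tree, cm = make_clade_tree(
        CladeTreeConfig(taxa_per_clan=2, deuterostome_stem=0.05,
                        protostome_stem=0.1, base_depth=0.4,
                        tip_rate_sigma=0.2, seed=41))
    return tree, cm


class TestHypothesisTrees:
    def test_deuterostome_set_shapes(self, clan_world):
        tree, cm = clan_world
        hyp = hypothesis_trees(tree, cm, "deuterostome")
        assert hyp.labels == ("DM", "D1", "D2")
        # D1: Xenambulacraria sister to Protostomia
        d1 = T.root_on_outgroup(hyp["D1"], cm)
        assert T.is_monophyletic(d1, cm["Xenambulacraria"] | cm.protostomia)
        # D2: Chordata sister to Protostomia
        d2 = T.root_on_outgroup(hyp["D2"], cm)
        assert T.is_monophyletic(d2, cm["Chordata"] | cm.protostomia)
        # DM keeps Deuterostomia monophyletic
        dm = T.root_on_outgroup(hyp["DM"], cm)
        assert T.is_monophyletic(dm, cm.deuterostomia)

    def test_protostome_set_shapes(self, clan_world):
        tree, cm = clan_world
        hyp = hypothesis_trees(tree, cm, "protostome")
        assert hyp.labels == ("PM", "P1", "P2")
        p1 = T.root_on_outgroup(hyp["P1"], cm)
        assert T.is_monophyletic(p1, cm["Lophotrochozoa"] | cm.deuterostomia)
        p2 = T.root_on_outgroup(hyp["P2"], cm)
        assert T.is_monophyletic(p2, cm["Ecdysozoa"] | cm.deuterostomia)

    def test_tip_sets_identical_and_subtrees_preserved(self, clan_world):
        tree, cm = clan_world
        hyp = hypothesis_trees(tree, cm, "deuterostome")
        tips = {frozenset(T.tip_labels(hyp[lab])) for lab in hyp.labels}
        assert len(tips) == 1 and tips.pop() == T.tip_labels(tree)
        # within-clan distances preserved exactly
        ref_d = T.tip_to_tip_distances(tree)
        for lab in hyp.labels:
            d = T.tip_to_tip_distances(hyp[lab])
            for clan in cm.clans.values():
                for a in clan:
                    for b in clan:
                        if a < b:
                            assert d[(a, b)] == pytest.approx(ref_d[(a, b)])

    def test_idempotent_on_own_dm_output(self, clan_world):
        tree, cm = clan_world
        hyp = hypothesis_trees(tree, cm, "deuterostome")
        again = hypothesis_trees(hyp["DM"], cm, "deuterostome")
        for lab in hyp.labels:
            a = T.root_on_outgroup(hyp[lab], cm)
            b = T.root_on_outgroup(again[lab], cm)
            # same topology: identical split sets over tip labels
            splits = lambda t: {
                frozenset(l.taxon.label for l in n.leaf_iter())
                for n in t.preorder_node_iter() if n.parent_node}
            assert splits(a) == splits(b)

    def test_nonmonophyletic_clan_rejected(self, clan_world):
        tree, cm = clan_world
        # swap a lophotrochozoan into Chordata: the clan is now broken
        lop = sorted(cm["Lophotrochozoa"])[0]
        broken = T.CladeMap({
            "Outgroup": cm["Outgroup"],
            "Lophotrochozoa": cm["Lophotrochozoa"] - {lop},
            "Ecdysozoa": cm["Ecdysozoa"],
            "Chordata": cm["Chordata"] | {lop},
            "Xenambulacraria": cm["Xenambulacraria"]})
        with pytest.raises((TopologyTestError, T.MonophylyError)):
            hypothesis_trees(tree, broken, "deuterostome")


class TestScaleAndClassify:
    def test_equal_lnls_give_uniform_point(self):
        point = scale_likelihoods([-5.0, -5.0, -5.0])
        assert point.weights == pytest.approx([1 / 3] * 3)
        assert classify_gene(point) == "unresolved"

    def test_dominant_lnl(self):
        point = scale_likelihoods([-10.0, -1000.0, -1000.0])
        assert point.weights[0] == pytest.approx(1.0)
        assert classify_gene(point) == "DM"

    def test_frozen_softmax_values(self):
        # direct evaluation of exp(lnL - max) / sum
        point = scale_likelihoods([-100.0, -101.0, -102.0])
        assert point.weights == pytest.approx(
            [0.66524096, 0.24472847, 0.09003057], abs=1e-7)

    def test_shift_invariance_and_order_preservation(self):
        rng = np.random.default_rng(3)
        lnls = rng.normal(-500, 5, size=3)
        a = scale_likelihoods(lnls).weights
        b = scale_likelihoods(lnls + 123.4).weights
        assert a == pytest.approx(b, rel=1e-9)
        assert list(np.argsort(a)) == list(np.argsort(lnls))

    def test_boundary_is_unresolved(self):
        point = TernaryPoint(np.array([2 / 3, 1 / 6, 1 / 6]),
                             ("DM", "D1", "D2"))
        assert classify_gene(point) == "unresolved"
        just_over = TernaryPoint(np.array([2 / 3 + 1e-9, 1 / 6, 1 / 6 - 1e-9]),
                                 ("DM", "D1", "D2"))
        assert classify_gene(just_over) == "DM"

    def test_nonfinite_lnl_rejected(self):
        with pytest.raises(TopologyTestError):
            scale_likelihoods([np.nan, -1.0, -2.0])

    def test_property_simplex_shift_invariance_order(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(deadline=None, derandomize=True, max_examples=100)
        # spans beyond ~745 nats underflow the weights to exact zeros,
        # where ordering degenerates to ties by design
        @given(lnls=st.lists(st.floats(-300.0, 0.0), min_size=3, max_size=3),
               shift=st.floats(-1e3, 1e3))
        def check(lnls, shift):
            w = scale_likelihoods(lnls).weights
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w >= 0)
            shifted = scale_likelihoods([x + shift for x in lnls]).weights
            assert shifted == pytest.approx(w, abs=1e-9)
            gaps = np.abs(np.subtract.outer(lnls, lnls))[np.triu_indices(3, 1)]
            if gaps.min() > 1e-6:  # order is only defined off exact ties
                assert list(np.argsort(w)) == list(np.argsort(lnls))

        check()


class TestPerGeneLnls:
    def test_strong_deuterostome_stem_selects_dm(self, clan_world):
        tree, cm = clan_world
        strong, _ = make_clade_tree(
            CladeTreeConfig(taxa_per_clan=2, deuterostome_stem=0.3,
                            protostome_stem=0.1, base_depth=0.4,
                            tip_rate_sigma=0.2, seed=41))
        model = SubstitutionModel.lg(gamma_alpha=0.8)
        gene = simulate_alignment(strong, model, 5000, seed=13)
        hyp = hypothesis_trees(tree, cm, "deuterostome")
        lnls = per_gene_topology_lnls(gene, hyp, model)
        assert hyp.labels[int(np.argmax(lnls))] == "DM"

    def test_duplicating_sites_doubles_lnl_differences(self, clan_world):
        tree, cm = clan_world
        model = SubstitutionModel.lg(gamma_alpha=0.8)
        gene = simulate_alignment(tree, model, 300, seed=14)
        doubled = Alignment(gene.taxon_names,
                            np.hstack([gene.residues, gene.residues]))
        hyp = hypothesis_trees(tree, cm, "deuterostome")
        a = per_gene_topology_lnls(gene, hyp, model, tol=1e-4)
        b = per_gene_topology_lnls(doubled, hyp, model, tol=1e-4)
        assert (b - 2 * a) == pytest.approx(np.zeros(3), abs=2e-2)
        diff_a = a - a[0]
        diff_b = b - b[0]
        assert diff_b == pytest.approx(2 * diff_a, abs=2e-2)

    def test_gene_missing_a_clan_is_filtered(self, clan_world):
        tree, cm = clan_world
        model = SubstitutionModel.lg(gamma_alpha=0.8)
        gene = simulate_alignment(tree, model, 100, seed=15)
        partial = gene.subset_taxa(gene.taxon_set() - cm["Chordata"])
        assert gene_clan_filter(partial, cm) is not None
        hyp = hypothesis_trees(tree, cm, "deuterostome")
        table = classify_geneset([partial], hyp, model, cm)
        assert table.empty


class TestGeneTreeInference:
    def test_recovers_easy_six_taxon_tree(self):
        truth = T.parse_newick(
            "((A:0.2,B:0.25):0.15,(C:0.2,(D:0.15,E:0.2):0.12):0.1,F:0.3);")
        model = SubstitutionModel.lg(gamma_alpha=1.0)
        aln = simulate_alignment(truth, model, 5000, seed=17)
        tree, lnl = infer_gene_tree(aln, model)
        tips = frozenset("ABCDEF")
        # unrooted splits as unordered pairs of sides
        splits = {
            frozenset({side, tips - side})
            for side in (frozenset(l.taxon.label for l in n.leaf_iter())
                         for n in tree.preorder_node_iter()
                         if n.parent_node and not n.is_leaf())}
        want = {frozenset({frozenset("AB"), tips - frozenset("AB")}),
                frozenset({frozenset("DE"), tips - frozenset("DE")}),
                frozenset({frozenset("CDE"), tips - frozenset("CDE")})}
        assert want <= splits

    def test_four_taxon_agrees_with_exhaustive_scan(self):
        truth = T.parse_newick("((A:0.3,B:0.25):0.15,(C:0.2,D:0.35):0.1);")
        model = SubstitutionModel.lg(gamma_alpha=1.0)
        aln = simulate_alignment(truth, model, 2000, seed=19)
        tree, lnl = infer_gene_tree(aln, model)
        quartets = ["((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
                    "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);",
                    "((A:0.1,D:0.1):0.1,(B:0.1,C:0.1):0.1);"]
        scan = [optimize_branch_lengths(aln, T.parse_newick(q), model).lnl
                for q in quartets]
        assert lnl == pytest.approx(max(scan), abs=0.05)

    def test_too_few_taxa(self):
        model = SubstitutionModel.lg()
        aln = Alignment.from_sequences(["A", "B", "C"], ["AR", "ND", "CQ"])
        with pytest.raises(TopologyTestError, match=">= 4"):
            infer_gene_tree(aln, model)


class TestMonophylyScore:
    def test_reference_tree_scores_one(self, clan_world):
        tree, cm = clan_world
        clades = [cm[c] for c in cm.clans]
        assert monophyly_score(tree, clades) == 1.0

    def test_broken_clade_counts_against(self):
        tree = T.parse_newick("(((A1:1,B1:1):1,A2:1):1,(B2:1,C1:1):1,C2:1);")
        clades = [{"A1", "A2"}, {"B1", "B2"}, {"C1", "C2"}]
        # none of the three pairs is a split on this tree
        assert monophyly_score(tree, clades) == 0.0
        clades2 = [{"A1", "B1"}, {"B2", "C1"}, {"A2", "Z9"}]
        # first two are splits; third has <2 present taxa -> excluded
        assert monophyly_score(tree, clades2) == 1.0

    def test_agrees_with_bipartition_oracle_on_random_trees(self):
        from conftest import random_tree_newick

        rng = np.random.default_rng(23)
        for _ in range(10):
            tree = T.parse_newick(random_tree_newick(rng, 8))
            tips = sorted(T.tip_labels(tree))
            clades = [set(rng.choice(tips, size=int(rng.integers(2, 5)),
                                     replace=False)) for _ in range(5)]
            score = monophyly_score(tree, clades)
            # oracle via dendropy bipartition encoding
            import dendropy

            enc = tree.encode_bipartitions()
            namespace = tree.taxon_namespace
            all_splits = set()
            for bp in tree.bipartition_encoding:
                mask = bp.leafset_bitmask
                inset = {t.label for t in namespace
                         if mask & namespace.taxon_bitmask(t)}
                all_splits.add(frozenset(inset))
                all_splits.add(frozenset(set(tips) - inset))
            tested = [c for c in clades if len(c) >= 2]
            oracle = np.mean([frozenset(c) in all_splits for c in tested])
            assert score == pytest.approx(oracle)

    def test_no_testable_clades_is_undefined(self):
        tree = T.parse_newick("((A:1,B:1):1,C:1);")
        assert monophyly_score(tree, [{"X", "Y"}]) is None


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_oracle(self):
        t, df, p = welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.5492, abs=1e-4)
        assert df == pytest.approx(2.9412, abs=1e-4)
        # cross-check against scipy's Welch test
        from scipy import stats

        ref = stats.ttest_ind([1, 2, 3], [2, 4, 6], equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_shift_invariance(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 2.5, 6.0, 1.0]
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t([x + 7 for x in a], [x + 7 for x in b])
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))

    def test_degenerate_inputs(self):
        with pytest.raises(TopologyTestError):
            welch_t([1.0], [2.0, 3.0])
        with pytest.raises(TopologyTestError):
            welch_t([2.0, 2.0], [3.0, 3.0])


def test_longer_genes_resolve_more_often():
    """At equal stems, longer gene alignments are classified as resolved
    more often, and resolved genes are significantly longer (Welch's t) —
    the informativeness contrast, direction only."""
    from phylosupport.synthetic_data import default_heterogeneous_model

    tree, cm = make_clade_tree(
        CladeTreeConfig(taxa_per_clan=2, deuterostome_stem=0.04,
                        protostome_stem=0.06, base_depth=0.4,
                        tip_rate_sigma=0.2, seed=61))
    gen = default_heterogeneous_model(k=3, seed=61)
    model = SubstitutionModel.lg(gamma_alpha=0.8)
    hyp = hypothesis_trees(tree, cm, "deuterostome")
    genes = []
    for i in range(40):
        n_sites = 1000 if i % 2 == 0 else 150
        genes.append(simulate_alignment(tree, gen, n_sites, seed=700 + i,
                                        name=f"g{i}"))
    table = classify_geneset(genes, hyp, model, cm, tol=1e-3)
    resolved = table["category"] != "unresolved"
    frac_long = resolved[table["n_sites"] == 1000].mean()
    frac_short = resolved[table["n_sites"] == 150].mean()
    assert frac_long > frac_short
    t, df, p = welch_t(table.loc[resolved, "n_sites"],
                       table.loc[~resolved, "n_sites"])
    assert t > 0 and p < 0.05


def test_triangle_summary_counts():
    import pandas as pd

    frame = pd.DataFrame({"category": ["DM", "DM", "unresolved", "D2"]})
    counts = triangle_summary(frame, ("DM", "D1", "D2"))
    assert counts == {"DM": 2, "D1": 0, "D2": 1, "unresolved": 1}
    assert sum(counts.values()) == len(frame)
    empty = triangle_summary(pd.DataFrame(columns=["category"]),
                             ("DM", "D1", "D2"))
    assert sum(empty.values()) == 0
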