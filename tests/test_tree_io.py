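"""Tree parsing, ages, artifact detection, reduced trees and tip dropping."""

import numpy as np
import pytest

import claderich as cr
from claderich.tree_io import NewickParseError, TreeStructureError


class TestParseWrite:
    def test_three_tip_structure(self, three_tip_tree):
        t = three_tip_tree
        assert t.n_tips == 3
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.node_depths()[t.root_id] == pytest.approx(2.0)

    def test_round_trip_is_identity(self, three_tip_tree):
        s = cr.write_newick(three_tip_tree)
        assert s == "((A:1,B:1):1,C:2);"
        assert cr.write_newick(cr.parse_newick(s)) == s

    def test_round_trip_preserves_branch_lengths(self):
        s = "((A:1.23456789,B:1.23456789):0.76543211,C:2);"
        t = cr.parse_newick(s)
        t2 = cr.parse_newick(cr.write_newick(t))
        d1, d2 = t.root_to_tip_distances(), t2.root_to_tip_distances()
        for lab in d1:
            assert d2[lab] == pytest.approx(d1[lab], abs=1e-9)

    def test_polytomy_parses(self, polytomy_tree):
        node = polytomy_tree.mrca_id(["A", "B", "C"])
        assert len(polytomy_tree.node(node).child_nodes()) == 3

    def test_malformed_string_raises(self):
        with pytest.raises(NewickParseError, match="malformed"):
            cr.parse_newick("((A:1,B:1):1,C:2;")

    def test_missing_branch_length_names_node(self):
        with pytest.raises(NewickParseError, match="B"):
            cr.parse_newick("((A:1,B):1,C:2);")

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(NewickParseError, match="duplicate"):
            cr.parse_newick("((A:1,A:1):1,C:2);")

    def test_node_ids_deterministic(self, three_tip_tree):
        t2 = cr.parse_newick("((A:1,B:1):1,C:2);")
        ids1 = {frozenset(cr.clade_tips(three_tip_tree, i)): i
                for i in range(three_tip_tree.n_nodes)}
        ids2 = {frozenset(cr.clade_tips(t2, i)): i for i in range(t2.n_nodes)}
        assert ids1 == ids2


class TestNodeAges:
    def test_three_tip_ages(self, three_tip_tree):
        t = three_tip_tree
        ages = cr.node_ages(t)
        ab = t.mrca_id(["A", "B"])
        assert ages.crown_age(t.root_id) == pytest.approx(2.0)
        assert ages.crown_age(ab) == pytest.approx(1.0)
        assert ages.stem_age(ab) == pytest.approx(2.0)

    def test_single_cherry(self):
        t = cr.parse_newick("(A:5,B:5);")
        assert cr.node_ages(t).crown_age(t.root_id) == pytest.approx(5.0)

    def test_four_tip_ladder(self, four_tip_ladder):
        t = four_tip_ladder
        ages = cr.node_ages(t)
        abc = t.mrca_id(["A", "B", "C"])
        assert ages.crown_age(abc) == pytest.approx(2.0)
        assert ages.stem_age(abc) == pytest.approx(5.0)

    def test_crown_le_stem_everywhere(self, small_forest):
        tree, _ = small_forest
        ages = cr.node_ages(tree)
        for nid, stem in ages.stem.items():
            assert ages.crown[nid] <= stem + 1e-9

    def test_non_ultrametric_rejected(self):
        t = cr.parse_newick("((A:1,B:1.5):1,C:2);")
        with pytest.raises(TreeStructureError, match="not ultrametric"):
            cr.node_ages(t)

    def test_subtree_ages_agree_with_parent_tree(self, small_forest):
        """Crown ages of shared nodes agree between a tree and its subtree."""
        tree, truth = small_forest
        ages = cr.node_ages(tree)
        nid = int(truth.node_id.iloc[0])
        labels = sorted(cr.clade_tips(tree, nid))
        sub = cr.TimeTree(
            tree._dtree.extract_tree_with_taxa_labels(
                labels, suppress_unifurcations=True
            )
        )
        sub_ages = cr.node_ages(sub)
        assert sub_ages.crown_age(sub.root_id) == pytest.approx(
            ages.crown_age(nid), abs=1e-9
        )
        # every cherry in the subtree has the same crown age as in the source
        for i in sub.internal_node_ids():
            tips = cr.clade_tips(sub, i)
            assert sub_ages.crown[i] == pytest.approx(
                ages.crown[tree.mrca_id(sorted(tips))], abs=1e-9
            )


class TestCladeTips:
    def test_internal_node(self, three_tip_tree):
        ab = three_tip_tree.mrca_id(["A", "B"])
        assert cr.clade_tips(three_tip_tree, ab) == {"A", "B"}

    def test_root_gives_all_tips(self, three_tip_tree):
        assert cr.clade_tips(three_tip_tree, three_tip_tree.root_id) == {"A", "B", "C"}

    def test_tip_node_is_singleton(self, three_tip_tree):
        tips = [i for i in range(three_tip_tree.n_nodes)
                if three_tip_tree.is_tip(i)]
        assert all(len(cr.clade_tips(three_tip_tree, i)) == 1 for i in tips)

    def test_polytomy_clade_richness(self, polytomy_tree):
        node = polytomy_tree.mrca_id(["A", "B", "C"])
        assert len(cr.clade_tips(polytomy_tree, node)) == 3

    def test_unknown_node_id(self, three_tip_tree):
        with pytest.raises(TreeStructureError):
            cr.clade_tips(three_tip_tree, 999)


class TestDetectArtifacts:
    def test_polytomy_flagged(self, polytomy_tree):
        node = polytomy_tree.mrca_id(["A", "B", "C"])
        flags = cr.detect_artifacts(polytomy_tree)
        assert flags[node].in_polytomy

    def test_zero_branch_and_zero_crown(self):
        t = cr.parse_newick("((A:0,B:0):2,C:2);")
        ab = t.mrca_id(["A", "B"])
        flags = cr.detect_artifacts(t)
        assert flags[ab].has_zero_branch
        assert cr.node_ages(t).crown_age(ab) == 0.0

    def test_clean_tree_all_false(self, four_tip_ladder):
        flags = cr.detect_artifacts(four_tip_ladder)
        assert not any(f.in_polytomy or f.has_zero_branch for f in flags.values())

    def test_crown_scope_does_not_propagate(self, polytomy_tree):
        root = polytomy_tree.root_id
        subtree = cr.detect_artifacts(polytomy_tree, polytomy_scope="subtree")
        crown = cr.detect_artifacts(polytomy_tree, polytomy_scope="crown")
        assert subtree[root].in_polytomy      # multifurcation below root
        assert not crown[root].in_polytomy    # root itself is bifurcating


class TestReducedTree:
    def test_two_clades(self, three_tip_tree):
        ab = three_tip_tree.mrca_id(["A", "B"])
        c = next(i for i in range(three_tip_tree.n_nodes)
                 if three_tip_tree.is_tip(i)
                 and cr.clade_tips(three_tip_tree, i) == {"C"})
        rt, reps = cr.reduced_tree(three_tip_tree, [ab, c])
        assert reps == ["A", "C"]
        assert cr.write_newick(rt) == "(A:2,C:2);"

    def test_reduced_tree_stays_ultrametric(self, small_forest):
        tree, truth = small_forest
        rt, _ = cr.reduced_tree(tree, truth.node_id.tolist())
        assert rt.is_ultrametric()

    def test_nested_clades_rejected(self, three_tip_tree):
        ab = three_tip_tree.mrca_id(["A", "B"])
        with pytest.raises(TreeStructureError, match="nested"):
            cr.reduced_tree(three_tip_tree, [three_tip_tree.root_id, ab])

    def test_representative_choice_leaves_distances_unchanged(self, small_forest):
        """Any representative yields the same pairwise distance matrix."""
        from claderich.phylo_regression import phylo_covariance

        tree, truth = small_forest
        ids = truth.node_id.tolist()
        rt1, reps1 = cr.reduced_tree(tree, ids)
        C1, _ = phylo_covariance(rt1, tip_order=reps1)
        # alternate representatives: lexicographically largest tip instead
        alts = [max(cr.clade_tips(tree, nid)) for nid in ids]
        sub = tree._dtree.extract_tree_with_taxa_labels(alts,
                                                        suppress_unifurcations=True)
        rt2 = cr.TimeTree(sub)
        C2, _ = phylo_covariance(rt2, tip_order=alts)
        np.testing.assert_allclose(C1, C2, atol=1e-8)


class TestDropTips:
    def test_keep_all_is_identity(self, small_forest):
        tree, _ = small_forest
        out = cr.drop_tips(tree, 1.0, seed=1)
        assert sorted(out.tip_labels) == sorted(tree.tip_labels)

    def test_fraction_and_ultrametricity(self, small_forest):
        tree, _ = small_forest
        out = cr.drop_tips(tree, 0.1, seed=5)
        assert out.n_tips == int(np.floor(tree.n_tips * 0.1))
        assert out.is_ultrametric()

    def test_deterministic_under_seed(self, small_forest):
        tree, _ = small_forest
        a = cr.drop_tips(tree, 0.3, seed=9)
        b = cr.drop_tips(tree, 0.3, seed=9)
        assert sorted(a.tip_labels) == sorted(b.tip_labels)
        assert cr.write_newick(a) == cr.write_newick(b)

    def test_surviving_pairwise_distances_preserved(self, small_forest):
        tree, _ = small_forest
        out = cr.drop_tips(tree, 0.2, seed=3)
        full = tree.root_to_tip_distances()
        sub = out.root_to_tip_distances()
        for lab, d in sub.items():
            assert d == pytest.approx(full[lab], abs=1e-9)

    def test_too_few_survivors(self, three_tip_tree):
        with pytest.raises(TreeStructureError):
            cr.drop_tips(three_tip_tree, 0.3, seed=1)

    def test_invalid_fraction(self, three_tip_tree):
        with pytest.raises(ValueError):
            cr.drop_tips(three_tip_tree, 0.0, seed=1)
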