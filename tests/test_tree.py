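"""Core tree structure: traversal, editing, search, distances, rooting."""
import random
from itertools import combinations

import pytest

import treescope as ts
from treescope import TreeError, TreeNode, parse_newick, populate_random
from treescope.newick import FLEXIBLE

from _oracles import (ancestor_path, brute_distance, brute_lca,
                      leaf_pair_distances)
from conftest import random_tree


class TestTraversal:
    def test_single_leaf(self):
        n = TreeNode(name="A")
        assert list(n.traverse("preorder")) == [n]
        assert list(n.traverse("postorder")) == [n]

    def test_postorder_definition(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        assert [n.name for n in t.traverse("postorder")] == \
            ["A", "B", "X", "C", "R"]

    def test_preorder_definition(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        assert [n.name for n in t.traverse("preorder")] == \
            ["R", "X", "A", "B", "C"]

    def test_levelorder_is_breadth_first(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        assert [n.name for n in t.traverse("levelorder")] == \
            ["R", "X", "C", "A", "B"]

    def test_internal_node_traverses_its_subtree_only(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        x = t.search_nodes(name="X")[0]
        assert [n.name for n in x.traverse("postorder")] == ["A", "B", "X"]

    def test_leaves_subsequence_and_len(self):
        t = parse_newick("((A,B),C);", FLEXIBLE)
        assert t.get_leaf_names() == ["A", "B", "C"]
        assert len(t) == 3
        assert [l.name for l in t] == ["A", "B", "C"]

    def test_membership_operator(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        assert "A" in t and "X" in t and "nope" not in t
        assert t.search_nodes(name="A")[0] in t


class TestEditing:
    def test_attach_child(self):
        t = parse_newick("A;", FLEXIBLE)
        t.add_child(name="B", dist=2.0)
        assert t.get_leaf_names() == ["B"] or len(t.children) == 1
        assert t.children[0].dist == 2.0

    def test_concatenation_combines_leaf_counts(self):
        t1 = random_tree(1, n_leaves=5)
        t2 = random_tree(2, n_leaves=7)
        t1.get_leaves()[0].up.add_child(t2)
        assert len(t1) == 12

    def test_attach_attached_child_raises(self):
        t = parse_newick("(A,B);", FLEXIBLE)
        with pytest.raises(TreeError):
            t.add_child(t.children[0])

    def test_attach_to_own_descendant_raises(self):
        t = parse_newick("((A,B)X,C);", FLEXIBLE)
        x = t.search_nodes(name="X")[0]
        orphan_parent = x.detach()
        with pytest.raises(TreeError, match="descendant"):
            orphan_parent.children[0].add_child(orphan_parent)

    def test_detach_splits_cleanly(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        x = t.search_nodes(name="X")[0]
        x.detach()
        assert x.up is None and len(x) == 2
        assert t.get_leaf_names() == ["C"]

    def test_detach_root_raises(self):
        with pytest.raises(TreeError):
            parse_newick("(A,B);", FLEXIBLE).detach()

    def test_cut_and_paste_conserves_leaves_and_features(self):
        for seed in range(25):
            t = random_tree(seed, min_leaves=6, max_leaves=25)
            for i, node in enumerate(t.traverse("preorder")):
                node.features["uid"] = i
            names = sorted(t.get_leaf_names())
            rng = random.Random(seed)
            internal = [n for n in t.iter_descendants()
                        if n.children and n.up]
            if not internal:
                continue
            chunk = rng.choice(internal).detach()
            target = rng.choice(t.get_leaves()).up
            target.add_child(chunk)
            assert sorted(t.get_leaf_names()) == names
            assert len({n.features["uid"]
                        for n in t.traverse("preorder")
                        if "uid" in n.features}) == \
                sum(1 for n in t.traverse("preorder") if "uid" in n.features)

    def test_delete_preserving_distances(self):
        t = parse_newick("((A:1,B:1)X:2,C:4)R;", FLEXIBLE)
        x = t.search_nodes(name="X")[0]
        x.delete(preserve_dist=True)
        a = t.search_nodes(name="A")[0]
        assert a.up is t and a.dist == 3.0
        assert a.get_distance("C") == 7.0

    def test_delete_without_preserve(self):
        t = parse_newick("((A:1,B:1)X:2,C)R;", FLEXIBLE)
        t.search_nodes(name="X")[0].delete(preserve_dist=False)
        assert t.search_nodes(name="A")[0].dist == 1.0

    def test_delete_root_raises(self):
        with pytest.raises(TreeError):
            parse_newick("(A,B);", FLEXIBLE).delete()

    def test_feature_shadowing_refused(self):
        with pytest.raises(TreeError):
            TreeNode().add_feature("dist", 3)


class TestPrune:
    def test_path_arithmetic_example(self):
        t = parse_newick("((A:1,B:1):2,C:3);", FLEXIBLE)
        t.prune({"A", "C"})
        assert sorted(t.get_leaf_names()) == ["A", "C"]
        a = t.search_nodes(name="A")[0]
        assert a.get_distance("C") == pytest.approx(6.0, abs=1e-9)

    def test_prune_to_all_leaves_is_identity(self):
        t = random_tree(7, n_leaves=12)
        before = leaf_pair_distances(t)
        t.prune(set(t.get_leaf_names()))
        after = leaf_pair_distances(t)
        for pair, d in before.items():
            assert after[pair] == pytest.approx(d, abs=1e-9)

    def test_unknown_names_listed(self):
        t = parse_newick("((A,B),C);", FLEXIBLE)
        with pytest.raises(TreeError, match="X.*Z|Z.*X"):
            t.prune({"A", "X", "Z"})

    def test_empty_keep_raises(self):
        with pytest.raises(TreeError):
            parse_newick("(A,B);", FLEXIBLE).prune(set())

    @pytest.mark.parametrize("seed", range(15))
    def test_random_subsets_preserve_kept_distances(self, seed):
        t = random_tree(seed, min_leaves=6, max_leaves=30)
        rng = random.Random(seed + 1)
        names = t.get_leaf_names()
        keep = set(rng.sample(names, rng.randint(2, len(names) - 1)))
        before = {p: d for p, d in leaf_pair_distances(t).items()
                  if p <= keep}
        t.prune(keep)
        assert sorted(t.get_leaf_names()) == sorted(keep)
        after = leaf_pair_distances(t)
        for pair, d in before.items():
            assert after[pair] == pytest.approx(d, abs=1e-9)


class TestSearchAndAncestry:
    def test_search_by_name_and_feature(self):
        t = parse_newick("((A[&&NHX:species=Hsa],B),C);", FLEXIBLE)
        assert len(t.search_nodes(name="A")) == 1
        hits = t.search_nodes(species="Hsa")
        assert [n.name for n in hits] == ["A"]

    def test_search_equals_linear_scan(self):
        t = random_tree(11, n_leaves=30)
        for node in t.traverse("preorder"):
            node.features["flag"] = node.name.endswith("1")
        expected = [n for n in t.traverse("preorder") if n.features["flag"]]
        assert t.search_nodes(flag=True) == expected

    def test_common_ancestor_examples(self):
        t = parse_newick("((A,B)X,C)R;", FLEXIBLE)
        a, b, c = (t.search_nodes(name=n)[0] for n in "ABC")
        assert t.get_common_ancestor([a, b]).name == "X"
        assert t.get_common_ancestor([a, c]).name == "R"
        assert t.get_common_ancestor([a]) is a

    def test_common_ancestor_cross_tree_raises(self):
        t1, t2 = random_tree(1), random_tree(2)
        with pytest.raises(TreeError):
            t1.get_common_ancestor([t1.get_leaves()[0], t2.get_leaves()[0]])

    @pytest.mark.parametrize("seed", range(20))
    def test_lca_matches_bruteforce(self, seed):
        t = random_tree(seed, min_leaves=5, max_leaves=25)
        nodes = list(t.traverse("preorder"))
        rng = random.Random(seed)
        for _ in range(30):
            pick = rng.sample(nodes, rng.randint(2, 4))
            assert t.get_common_ancestor(pick) is brute_lca(pick)


class TestDistances:
    def test_examples(self):
        t = parse_newick("(A:1,(B:2,C:3):4);", FLEXIBLE)
        a = t.search_nodes(name="A")[0]
        assert a.get_distance("B") == pytest.approx(7.0)
        assert a.get_distance(a) == 0.0
        assert a.get_distance("B", topology_only=True) == 3.0

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_properties_and_oracle(self, seed):
        t = random_tree(seed, min_leaves=5, max_leaves=15)
        nodes = list(t.traverse("preorder"))
        for a, b in combinations(nodes, 2):
            d = a.get_distance(b)
            assert d == pytest.approx(brute_distance(a, b), abs=1e-9)
            assert d == pytest.approx(b.get_distance(a), abs=1e-9)
            assert d >= 0
        # triangle inequality on a few triples
        rng = random.Random(seed)
        for _ in range(20):
            x, y, z = rng.sample(nodes, 3)
            assert x.get_distance(z) <= \
                x.get_distance(y) + y.get_distance(z) + 1e-9

    def test_cross_tree_distance_raises(self):
        t1, t2 = random_tree(1), random_tree(2)
        with pytest.raises(TreeError):
            t1.get_leaves()[0].get_distance(t2.get_leaves()[0])


class TestFarthest:
    def test_examples(self):
        t = parse_newick("(A:1,(B:2,C:3):4);", FLEXIBLE)
        a = t.search_nodes(name="A")[0]
        node, d = a.get_farthest_leaf()
        assert node.name == "C" and d == pytest.approx(8.0)
        single = parse_newick("A;", FLEXIBLE)
        assert single.get_farthest_leaf() == (single, 0.0)

    def test_searches_whole_tree_not_subtree(self):
        t = parse_newick("((A:1,B:1)X:1,C:9);", FLEXIBLE)
        a = t.search_nodes(name="A")[0]
        node, d = a.get_farthest_leaf()
        assert node.name == "C" and d == pytest.approx(11.0)
        # descendant variant stays inside the subtree
        x = t.search_nodes(name="X")[0]
        node, d = x.get_farthest_leaf(descendants_only=True)
        assert node.name == "A" and d == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_argmax_of_distance_oracle(self, seed):
        t = random_tree(seed, min_leaves=4, max_leaves=20)
        rng = random.Random(seed)
        src = rng.choice(list(t.traverse("preorder")))
        node, d = src.get_farthest(leaves_only=True)
        best = max(brute_distance(src, l) for l in t.get_leaves())
        assert d == pytest.approx(best, abs=1e-9)
        assert brute_distance(src, node) == pytest.approx(best, abs=1e-9)


class TestRooting:
    def test_midpoint_on_asymmetric_tree(self):
        t = parse_newick("(A:3,(B:1,C:1):1);", FLEXIBLE)
        assert t.get_midpoint_outgroup().name == "A"

    def test_midpoint_tie_on_balanced_quartet(self, quartet):
        og = quartet.get_midpoint_outgroup()
        assert og in quartet.children  # either root child is valid

    def test_zero_length_tree_raises(self):
        t = parse_newick("(A:0,B:0);", FLEXIBLE)
        with pytest.raises(TreeError, match="topology"):
            t.get_midpoint_outgroup()

    def test_set_outgroup_shape(self):
        t = parse_newick("((A,B),C);", FLEXIBLE)
        r = t.set_outgroup(t.search_nodes(name="C")[0])
        assert len(r.children) == 2
        sides = sorted(tuple(sorted(c.get_leaf_names())) for c in r.children)
        assert sides == [("A", "B"), ("C",)]

    def test_outgroup_cannot_be_root(self):
        t = parse_newick("(A,B);", FLEXIBLE)
        with pytest.raises(TreeError):
            t.set_outgroup(t)

    def test_trifurcating_root_resolved(self):
        t = parse_newick("(A:1,B:1,C:1);", FLEXIBLE)
        r = t.set_outgroup(t.search_nodes(name="A")[0])
        assert len(r.children) == 2
        rest = [c for c in r.children if c.name != "A"][0]
        assert sorted(rest.get_leaf_names()) == ["B", "C"]

    @pytest.mark.parametrize("seed", range(15))
    def test_rerooting_preserves_leaf_distances(self, seed):
        t = random_tree(seed, min_leaves=5, max_leaves=30)
        before = leaf_pair_distances(t)
        rng = random.Random(seed)
        og = rng.choice(list(t.iter_descendants()))
        r = t.set_outgroup(og)
        after = leaf_pair_distances(r)
        for pair, d in before.items():
            assert after[pair] == pytest.approx(d, abs=1e-9)

    def test_rerooting_twice_is_idempotent(self):
        t = random_tree(4, n_leaves=12)
        og = t.get_leaves()[3]
        r1 = t.set_outgroup(og)
        d1 = leaf_pair_distances(r1)
        r2 = r1.set_outgroup(og)
        d2 = leaf_pair_distances(r2)
        for pair, d in d1.items():
            assert d2[pair] == pytest.approx(d, abs=1e-9)

    @pytest.mark.parametrize("seed", range(15))
    def test_midpoint_rooting_balances_depths(self, seed):
        t = random_tree(seed, min_leaves=4, max_leaves=25)
        r = t.set_outgroup(t.get_midpoint_outgroup())
        left, right = r.children
        dl = max(left.get_distance(l) for l in left.iter_leaves())
        dr = max(right.get_distance(l) for l in right.iter_leaves())
        interior = left.dist > 1e-9 and right.dist > 1e-9
        if interior:
            assert abs((dl + left.dist) - (dr + right.dist)) <= 1e-6


class TestRandomTrees:
    def test_node_and_leaf_counts(self):
        assert sum(1 for _ in populate_random(1).traverse("preorder")) == 1
        t = populate_random(5, seed=3)
        assert len(t) == 5
        assert sum(1 for _ in t.traverse("preorder")) == 9

    def test_determinism_and_variation(self):
        a = ts.write_newick(populate_random(20, seed=7))
        b = ts.write_newick(populate_random(20, seed=7))
        assert a == b
        others = {ts.write_newick(populate_random(20, seed=s))
                  for s in range(30)}
        assert len(others) > 1

    def test_names_and_errors(self):
        t = populate_random(3, names=["x", "y", "z"], seed=0)
        assert sorted(t.get_leaf_names()) == ["x", "y", "z"]
        with pytest.raises(TreeError):
            populate_random(0)
        with pytest.raises(TreeError):
            populate_random(3, names=["only", "two"])


class TestAscii:
    def test_single_leaf(self):
        assert "A" in TreeNode(name="A").ascii()

    def test_depth_proportional_indent(self):
        art = parse_newick("((A,B),C);", FLEXIBLE).ascii()
        lines = art.splitlines()
        line = {n: next(l for l in lines if n in l) for n in "ABC"}
        assert line["A"].index("A") > line["C"].index("C")
        assert line["B"].index("B") > line["C"].index("C")

    @pytest.mark.parametrize("seed", range(8))
    def test_each_leaf_name_exactly_once(self, seed):
        t = random_tree(seed, min_leaves=3, max_leaves=20)
        art = t.ascii()
        for name in t.get_leaf_names():
            assert sum(1 for l in art.splitlines()
                       if l.endswith(f"-{name}")) == 1
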