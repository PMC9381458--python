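import numpy as np
import pandas as pd
import pytest

from scclone.clones import Clone
from scclone.phylo import (
    EvolutionCall,
    InvalidDistanceError,
    RootAnchorError,
    TreeNode,
    classify_evolution,
    clone_distance_matrix,
    fishplot_table,
    leaf_distances,
    nj_tree,
    parse_newick,
    root_tree,
    to_newick,
)


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Independent oracle: build a random binary tree with positive branch
    lengths, return (leaf names, pairwise path-distance matrix, splits)."""
    nodes = [{"leaves": frozenset([f"t{i}"])} for i in range(n_taxa)]
    dist = {f"t{i}": {f"t{i}": 0.0} for i in range(n_taxa)}
    # pairwise distances accumulated bottom-up
    leaf_depth = {f"t{i}": 0.0 for i in range(n_taxa)}
    D = np.zeros((n_taxa, n_taxa))
    names = [f"t{i}" for i in range(n_taxa)]
    groups = [[i] for i in range(n_taxa)]
    depths = [dict({names[i]: 0.0}) for i in range(n_taxa)]
    splits = set()
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        li = float(rng.uniform(0.5, 3.0))
        lj = float(rng.uniform(0.5, 3.0))
        gi, gj = groups[i], groups[j]
        di, dj = depths[i], depths[j]
        for a in gi:
            for b in gj:
                D[a, b] = D[b, a] = di[names[a]] + li + dj[names[b]] + lj
        merged_depth = {}
        for a in gi:
            merged_depth[names[a]] = di[names[a]] + li
        for b in gj:
            merged_depth[names[b]] = dj[names[b]] + lj
        merged = gi + gj
        if 1 < len(merged) < len(names) - 1:
            splits.add(frozenset(names[k] for k in merged))
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
        depths = [d for k, d in enumerate(depths) if k not in (i, j)] + [merged_depth]
    return names, pd.DataFrame(D, index=names, columns=names), splits


def tree_splits(root: TreeNode, all_leaves: frozenset) -> set:
    """Non-trivial bipartitions induced by the tree's internal edges."""
    splits = set()

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            side = min(below, frozenset(all_leaves - below), key=sorted)
            splits.add(side)
        return below

    walk(root)
    return splits


class TestNjTree:
    def test_three_taxa_closed_form(self):
        # d(ab)=3, d(ac)=5, d(bc)=6 -> la=1, lb=2, lc=4
        D = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]],
            index=["a", "b", "c"], columns=["a", "b", "c"], dtype=float,
        )
        tree = nj_tree(D)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_four_taxon_additive_roundtrip(self):
        names, D, true_splits = random_additive_tree(4, np.random.default_rng(0))
        tree = nj_tree(D)
        recovered = leaf_distances(tree)
        np.testing.assert_allclose(
            recovered.loc[names, names].to_numpy(), D.to_numpy(), atol=1e-9
        )

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_random_additive_trees_recovered_exactly(self, n_taxa):
        for rep in range(8):
            rng = np.random.default_rng(100 * n_taxa + rep)
            names, D, true_splits = random_additive_tree(n_taxa, rng)
            tree = nj_tree(D)
            recovered = leaf_distances(tree)
            np.testing.assert_allclose(
                recovered.loc[names, names].to_numpy(), D.to_numpy(), atol=1e-9
            )
            all_leaves = frozenset(names)
            canon_true = {
                min(s, frozenset(all_leaves - s), key=sorted) for s in true_splits
            }
            assert tree_splits(tree, all_leaves) == canon_true

    def test_identical_profiles_zero_length_cherry(self):
        D = pd.DataFrame(
            [[0, 0, 4], [0, 0, 4], [4, 4, 0]],
            index=["a", "b", "c"], columns=["a", "b", "c"], dtype=float,
        )
        tree = nj_tree(D)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == 0.0 and lengths["b"] == 0.0

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(InvalidDistanceError):
            nj_tree(D)

    def test_too_few_taxa_rejected(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"),
                         dtype=float)
        with pytest.raises(InvalidDistanceError):
            nj_tree(D)

    def test_branch_lengths_nonnegative_on_nonadditive_input(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            M = rng.uniform(1, 10, size=(5, 5))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            D = pd.DataFrame(D, index=list("abcde"), columns=list("abcde"))
            tree = nj_tree(D)

            def check(node):
                assert node.length >= 0
                for c in node.children:
                    check(c)

            check(tree)


class TestRooting:
    @pytest.fixture
    def tree(self):
        D = pd.DataFrame(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
            index=["A", "B", "C", "normal"], columns=["A", "B", "C", "normal"],
            dtype=float,
        )
        return nj_tree(D)

    def test_normal_is_root_child(self, tree):
        rooted = root_tree(tree)
        assert rooted.children[0].name == "normal"

    def test_rerooting_idempotent(self, tree):
        r1 = root_tree(tree)
        r2 = root_tree(r1)
        assert to_newick(r1) == to_newick(r2)

    def test_path_distances_preserved_by_rooting(self, tree):
        before = leaf_distances(tree)
        after = leaf_distances(root_tree(tree))
        np.testing.assert_allclose(
            before.to_numpy(), after.loc[before.index, before.columns].to_numpy(),
            atol=1e-9,
        )

    def test_missing_normal_leaf_rejected(self):
        D = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        with pytest.raises(RootAnchorError):
            root_tree(nj_tree(D))


class TestNewick:
    def test_roundtrip_lossless(self):
        D = pd.DataFrame(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
            index=["A", "B", "C", "normal"], columns=["A", "B", "C", "normal"],
            dtype=float,
        )
        rooted = root_tree(nj_tree(D))
        nwk = to_newick(rooted)
        assert to_newick(parse_newick(nwk)) == nwk

    def test_roundtrip_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        D = pd.DataFrame(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
            index=["A", "B", "C", "normal"], columns=["A", "B", "C", "normal"],
            dtype=float,
        )
        rooted = root_tree(nj_tree(D))
        nwk = to_newick(rooted)
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in dt.leaf_node_iter()} == {"A", "B", "C", "normal"}
        pdm = dt.phylogenetic_distance_matrix()
        mine = leaf_distances(rooted)
        for t1 in pdm.taxon_iter():
            for t2 in pdm.taxon_iter():
                assert pdm.distance(t1, t2) == pytest.approx(
                    mine.loc[t1.label, t2.label], abs=1e-6
                )


def _clone(cid, cells, consensus, regions=None):
    return Clone(
        clone_id=cid, cells=cells, consensus=np.asarray(consensus),
        is_normal=bool((np.asarray(consensus) == 2).all()),
        region_counts=regions or {},
    )


class _FakeEvent:
    def __init__(self, key):
        self._key = key
        self.chrom = key[0]

    def key(self):
        return self._key


class _FakeAnnotated:
    kind = "cnv"

    def __init__(self, key, presence):
        self.event = _FakeEvent(key)
        self.clone_presence = presence


class TestClassifyEvolution:
    def _tree(self, newick):
        return parse_newick(newick)

    def test_single_clone_no_evolution(self):
        clones = [_clone("A", ["c1", "c2"], [3, 2])]
        tree = self._tree("(normal:1,A:1);")
        call = classify_evolution(clones, tree, [])
        assert call.mode == "no_evolution"

    def test_two_siblings_shared_and_private_punctuated(self):
        clones = [
            _clone("A", ["a1"], [3, 1, 3, 2]),
            _clone("B", ["b1"], [3, 1, 2, 1]),
        ]
        tree = self._tree("(normal:5,(A:1,B:1):3);")
        events = [
            _FakeAnnotated(("chr1", 0, 10, 3), {"A": True, "B": True}),
            _FakeAnnotated(("chr2", 0, 10, 1), {"A": True, "B": True}),
            _FakeAnnotated(("chr3", 0, 10, 3), {"A": True, "B": False}),
            _FakeAnnotated(("chr4", 0, 10, 1), {"A": False, "B": True}),
        ]
        call = classify_evolution(clones, tree, events)
        assert call.mode == "punctuated"
        assert call.evidence["n_shared_events"] == 2

    def test_nested_event_sets_gradual(self):
        clones = [
            _clone("A", ["a1"], [3, 2, 2]),
            _clone("B", ["b1"], [3, 1, 2]),
            _clone("C", ["c1"], [3, 1, 4]),
        ]
        tree = self._tree("(normal:5,(A:1,(B:1,C:1):1):3);")
        events = [
            _FakeAnnotated(("chr1", 0, 10, 3), {"A": True, "B": True, "C": True}),
            _FakeAnnotated(("chr2", 0, 10, 1), {"A": False, "B": True, "C": True}),
            _FakeAnnotated(("chr3", 0, 10, 4), {"A": False, "B": False, "C": True}),
        ]
        call = classify_evolution(clones, tree, events)
        assert call.mode == "gradual_branching"
        assert call.evidence["nesting"]

    def test_lost_event_detected_as_nonconvex_carriers(self):
        clones = [
            _clone("A", ["a1"], [1, 2, 2]),
            _clone("B", ["b1"], [1, 3, 2]),
            _clone("C", ["c1"], [2, 3, 3]),
        ]
        tree = self._tree("(normal:5,(A:1,(B:1,C:1):1):3);")
        events = [
            # carried by A and B but lost in C (carriers {A,B} not a subtree)
            _FakeAnnotated(("chr1", 0, 10, 1), {"A": True, "B": True, "C": False}),
            _FakeAnnotated(("chr2", 0, 10, 3), {"A": False, "B": True, "C": True}),
            _FakeAnnotated(("chr3", 0, 10, 3), {"A": False, "B": False, "C": True}),
        ]
        call = classify_evolution(clones, tree, events)
        assert call.mode == "gradual_branching"
        assert call.evidence["lost_events"] == [("chr1", 0, 10, 1)]


class TestFishplot:
    def test_single_clone_earlier_equals_later(self):
        clones = [
            _clone("A", ["c1"] * 9, [3], {"r1": 9}),
            _clone("N", ["n1"], [2], {"r1": 1}),
        ]
        clones[1].is_normal = True
        tree = parse_newick("(normal:1,A:1);")
        tab = fishplot_table(clones, tree)
        later_a = tab.query("clone=='A' and timepoint=='Later'")["fraction"].iloc[0]
        earlier_a = tab.query("clone=='A' and timepoint=='Earlier'")["fraction"].iloc[0]
        assert later_a == earlier_a == pytest.approx(0.9)

    def test_two_siblings_collapse_to_ancestor(self):
        clones = [
            _clone("A", ["a"] * 6, [3, 2], {"r1": 6}),
            _clone("B", ["b"] * 4, [2, 3], {"r1": 4}),
        ]
        tree = parse_newick("(normal:1,(A:1,B:1):1);")
        tab = fishplot_table(clones, tree)
        earlier = tab.query("timepoint=='Earlier'")
        assert set(earlier["clone"]) == {"ancestor", "normal"}
        assert earlier.query("clone=='ancestor'")["fraction"].iloc[0] == pytest.approx(1.0)
        later = tab.query("timepoint=='Later'").set_index("clone")["fraction"]
        assert later["A"] == pytest.approx(0.6)
        assert later["B"] == pytest.approx(0.4)

    def test_nested_chain_collapses_to_head_clone(self):
        clones = [
            _clone("A", ["a"] * 5, [3, 2, 2], {"r1": 5}),
            _clone("B", ["b"] * 3, [3, 1, 2], {"r1": 3}),
            _clone("C", ["c"] * 2, [3, 1, 4], {"r1": 2}),
        ]
        tree = parse_newick("(normal:1,(A:1,(B:1,C:1):1):1);")
        tab = fishplot_table(clones, tree)
        earlier = tab.query("timepoint=='Earlier'").set_index("clone")["fraction"]
        assert earlier["A"] == pytest.approx(1.0)
        later = tab.query("timepoint=='Later'").set_index("clone")["fraction"]
        assert later.loc[["A", "B", "C"]].tolist() == pytest.approx([0.5, 0.3, 0.2])

    def test_columns_sum_to_one(self):
        clones = [
            _clone("A", ["a"] * 5, [3], {"r1": 3, "r2": 2}),
            _clone("B", ["b"] * 3, [1], {"r1": 1, "r2": 2}),
            _clone("N", ["n"] * 2, [2], {"r1": 1, "r2": 1}),
        ]
        clones[2].is_normal = True
        tree = parse_newick("(normal:1,(A:1,B:1):1);")
        tab = fishplot_table(clones, tree)
        sums = tab.groupby(["region", "timepoint"])["fraction"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0)


def test_simulated_tree_separates_clones(three_clone_run):
    """NJ on inferred consensus profiles keeps every clone a distinct taxon
    attached below the diploid root."""
    rep = three_clone_run["report"]
    tree = rep.tree
    leaf_names = set(tree.leaf_names())
    assert "normal" in leaf_names
    clone_ids = {c.clone_id for c in rep.clones if not c.is_normal}
    assert clone_ids <= leaf_names
    assert tree.children[0].name == "normal"
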