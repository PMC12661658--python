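"""Leiden/CPM communities, tree reconciliation, RF pruning, polytomies."""

import numpy as np
import pytest
from oracles import cpm_optimum, polytomy_optimum, reconciliation_optimum

from clefam import hierarchy
from clefam.graph import SimilarityGraph
from clefam.hierarchy import HierarchyTree, Partition, TreeNode


def two_triangles():
    g = SimilarityGraph()
    for group in (["a", "b", "c"], ["x", "y", "z"]):
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(group[i], group[j], 1.0)
    return g


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    g = SimilarityGraph([f"n{i}" for i in range(n)])
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", float(rng.uniform(0.1, 2.0)))
    return g


class TestCpm:
    def test_two_cliques_recovered(self):
        g = two_triangles()
        part = hierarchy.multires_communities(g, [0.5])[0]
        comms = sorted(part.communities().values(), key=min)
        assert comms == [{"a", "b", "c"}, {"x", "y", "z"}]

    def test_large_gamma_singletons(self):
        g = two_triangles()
        part = hierarchy.multires_communities(g, [100.0])[0]
        assert all(len(c) == 1 for c in part.communities().values())

    def test_tiny_gamma_connected_components(self):
        g = two_triangles()
        part = hierarchy.multires_communities(g, [1e-9])[0]
        comms = sorted(part.communities().values(), key=min)
        assert comms == [{"a", "b", "c"}, {"x", "y", "z"}]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_optimum(self, seed):
        g = random_graph(6, 0.5, seed)
        for gamma in (0.2, 0.8):
            part = hierarchy.multires_communities(g, [gamma], seed=seed)[0]
            q = hierarchy.cpm_quality(g, part.assignment, gamma)
            assert q == pytest.approx(cpm_optimum(g, gamma), abs=1e-9)

    def test_empty_resolution_list(self):
        with pytest.raises(ValueError):
            hierarchy.multires_communities(two_triangles(), [])

    def test_default_ladder_ascending(self):
        ladder = hierarchy.default_resolution_ladder(two_triangles())
        assert len(ladder) == 6
        assert ladder == sorted(ladder)
        assert all(g > 0 for g in ladder)


def nested_partitions():
    coarse = Partition(0.1, {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1})
    fine = Partition(1.0, {"a": 0, "b": 0, "c": 1, "d": 2, "e": 2, "f": 3})
    return [coarse, fine]


class TestReconcile:
    def test_nested_input_is_fixed_point(self):
        tree = hierarchy.reconcile_tree(nested_partitions())
        tree.validate_nested()
        assert tree.n_reassignments == 0
        leaf_sets = sorted((sorted(n.members) for n in tree.leaves()))
        assert leaf_sets == [["a", "b"], ["c"], ["d", "e"], ["f"]]
        level1 = sorted(sorted(c.members) for c in tree.root.children)
        assert level1 == [["a", "b", "c"], ["d", "e", "f"]]

    def test_single_partition_two_levels(self):
        p = Partition(1.0, {"a": 0, "b": 0, "c": 1})
        tree = hierarchy.reconcile_tree([p])
        assert {frozenset(c.members) for c in tree.root.children} == {
            frozenset({"a", "b"}), frozenset({"c"})}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hierarchy.reconcile_tree([])

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="same gene set"):
            hierarchy.reconcile_tree([Partition(0.1, {"a": 0}),
                                      Partition(1.0, {"b": 0})])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_near_nested_matches_brute_force(self, seed):
        """Flipping one or two genes between otherwise nested layers: the
        reconciled cost equals the exhaustive minimum over leaf partitions."""
        rng = np.random.default_rng(seed)
        genes = list("abcdefg")
        coarse = {g: (0 if g < "d" else 1) for g in genes}
        fine = {"a": 0, "b": 0, "c": 1, "d": 2, "e": 2, "f": 3, "g": 3}
        for g in rng.choice(genes, size=rng.integers(1, 3), replace=False):
            fine[g] = int(rng.integers(0, 4))
        parts = [Partition(0.1, coarse), Partition(1.0, fine)]
        tree = hierarchy.reconcile_tree(parts)
        tree.validate_nested()
        assert tree.n_reassignments == reconciliation_optimum(parts)

    def test_non_nested_input_still_nested_output(self):
        # layers in outright conflict
        parts = [Partition(0.1, {"a": 0, "b": 0, "c": 1, "d": 1}),
                 Partition(1.0, {"a": 0, "b": 1, "c": 0, "d": 1})]
        tree = hierarchy.reconcile_tree(parts)
        tree.validate_nested()

    def test_validate_nested_catches_overlap(self):
        root = TreeNode("r", 0, frozenset({"a", "b"}))
        root.children = [TreeNode("x", 1, frozenset({"a"})),
                         TreeNode("y", 1, frozenset({"a", "b"}))]
        with pytest.raises(ValueError, match="overlap"):
            HierarchyTree(root=root).validate_nested()

    def test_newick_and_json(self):
        tree = hierarchy.reconcile_tree(nested_partitions())
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        assert "L1_C" in nwk
        js = tree.to_json()
        assert '"members"' in js


def flat_tree(groups: dict[str, list[str]]) -> HierarchyTree:
    members = frozenset(g for mem in groups.values() for g in mem)
    root = TreeNode("root", 0, members)
    for gid, mem in sorted(groups.items()):
        root.children.append(TreeNode(gid, 1, frozenset(mem)))
    t = HierarchyTree(root=root)
    t.validate_nested()
    return t


class TestPruneSistersRF:
    def motifs_for(self, prefix, motif, n):
        return {f"{prefix}{i}": motif for i in range(n)}

    def test_identical_multisets_usually_merge(self):
        base = ["RTVPSGPDPLHH", "RTVPSGPDPLHY", "RTVPSGPDPLHW"] * 2
        motifs = {}
        for i, m in enumerate(base):
            motifs[f"a{i}"] = m
            motifs[f"b{i}"] = m
        tree = flat_tree({"A": sorted(k for k in motifs if k[0] == "a"),
                          "B": sorted(k for k in motifs if k[0] == "b")})
        merges = 0
        for seed in range(20):
            pruned = hierarchy.prune_sisters_rf(tree, motifs, n_perm=99,
                                                seed=seed, n_estimators=50)
            merges += len(pruned.leaves()) == 1
        assert merges >= 16          # nominal >= 95% merge rate

    def test_fully_distinct_never_merge(self):
        motifs = {f"a{i}": "A" * 12 for i in range(6)}
        motifs.update({f"b{i}": "C" * 12 for i in range(6)})
        tree = flat_tree({"A": sorted(k for k in motifs if k[0] == "a"),
                          "B": sorted(k for k in motifs if k[0] == "b")})
        for seed in range(5):
            pruned = hierarchy.prune_sisters_rf(tree, motifs, n_perm=99,
                                                seed=seed, n_estimators=50)
            assert len(pruned.leaves()) == 2

    def test_alpha_one_merges_everything(self):
        motifs = {f"g{i}": "A" * 12 for i in range(6)}
        tree = flat_tree({"A": ["g0", "g1"], "B": ["g2", "g3"],
                          "C": ["g4", "g5"]})
        pruned = hierarchy.prune_sisters_rf(tree, motifs, alpha=1.0, seed=0)
        assert pruned.root.is_leaf()

    def test_singleton_leaf_auto_merges(self, caplog):
        motifs = {"solo": "A" * 12}
        motifs.update({f"b{i}": "C" * 12 for i in range(4)})
        tree = flat_tree({"A": ["solo"], "B": sorted(k for k in motifs
                                                     if k[0] == "b")})
        import logging
        with caplog.at_level(logging.INFO, logger="clefam.hierarchy"):
            pruned = hierarchy.prune_sisters_rf(tree, motifs, n_perm=19, seed=0)
        assert len(pruned.leaves()) == 1
        assert "auto-merging" in caplog.text

    def test_input_tree_untouched(self):
        motifs = {f"g{i}": "A" * 12 for i in range(4)}
        tree = flat_tree({"A": ["g0", "g1"], "B": ["g2", "g3"]})
        hierarchy.prune_sisters_rf(tree, motifs, alpha=1.0, seed=0)
        assert len(tree.leaves()) == 2


class TestPolytomy:
    def test_identical_compositions_deterministic(self):
        children = {f"c{i}": ["RTVPSGPDPLHH"] * 2 for i in range(4)}
        s1 = hierarchy.resolve_polytomy_entropy(children)
        s2 = hierarchy.resolve_polytomy_entropy(children)
        assert s1 == s2

    def test_glycine_children_merge_first(self):
        children = {"g1": ["G" * 12], "g2": ["G" * 12], "s": ["S" * 12]}
        shape, obj = hierarchy.resolve_polytomy_entropy(children)
        assert shape == (("g1", "g2"), "s")

    def test_exhaustive_matches_independent_oracle(self):
        rng = np.random.default_rng(0)
        from clefam import aa
        for _ in range(10):
            m = int(rng.integers(3, 7))
            children = {
                f"c{i}": ["".join(aa.ALPHABET[j] for j in rng.integers(0, 20, 12))
                          for _ in range(int(rng.integers(1, 4)))]
                for i in range(m)
            }
            _, obj = hierarchy.resolve_polytomy_entropy(children)
            assert obj == pytest.approx(polytomy_optimum(children), abs=1e-9)

    def test_greedy_never_beats_exhaustive(self):
        rng = np.random.default_rng(1)
        from clefam import aa
        for _ in range(5):
            children = {
                f"c{i}": ["".join(aa.ALPHABET[j] for j in rng.integers(0, 20, 12))
                          for _ in range(2)]
                for i in range(6)
            }
            _, exact = hierarchy.resolve_polytomy_entropy(children,
                                                          exhaustive_limit=6)
            _, greedy = hierarchy.resolve_polytomy_entropy(children,
                                                           exhaustive_limit=2)
            assert greedy >= exact - 1e-9

    def test_too_few_children(self):
        with pytest.raises(ValueError):
            hierarchy.resolve_polytomy_entropy({"a": ["G" * 12], "b": ["G" * 12]})
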