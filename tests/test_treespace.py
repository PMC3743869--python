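import itertools

import dendropy
import networkx as nx
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage

import phylomorph as pm
from phylomorph.matrices import DistanceMatrix

from conftest import random_distance_matrix


# ----------------------------------------------------------------------
# UPGMA
# ----------------------------------------------------------------------

def naive_upgma(dm: DistanceMatrix):
    """Definitional oracle: recompute average cross-cluster distances from
    the original matrix at every step (no Lance-Williams update)."""
    clusters = [frozenset([l]) for l in dm.labels]
    idx = {l: i for i, l in enumerate(dm.labels)}
    heights = {c: 0.0 for c in clusters}
    history = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([dm.values[idx[x], idx[y]] for x in a for y in b])
            key = (d, tuple(sorted((tuple(sorted(a)), tuple(sorted(b))))))
            if best is None or key < best[0]:
                best = (key, (a, b))
        (d, _), (a, b) = best
        merged = a | b
        history.append((tuple(sorted(a)), tuple(sorted(b)), d / 2.0))
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
        heights[merged] = d / 2.0
    return history


class TestAverageLinkage:
    def test_hand_worked_three_taxa(self):
        d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float))
        history = pm.treespace.upgma_merge_history(d)
        assert history[0] == (("A",), ("B",), 1.0)
        assert history[1][2] == pytest.approx(4.0)
        coph = pm.cophenetic_matrix(pm.average_linkage_tree(d))
        assert coph[("A", "C")] == pytest.approx(8.0)
        assert coph[("A", "B")] == pytest.approx(2.0)

    def test_two_labels_single_merge_at_half_distance(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 3.0], [3.0, 0]]))
        history = pm.treespace.upgma_merge_history(d)
        assert history == [(("A",), ("B",), 1.5)]

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_naive_oracle_on_random_matrices(self, n):
        rng = np.random.default_rng(100 + n)
        for rep in range(50):
            dm = random_distance_matrix(n, rng)
            fast = pm.treespace.upgma_merge_history(dm)
            slow = naive_upgma(dm)
            for (fl, fr, fh), (sl, sr, sh) in zip(fast, slow):
                assert {fl, fr} == {sl, sr}
                assert fh == pytest.approx(sh, rel=1e-10)

    def test_cophenetic_matches_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            dm = random_distance_matrix(6, rng)
            coph = pm.cophenetic_matrix(pm.average_linkage_tree(dm))
            Z = linkage(dm.condensed(), method="average")
            from scipy.spatial.distance import squareform

            expected = squareform(cophenet(Z))
            np.testing.assert_allclose(coph.values, expected, rtol=1e-9)

    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(7)
        dm = random_distance_matrix(8, rng)
        coph = pm.cophenetic_matrix(pm.average_linkage_tree(dm)).values
        for i, j, k in itertools.combinations(range(8), 3):
            trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert trio[2] == pytest.approx(trio[1], rel=1e-9)

    def test_nan_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], vals)

    def test_cluster_labels_recover_blocks(self):
        # two tight blocks far apart
        n = 6
        vals = np.full((n, n), 10.0)
        vals[:3, :3] = 1.0
        vals[3:, 3:] = 1.0
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix([f"x{i}" for i in range(n)], vals)
        labels = pm.cluster_labels(dm, 2)
        assert len({labels[f"x{i}"] for i in range(3)}) == 1
        assert labels["x0"] != labels["x5"]


# ----------------------------------------------------------------------
# Topological distances
# ----------------------------------------------------------------------

def _random_binary_newick(n_leaves: int, rng: np.random.Generator) -> str:
    items = [f"T{i}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return items[0] + ";"


def _bfs_leaf_distances(tree: dendropy.Tree) -> dict:
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            g.add_edge(id(node), id(child))
    leaves = {l.taxon.label: id(l) for l in tree.leaf_node_iter()}
    out = {}
    for a in leaves:
        lengths = nx.single_source_shortest_path_length(g, leaves[a])
        for b in leaves:
            if a < b:
                out[(a, b)] = lengths[leaves[b]]
    return out


class TestTopologicalDistances:
    def test_balanced_four_leaves(self):
        td = pm.topological_distances(pm.read_newick("((A,B),(C,D));"))
        assert td[("A", "B")] == 2
        assert td[("A", "C")] == 4

    def test_caterpillar(self):
        td = pm.topological_distances(pm.read_newick("(((A,B),C),D);"))
        assert td[("A", "D")] == 4
        assert td[("C", "D")] == 3

    def test_branch_length_invariance(self):
        t1 = pm.read_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        t2 = pm.read_newick("((A:9,B:1):7,C:2);")
        np.testing.assert_array_equal(
            pm.topological_distances(t1).values, pm.topological_distances(t2).values)

    def test_matches_bfs_oracle_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(3, 13))
            tree = pm.read_newick(_random_binary_newick(n, rng))
            td = pm.topological_distances(tree)
            oracle = _bfs_leaf_distances(tree)
            for (a, b), expected in oracle.items():
                assert td[(a, b)] == expected

    def test_max_distance_bound_binary_tree(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            td = pm.topological_distances(pm.read_newick(_random_binary_newick(n, rng)))
            assert td.values.max() <= 2 * (n - 1)

    def test_entries_are_integers_at_least_two(self):
        rng = np.random.default_rng(2)
        td = pm.topological_distances(pm.read_newick(_random_binary_newick(8, rng)))
        off = td.condensed()
        np.testing.assert_array_equal(off, np.round(off))
        assert off.min() >= 2


# ----------------------------------------------------------------------
# Allele collapsing
# ----------------------------------------------------------------------

class TestCollapseAlleleDistances:
    def test_all_homozygous_is_a_relabeling(self):
        rng = np.random.default_rng(3)
        d = random_distance_matrix(4, rng, labels=["a", "b", "c", "d"])
        out = pm.collapse_allele_distances(d, {x.upper(): [x] for x in "abcd"})
        assert out.labels == ["A", "B", "C", "D"]
        np.testing.assert_allclose(out.values, d.values)

    def test_het_vs_hom_duplication_average(self):
        # het {x1,x2} vs hom {y}: entries 4 and 6 -> mean of (4,4,6,6) = 5
        labels = ["x1", "x2", "y"]
        vals = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float)
        d = DistanceMatrix(labels, vals)
        out = pm.collapse_allele_distances(d, {"X": ["x1", "x2"], "Y": ["y"]})
        assert out[("X", "Y")] == pytest.approx(5.0)
        assert np.all(np.diag(out.values) == 0)
        np.testing.assert_allclose(out.values, out.values.T)

    def test_unmapped_allele_errors(self):
        rng = np.random.default_rng(4)
        d = random_distance_matrix(3, rng, labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="not mapped"):
            pm.collapse_allele_distances(d, {"A": ["a"], "B": ["b"]})


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

class TestNewick:
    def test_roundtrip_topology(self):
        tree = pm.read_newick("((A,B),(C,D));")
        again = pm.read_newick(pm.write_newick(tree))
        np.testing.assert_array_equal(
            pm.topological_distances(tree).values,
            pm.topological_distances(again).values)

    def test_branch_lengths_preserved(self):
        text = "((A:0.1,B:0.2):0.05,C:0.3);"
        tree = pm.read_newick(text)
        again = pm.read_newick(pm.write_newick(tree))
        c1 = pm.cophenetic_matrix(tree)
        c2 = pm.cophenetic_matrix(again)
        np.testing.assert_allclose(c1.values, c2.values, rtol=1e-9)
        assert c1[("A", "B")] == pytest.approx(0.3)

    def test_unbalanced_parentheses_error(self):
        with pytest.raises(ValueError, match="parse"):
            pm.read_newick("((A,B);")

    def test_duplicate_leaves_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            pm.read_newick("((A,A),B);")
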