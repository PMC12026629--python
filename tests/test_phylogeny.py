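import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import path_distance_matrix, random_binary_tree, unrooted_splits

from mitokit import phylogeny as ph
from mitokit.phylogeny import (
    DistanceMatrix,
    NewickParseError,
    PhyloTree,
    Supermatrix,
    TreeNode,
    concat_supermatrix,
    is_monophyletic,
    neighbor_joining,
    p_distance_matrix,
    read_newick,
    root_with_outgroup,
    write_newick,
)


class TestSupermatrix:
    def test_concatenation_and_partition_spans(self):
        sm = concat_supermatrix(
            {
                "g1": {"A": "A" * 10, "B": "C" * 10, "C": "G" * 10},
                "g2": {"A": "T" * 20, "B": "G" * 20, "C": "A" * 20},
            }
        )
        assert sm.n_columns == 30
        assert sm.partitions == {"g1": (1, 10), "g2": (11, 30)}
        assert all(len(row) == 30 for row in sm.rows.values())

    def test_missing_taxon_is_gap_filled(self):
        sm = concat_supermatrix(
            {"g1": {"A": "AAAA", "B": "CCCC"}, "g2": {"A": "TTTTT"}}
        )
        assert sm.rows["B"] == "CCCC" + "-" * 5

    def test_ragged_gene_rejected(self):
        with pytest.raises(ValueError, match="g1"):
            concat_supermatrix({"g1": {"A": "AAA", "B": "AAAA"}})

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=6))
    def test_partitions_always_tile_the_columns(self, lengths):
        aln = {
            f"g{i}": {"A": "A" * n, "B": "C" * n} for i, n in enumerate(lengths)
        }
        sm = concat_supermatrix(aln)
        covered = []
        for start, end in sm.partitions.values():
            covered.extend(range(start, end + 1))
        assert sorted(covered) == list(range(1, sm.n_columns + 1))


class TestPDistance:
    def test_identical_rows(self):
        sm = Supermatrix(["A", "B"], {"A": "ACGT", "B": "ACGT"}, {"g": (1, 4)})
        assert p_distance_matrix(sm).get("A", "B") == 0.0

    def test_single_mismatch(self):
        sm = Supermatrix(["A", "B"], {"A": "AAAA", "B": "AAAT"}, {"g": (1, 4)})
        assert p_distance_matrix(sm).get("A", "B") == 0.25

    def test_matches_columnwise_brute_force(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            n, L = int(rng.integers(2, 6)), int(rng.integers(5, 40))
            rows = {
                f"t{i}": "".join(rng.choice(list("ACGT-"), size=L))
                for i in range(n)
            }
            try:
                dm = p_distance_matrix(Supermatrix(list(rows), rows, {"g": (1, L)}))
            except ValueError:
                continue  # a pair with no comparable columns
            for i, a in enumerate(rows):
                for b in list(rows)[i + 1 :]:
                    diffs = comp = 0
                    for x, y in zip(rows[a], rows[b]):
                        if x in "-?" or y in "-?":
                            continue
                        comp += 1
                        diffs += x != y
                    assert dm.get(a, b) == pytest.approx(diffs / comp)

    def test_gap_only_overlap_raises(self):
        sm = Supermatrix(
            ["A", "B"], {"A": "AC--", "B": "--GT"}, {"g": (1, 4)}
        )
        with pytest.raises(ValueError, match="no comparable columns"):
            p_distance_matrix(sm)

    def test_poisson_correction(self):
        sm = Supermatrix(["A", "B"], {"A": "AAAA", "B": "AAAT"}, {"g": (1, 4)})
        d = p_distance_matrix(sm, poisson_correction=True).get("A", "B")
        assert d == pytest.approx(-math.log(0.75))


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        """NJ on the path-distance matrix of ((A:1,B:2):5,C:3,D:4) returns
        exactly that topology and those branch lengths."""
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))
        assert write_newick(tree) == "(C:3,D:4,(A:1,B:2):5);"

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_consistency_on_random_additive_matrices(self):
        """The generating topology is recovered for every additive matrix
        from random binary trees (4-8 leaves)."""
        rng = np.random.default_rng(7)
        for i in range(20):
            n = 4 + i % 5
            true = random_binary_tree(rng, n)
            dm = path_distance_matrix(true)
            est = neighbor_joining(dm)
            assert unrooted_splits(est) == unrooted_splits(true)

    def test_ultrametric_matrix_matches_clustering_truth(self):
        """On an ultrametric 8-taxon matrix NJ agrees with the hierarchy
        that generated it."""
        rng = np.random.default_rng(13)
        # random ultrametric hierarchy: merge at strictly increasing heights
        nodes = [TreeNode(name=f"t{i}") for i in range(8)]
        heights = {id(n): 0.0 for n in nodes}
        h = 0.0
        while len(nodes) > 1:
            h += float(rng.uniform(0.2, 1.0))
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            a, b = nodes[i], nodes[j]
            a.length = h - heights[id(a)]
            b.length = h - heights[id(b)]
            parent = TreeNode(children=[a, b])
            heights[id(parent)] = h
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
        truth = PhyloTree(root=nodes[0], rooted=True)
        est = neighbor_joining(path_distance_matrix(truth))
        assert unrooted_splits(est) == unrooted_splits(truth)

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check against scikit-bio's NJ on noisy (still
        tree-like) matrices."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(42)
        for _ in range(5):
            true = random_binary_tree(rng, 6)
            m = path_distance_matrix(true)
            noise = rng.uniform(0.99, 1.01, size=m.matrix.shape)
            noisy = m.matrix * (noise + noise.T) / 2
            np.fill_diagonal(noisy, 0)
            mine = neighbor_joining(DistanceMatrix(m.taxa, noisy))
            sk_tree = sk_nj(SkDM(noisy, ids=m.taxa))
            theirs = read_newick(str(sk_tree))
            assert unrooted_splits(mine) == unrooted_splits(theirs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)


class TestRooting:
    def _tree(self):
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
            dtype=float,
        )
        return neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], d))

    def test_outgroup_is_sister_to_the_rest(self):
        rooted = root_with_outgroup(self._tree(), "D")
        assert rooted.rooted
        kids = rooted.root.children
        assert {frozenset(k.leaf_names()) for k in kids} == {
            frozenset({"D"}), frozenset({"A", "B", "C"}),
        }

    def test_rerooting_is_idempotent(self):
        r1 = root_with_outgroup(self._tree(), "D")
        r2 = root_with_outgroup(r1, "D")
        assert unrooted_splits(r1) == unrooted_splits(r2)

    def test_path_lengths_preserved(self):
        unrooted = self._tree()
        rooted = root_with_outgroup(unrooted, "D")
        before = path_distance_matrix(unrooted)
        after = path_distance_matrix(rooted)
        assert np.allclose(before.matrix, after.matrix)

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(KeyError):
            root_with_outgroup(self._tree(), "Z")


class TestMonophyly:
    def test_simple_clades(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_unknown_taxon_rejected(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(KeyError):
            is_monophyletic(t, {"A", "Z"})

    def test_agrees_with_clade_enumeration_on_random_trees(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            tree = random_binary_tree(rng, 10)
            clades = {node.leaf_names() for node in tree.root.walk()}
            leaves = sorted(tree.leaf_names())
            for _q in range(10):
                k = int(rng.integers(1, 10))
                query = frozenset(rng.choice(leaves, size=k, replace=False))
                assert is_monophyletic(tree, query) == (query in clades)

    def test_invariant_to_child_rotation(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        for node in t.root.walk():
            node.children = list(reversed(node.children))
        assert is_monophyletic(t, {"C", "D"})


class TestNewick:
    def test_round_trip(self):
        s = "((A:1,B:2):0.5,C:3);"
        assert write_newick(read_newick(s)) == s

    def test_underscores_preserved(self):
        t = read_newick("((Caridina_mariae:1,Caridina_gracilipes:2):0.5,Harpiosquilla_harpax:3);")
        assert "Caridina_mariae" in t.leaf_names()

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = random_binary_tree(rng, int(rng.integers(3, 12)))
            s = write_newick(t)
            back = read_newick(s)
            assert write_newick(back) == s
            assert unrooted_splits(back) == unrooted_splits(t)

    def test_unbalanced_parentheses_report_position(self):
        with pytest.raises(NewickParseError, match="position"):
            read_newick("((A:1,B:2):0.5,C:3));")
        with pytest.raises(NewickParseError):
            read_newick("(((A:1,B:2):0.5,C:3);")
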