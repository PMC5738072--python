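from functools import lru_cache

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from gliascan.phylo import (
    cluster_purity,
    global_align,
    neighbor_joining,
    p_distance,
    protein_distance_matrix,
    read_newick,
    write_newick,
)


def _brute_align_score(s1, s2, match=1.0, mismatch=0.0, gap=-1.0):
    """Exhaustive enumeration over all global alignments."""

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == 0 and j == 0:
            return 0.0
        best = -1e18
        if i and j:
            best = max(best, f(i - 1, j - 1)
                       + (match if s1[i - 1] == s2[j - 1] else mismatch))
        if i:
            best = max(best, f(i - 1, j) + gap)
        if j:
            best = max(best, f(i, j - 1) + gap)
        return best

    return f(len(s1), len(s2))


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Rooting-invariant non-trivial bipartitions (one canonical side)."""
    leaves = frozenset(l.name for l in tree.tips())
    out = set()
    for node in tree.traverse(include_self=False):
        side = frozenset(l.name for l in node.tips()) or frozenset({node.name})
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(side, leaves - side, key=sorted))
    return out


def _random_additive(n, rng):
    """A random binary tree with positive branch lengths and its
    leaf-to-leaf distance matrix (additive by construction)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode()
        parent.extend([a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for x in nodes:
        x.length = float(rng.uniform(0.1, 2.0))
    root.extend(nodes)
    names = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            D[x, y] = D[y, x] = root.find(names[x]).distance(root.find(names[y]))
    return DistanceMatrix(D, names), root


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        a1, a2, score = global_align("QPFL", "QPFL")
        assert (a1, a2) == ("QPFL", "QPFL")
        assert score == 4.0

    def test_one_gap_case(self):
        a1, a2, score = global_align("QQQ", "QQ")
        assert score == 2 * 1 + (-1)  # two matches, one gap
        assert a1.replace("-", "") == "QQQ"
        assert a2.replace("-", "") == "QQ"
        assert len(a1) == len(a2)
        assert a2.count("-") == 1

    def test_gap_removal_restores_inputs(self):
        a1, a2, _ = global_align("QLPFSQ", "QPFFQ")
        assert a1.replace("-", "") == "QLPFSQ"
        assert a2.replace("-", "") == "QPFFQ"

    def test_score_equals_brute_force_on_short_random_pairs(self):
        rng = np.random.default_rng(11)
        letters = list("QPLF")
        for _ in range(150):
            s1 = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            s2 = "".join(rng.choice(letters, size=int(rng.integers(1, 9))))
            _, _, score = global_align(s1, s2)
            assert score == pytest.approx(_brute_align_score(s1, s2))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "Q")


class TestPDistance:
    def test_identical(self):
        assert p_distance("QQQQQQQQQQ", "QQQQQQQQQQ") == 0.0

    def test_one_substitution_in_ten(self):
        assert p_distance("QQQQQQQQQQ", "QQQQQQQQQL") == pytest.approx(0.1)

    def test_gap_columns_excluded(self):
        assert p_distance("Q-QQ", "QPQQ") == 0.0

    def test_all_gap_comparison_rejected(self):
        with pytest.raises(ValueError):
            p_distance("Q-", "-Q")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("QQ", "QQQ")


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4))
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ["A", "B", "C", "D"],
        )
        res = neighbor_joining(dm)
        assert res.n_clamped == 0
        assert _bipartitions(res.tree) == {frozenset({"A", "B"})}
        for x in "ABCD":
            for y in "ABCD":
                if x < y:
                    assert res.tree.find(x).distance(res.tree.find(y)) == \
                        pytest.approx(dm[x, y])

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 4, 5], [4, 0, 7], [5, 7, 0]], ["a", "b", "c"])
        res = neighbor_joining(dm)
        lengths = {t.name: t.length for t in res.tree.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 3.0, "c": 4.0})

    def test_recovers_random_additive_trees_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            dm, true_tree = _random_additive(n, rng)
            res = neighbor_joining(dm)
            assert _bipartitions(res.tree) == _bipartitions(true_tree)
            for x in dm.ids:
                for y in dm.ids:
                    if x < y:
                        d = res.tree.find(x).distance(res.tree.find(y))
                        assert d == pytest.approx(dm[x, y], abs=1e-8)

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(19)
        dm, _ = _random_additive(7, rng)
        res = neighbor_joining(dm)
        perm = list(rng.permutation(list(dm.ids)))
        dm2 = dm.filter(perm)
        res2 = neighbor_joining(dm2)
        assert _bipartitions(res.tree) == _bipartitions(res2.tree)
        for x in dm.ids:
            for y in dm.ids:
                if x < y:
                    d1 = res.tree.find(x).distance(res.tree.find(y))
                    d2 = res2.tree.find(x).distance(res2.tree.find(y))
                    assert d1 == pytest.approx(d2, abs=1e-9)

    def test_agrees_with_reference_nj_on_noisy_matrix(self):
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        M = np.abs(rng.normal(1.0, 0.4, (7, 7)))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        dm = DistanceMatrix(M, list("ABCDEFG"))
        assert _bipartitions(neighbor_joining(dm).tree) == \
            _bipartitions(skbio_nj(dm))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_newick_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        dm, _ = _random_additive(6, rng)
        res = neighbor_joining(dm)
        path = tmp_path / "tree.nwk"
        write_newick(res.tree, path)
        back = read_newick(path)
        assert _bipartitions(back) == _bipartitions(res.tree)
        for x in dm.ids:
            for y in dm.ids:
                if x < y:
                    assert back.find(x).distance(back.find(y)) == pytest.approx(
                        res.tree.find(x).distance(res.tree.find(y)), abs=1e-6)


class TestClusterPurity:
    def test_synthetic_family_forms_three_pure_locus_clusters(self, default_family):
        _, genes, _ = default_family
        dm = protein_distance_matrix({g.gene_id: g.protein for g in genes})
        res = neighbor_joining(dm)
        report = cluster_purity(res.tree, {g.gene_id: g.locus for g in genes})
        assert [r.locus for r in report] == ["Gli-A2", "Gli-B2", "Gli-D2"]
        assert all(r.pure and not r.exceptions for r in report)

    def test_single_locus_input_trivially_pure(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 2], [2, 2, 0]], ["a", "b", "c"])
        res = neighbor_joining(dm)
        report = cluster_purity(res.tree, {"a": "L", "b": "L", "c": "L"})
        assert report[0].pure

    def test_misplaced_leaf_reported_by_name(self):
        # additive distances from ((a1,(a2,odd)),a3,(b1,b2)): the "B"
        # leaf "odd" is nested deep inside the A clade, so no edge
        # separates exactly the B leaves
        dm = DistanceMatrix(
            [
                [0, 2, 2, 3, 6, 6],
                [2, 0, 1, 3, 6, 6],
                [2, 1, 0, 3, 6, 6],
                [3, 3, 3, 0, 5, 5],
                [6, 6, 6, 5, 0, 2],
                [6, 6, 6, 5, 2, 0],
            ],
            ["a1", "a2", "odd", "a3", "b1", "b2"],
        )
        res = neighbor_joining(dm)
        labels = {"a1": "A", "a2": "A", "odd": "B", "a3": "A",
                  "b1": "B", "b2": "B"}
        strict = cluster_purity(res.tree, labels, allowed_exceptions=0)
        relaxed = cluster_purity(res.tree, labels, allowed_exceptions=1)
        by_locus = {r.locus: r for r in strict}
        assert not by_locus["B"].pure
        assert "odd" in by_locus["B"].exceptions
        assert all(r.pure for r in relaxed)

    def test_unassigned_leaf_rejected(self, default_family):
        _, genes, _ = default_family
        proteins = {g.gene_id: g.protein for g in genes[:4]}
        dm = protein_distance_matrix(proteins)
        res = neighbor_joining(dm)
        with pytest.raises(ValueError, match="without locus"):
            cluster_purity(res.tree, {genes[0].gene_id: "Gli-A2"})
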