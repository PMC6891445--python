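"""Distances, UPGMA/NJ construction, bootstrap, Newick, monophyly."""

import math

import numpy as np
import pytest

from amomarker.errors import DataError, SaturationError
from amomarker.phylo import (DistanceMatrix, TreeNode, bipartitions,
                             bootstrap, distance_matrix, is_monophyletic,
                             neighbor_joining, pairwise_distance,
                             parse_newick, upgma, write_newick)
from amomarker.seq_core import LocusAlignment, SeqRecord

# A 12-substitution pair whose corrected distances were frozen from an
# independent phylogenetics package run with identical model settings.
_PAIR_A = ("TGGTGTTAACCTTACTATACTCCCGCTCCGGGGTTTGGCTCATATGAACA"
           "AGTCTTTGCGCCCATAAATGTAGCCAGTGAGCTTAGTTGGAGCAAGGGGT")
_PAIR_B = ("TGGTGATAACATTACAATACTCACGCTCCGGACTTTGACTCATATGAACA"
           "AGTCTATGTGCTTATAAATGTAGCCAGTGAGCTTAGTTGGAGCAAGAGGT")


def _codes(seq):
    lookup = {c: i for i, c in enumerate("ACGT")}
    return np.array([lookup.get(c, 255) for c in seq], dtype=np.uint8)


def _aln(seqs, ids=None):
    ids = ids or [f"t{i}" for i in range(len(seqs))]
    return LocusAlignment("toy", [SeqRecord(i, s) for i, s in zip(ids, seqs)])


class TestDistances:
    def test_identical_pair_is_zero(self):
        for model in ("p", "jc69", "k2p", "tn93"):
            assert pairwise_distance(_codes("ACGTACGTCC"),
                                     _codes("ACGTACGTCC"), model) == 0.0

    def test_p_distance(self):
        a, b = _codes("AAAAAAAAAA"), _codes("AAAAAAAAGG")
        assert pairwise_distance(a, b, "p") == pytest.approx(0.2)

    def test_jc69_closed_form(self):
        # two mismatches over 20 comparable columns: p = 0.1
        a = _codes("ACGTACGTACGTACGTACGT")
        b = _codes("ACGTACGTACGTACGTACTA")
        expected = -0.75 * math.log(1 - 4 * 0.1 / 3)
        d = pairwise_distance(a, b, "jc69")
        assert d == pytest.approx(0.107326, abs=1e-6)
        assert d == pytest.approx(expected)

    @pytest.mark.parametrize("model,expected", [
        ("p", 0.12), ("jc69", 0.130765), ("k2p", 0.1311838),
        ("tn93", 0.1312954),
    ])
    def test_frozen_independent_oracle(self, model, expected):
        d = pairwise_distance(_codes(_PAIR_A), _codes(_PAIR_B), model)
        assert d == pytest.approx(expected, abs=5e-7)

    def test_pairwise_deletion(self):
        a = _codes("ACGTN-GG")
        b = _codes("ACCT-AGG")
        # comparable columns: 0,1,2,3,6,7 minus those with non-ACGT: 4,5
        assert pairwise_distance(a, b, "p") == pytest.approx(1 / 6)

    def test_saturation_is_an_error_not_infinity(self):
        a = _codes("AAAAAAAAAA")
        b = _codes("GGGGGGGGGG")
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, "jc69")

    def test_jc69_dominates_p(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.integers(0, 4, 60).astype(np.uint8)
            b = a.copy()
            hits = rng.choice(60, 12, replace=False)
            b[hits] = (b[hits] + rng.integers(1, 4, 12)) % 4
            assert (pairwise_distance(a, b, "jc69")
                    >= pairwise_distance(a, b, "p"))

    def test_matrix_symmetry_and_diagonal(self):
        dm = distance_matrix(_aln(["ACGTACGT", "ACGTACTT", "ACCTACTT"]),
                             "jc69")
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)


class TestUpgma:
    def test_three_taxon_hand_case(self):
        dm = DistanceMatrix(
            ids=["A", "B", "C"],
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
            model="p")
        assert write_newick(upgma(dm)) == \
            "((A:1.000000,B:1.000000):1.000000,C:2.000000);"

    def test_two_taxon_cherry(self):
        dm = DistanceMatrix(ids=["A", "B"],
                            values=np.array([[0, 3.0], [3.0, 0]]), model="p")
        tree = upgma(dm)
        assert tree.leaf_depths() == {"A": 1.5, "B": 1.5}

    def test_recovers_random_ultrametric_trees(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 6
            # Random agglomeration with increasing heights -> ultrametric.
            heights = np.sort(rng.uniform(0.5, 5.0, size=n - 1))
            clusters = [({i}, 0.0) for i in range(n)]
            true_merges = []
            for h in heights:
                i, j = sorted(rng.choice(len(clusters), 2, replace=False))
                (set_j, _) = clusters.pop(j)
                (set_i, _) = clusters.pop(i)
                clusters.append((set_i | set_j, h))
                true_merges.append((frozenset(set_i | set_j), h))
            d = np.zeros((n, n))
            for members, h in true_merges:
                for a in members:
                    for b in members:
                        if a != b and d[a, b] == 0:
                            d[a, b] = d[b, a] = 2 * h
            ids = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(ids=ids, values=d, model="p"))
            depths = tree.leaf_depths()
            root_height = max(h for _, h in true_merges)
            for leaf, depth in depths.items():
                assert depth == pytest.approx(root_height)
            got = {frozenset(int(name[1:]) for name in node.leaf_names())
                   for node in tree.walk() if not node.is_leaf}
            want = {members for members, _ in true_merges}
            assert want <= got

    def test_ultrametric_output(self, default_panel):
        dm = distance_matrix(default_panel["rpoB"], "p")
        depths = upgma(dm).leaf_depths()
        values = list(depths.values())
        assert max(values) - min(values) < 1e-9


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # Tree ((A:1,B:2):1,(C:3,D:1)) -> path-length matrix below.
        d = np.array([[0, 3, 5, 3],
                      [3, 0, 6, 4],
                      [5, 6, 0, 4],
                      [3, 4, 4, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids=list("ABCD"), values=d,
                                               model="p"))
        splits = bipartitions(tree)
        assert frozenset((frozenset("AB"), frozenset("CD"))) in splits
        assert np.allclose(_tree_path_lengths(tree), d, atol=1e-9)

    def test_path_lengths_reproduce_random_additive_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            n = 7
            d = _random_additive_matrix(rng, n)
            ids = [f"t{i}" for i in range(n)]
            tree = neighbor_joining(DistanceMatrix(ids=ids, values=d,
                                                   model="p"))
            assert np.allclose(_tree_path_lengths(tree), d, atol=1e-9)

    def test_equidistant_taxa_resolve_to_zero_internal_branches(self):
        n = 5
        d = np.ones((n, n)) - np.eye(n)
        tree = neighbor_joining(DistanceMatrix(
            ids=[f"t{i}" for i in range(n)], values=d, model="p"))
        for node in tree.walk():
            if not node.is_leaf and node is not tree:
                assert node.length == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_taxa_is_an_error(self):
        dm = DistanceMatrix(ids=["A", "B"],
                            values=np.array([[0, 1.0], [1.0, 0]]), model="p")
        with pytest.raises(DataError):
            neighbor_joining(dm)

    def test_topology_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj
        rng = np.random.default_rng(33)
        d = _random_additive_matrix(rng, 8)
        ids = [f"t{i}" for i in range(8)]
        mine = neighbor_joining(DistanceMatrix(ids=ids, values=d, model="p"))
        theirs = sknj(skbio.DistanceMatrix(d, ids))
        their_splits = set()
        names = frozenset(ids)
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 2 <= len(below) <= len(ids) - 2:
                their_splits.add(frozenset((below, names - below)))
        assert bipartitions(mine) == their_splits


def _random_additive_matrix(rng, n):
    """Path-length matrix of a random binary tree with positive branches."""
    import itertools
    parent = {}
    lengths = {}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        i = active.pop(int(rng.integers(len(active))))
        j = active.pop(int(rng.integers(len(active))))
        for child in (i, j):
            parent[child] = nxt
            lengths[child] = float(rng.uniform(0.1, 1.0))
        active.append(nxt)
        nxt += 1

    def path_to_root(x):
        path = []
        while x in parent:
            path.append(x)
            x = parent[x]
        return path

    d = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        pa, pb = path_to_root(a), path_to_root(b)
        shared = set(pa) & set(pb)

        def climb(path):
            total = 0.0
            for node in path:
                if node in shared:
                    break
                total += lengths[node]
            return total

        d[a, b] = d[b, a] = climb(pa) + climb(pb)
    return d


def _tree_path_lengths(tree):
    leaves = sorted(tree.leaf_names())
    index = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def walk(node, path):
        path = path + [node]
        if node.is_leaf:
            paths[node.name] = path
        for child in node.children:
            walk(child, path)

    paths = {}
    walk(tree, [])
    for a in leaves:
        for b in leaves:
            if a >= b:
                continue
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            total = sum(x.length for x in pa[k:]) + sum(x.length
                                                        for x in pb[k:])
            d[index[a], index[b]] = d[index[b], index[a]] = total
    return d


class TestBootstrap:
    def test_zero_variable_sites_give_full_support(self):
        # Every replicate reproduces the identical all-zero matrix, so
        # the (tie-broken) tree is the same in each and supports are 100.
        aln = _aln(["ACGTACGT"] * 5)
        tree = bootstrap(aln, 20, method="upgma", model="p", seed=3)
        supports = [node.support for node in tree.walk()
                    if node is not tree and not node.is_leaf]
        assert supports and all(s == 100 for s in supports)

    def test_same_seed_reproduces_supports(self, default_panel):
        aln = default_panel["rpoB"].subset(
            ids=[f"AV{i:02d}" for i in (1, 2)] + ["AX01", "AL01", "AK01",
                                                  "AH01", "BRA01"])
        t1 = bootstrap(aln, 30, method="upgma", model="jc69", seed=9)
        t2 = bootstrap(aln, 30, method="upgma", model="jc69", seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_under_taxon_permutation(self, default_panel):
        ids = ["AV01", "AX01", "AL01", "AK01", "AO01", "BRA01"]
        aln = default_panel["ITS"].subset(ids=ids)
        shuffled = LocusAlignment("ITS", list(reversed(aln.records)))

        def support_map(tree):
            alln = tree.leaf_names()
            out = {}
            for node in tree.walk():
                if node is tree or node.is_leaf:
                    continue
                below = node.leaf_names()
                out[frozenset((below, alln - below))] = node.support
            return out

        m1 = support_map(bootstrap(aln, 30, model="jc69", seed=5))
        m2 = support_map(bootstrap(shuffled, 30, model="jc69", seed=5))
        # The strongly supported split (the three genuine species) must be
        # present on both orderings with identical support; weak splits
        # may legitimately differ through tie-broken co-optimal trees.
        ingroup = frozenset({"AV01", "AX01", "AL01"})
        rest = frozenset({"AK01", "AO01", "BRA01"})
        split = frozenset((ingroup, rest))
        assert m1[split] == m2[split] == 100


class TestMonophylyAndNewick:
    def _tree(self):
        return parse_newick("((A:1.000000,B:1.000000):1.000000,C:2.000000);")

    def test_cherry_is_monophyletic(self):
        assert is_monophyletic(self._tree(), {"A", "B"}, "C")

    def test_set_containing_the_outgroup_is_not_a_clade(self):
        assert not is_monophyletic(self._tree(), {"A", "C"}, "C")

    def test_paraphyletic_set_in_a_quartet(self):
        tree = parse_newick(
            "(((A:1.000000,B:1.000000):1.000000,C:2.000000):1.000000,"
            "D:3.000000);")
        assert is_monophyletic(tree, {"A", "B"}, "D")
        assert not is_monophyletic(tree, {"A", "C"}, "D")

    def test_unknown_taxon_is_an_error(self):
        with pytest.raises(DataError):
            is_monophyletic(self._tree(), {"A", "Z"}, "C")

    def test_newick_round_trip(self):
        text = "((A:1.000000,B:2.500000)98:0.750000,C:2.000000);"
        assert write_newick(parse_newick(text)) == text

    def test_support_label_format(self):
        tree = TreeNode(children=[
            TreeNode(name="C", length=2.0),
            TreeNode(support=98, length=0.75, children=[
                TreeNode(name="A", length=1.0),
                TreeNode(name="B", length=2.5)]),
        ])
        assert write_newick(tree) == \
            "((A:1.000000,B:2.500000)98:0.750000,C:2.000000);"
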