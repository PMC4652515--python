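"""Neighbor joining against additive-matrix oracles and an independent
library implementation; bootstrap and consensus semantics."""

import numpy as np
import pandas as pd
import pytest

from kmerphylo import (
    AbundanceMatrix,
    DistanceMatrix,
    bootstrap_trees,
    majority_consensus,
    neighbor_joining,
    read_newick,
    tree_path_distances,
    tree_splits,
    write_newick,
)


# ---------------------------------------------------------------------------
# oracle: random weighted binary trees built on plain adjacency dicts
# ---------------------------------------------------------------------------

def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree with uniform branch lengths, represented
    as an adjacency dict {node: {neighbor: length}} — independent of any
    tree library. Leaves are 't0'..'t{n-1}'."""
    nodes = [f"t{i}" for i in range(n_taxa)]
    adj = {v: {} for v in nodes}
    free = list(nodes)
    nxt = 0
    while len(free) > 3:
        i, j = sorted(rng.choice(len(free), size=2, replace=False))
        a, b = free[j], free[i]
        new = f"x{nxt}"
        nxt += 1
        adj[new] = {}
        for leaf in (a, b):
            length = rng.uniform(0.5, 2.0)
            adj[new][leaf] = length
            adj[leaf][new] = length
        free = [v for v in free if v not in (a, b)] + [new]
    center = f"x{nxt}"
    adj[center] = {}
    for leaf in free:
        length = rng.uniform(0.5, 2.0)
        adj[center][leaf] = length
        adj[leaf][center] = length
    return nodes, adj


def path_lengths(adj, nodes):
    """All-pairs leaf path sums by depth-first search."""
    n = len(nodes)
    out = np.zeros((n, n))
    for i, src in enumerate(nodes):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            v = stack.pop()
            for w, length in adj[v].items():
                if w not in dist:
                    dist[w] = dist[v] + length
                    stack.append(w)
        for j, dst in enumerate(nodes):
            out[i, j] = dist[dst]
    return out


def adjacency_splits(adj, nodes):
    """Non-trivial bipartitions by removing each internal edge."""
    pos = {t: i for i, t in enumerate(sorted(nodes))}
    full = (1 << len(nodes)) - 1
    splits = set()
    seen = set()
    for v in adj:
        for w in adj[v]:
            if (w, v) in seen:
                continue
            seen.add((v, w))
            # leaves on v's side when edge (v, w) is removed
            mask = 0
            stack, visited = [v], {v, w}
            while stack:
                u = stack.pop()
                if u in pos:
                    mask |= 1 << pos[u]
                for x in adj[u]:
                    if x not in visited:
                        visited.add(x)
                        stack.append(x)
            if mask & 1:
                mask ^= full
            if 2 <= bin(mask).count("1") <= len(nodes) - 2:
                splits.add(mask)
    return splits


def abundance_fixture(rng, n_features=60, n_samples=6):
    cols = rng.random((n_features, n_samples))
    cols /= cols.sum(axis=0)
    kmers = []
    for i in range(n_features):
        digits, x = [], i
        for _ in range(6):
            digits.append("ACGT"[x % 4])
            x //= 4
        kmers.append("".join(reversed(digits)))
    return AbundanceMatrix.from_frame(
        pd.DataFrame(cols, index=kmers,
                     columns=[f"s{j}" for j in range(n_samples)])
    )


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = neighbor_joining(d)
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_known_tree(self):
        # tree: (a:1, b:2) joined to (c:3, d:4) by an internal edge of 5
        names = ["a", "b", "c", "d"]
        mat = np.array([
            [0, 3, 9, 10],
            [3, 0, 10, 11],
            [9, 10, 0, 7],
            [10, 11, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(names, mat))
        assert np.allclose(tree_path_distances(tree, names), mat, atol=1e-9)
        _, splits = tree_splits(tree)
        # the single non-trivial split is {a,b} | {c,d}
        assert splits == {0b1100}

    def test_additive_recovery_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            nodes, adj = random_additive_tree(n, rng)
            order = sorted(nodes)
            mat = path_lengths(adj, order)
            tree = neighbor_joining(DistanceMatrix(order, mat))
            assert np.allclose(tree_path_distances(tree, order), mat,
                               atol=1e-9)
            _, nj_splits = tree_splits(tree)
            assert nj_splits == adjacency_splits(adj, nodes)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        names = [f"s{i}" for i in range(7)]
        pts = rng.random((7, 4))
        mat = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ours = neighbor_joining(DistanceMatrix(names, mat))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=names))
        their_splits = set()
        taxa = sorted(names)
        pos = {t: i for i, t in enumerate(taxa)}
        full = (1 << len(taxa)) - 1
        for node in theirs.non_tips(include_self=False):
            mask = 0
            for tip in node.tips():
                mask |= 1 << pos[tip.name]
            if mask & 1:
                mask ^= full
            if 2 <= bin(mask).count("1") <= len(taxa) - 2:
                their_splits.add(mask)
        _, our_splits = tree_splits(ours)
        assert our_splits == their_splits

    def test_input_validation(self):
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0, 1], [1, 0.0]])))

    def test_deterministic_on_ties(self):
        # equidistant points: many Q ties; result must be reproducible
        mat = np.ones((5, 5)) - np.eye(5)
        d = DistanceMatrix(list("abcde"), mat)
        t1 = write_newick(neighbor_joining(d))
        t2 = write_newick(neighbor_joining(d))
        assert t1 == t2


class TestBootstrap:
    def test_constant_features_identical_trees(self, rng):
        template = abundance_fixture(rng)
        vals = np.tile(rng.random(6), (20, 1))  # 20 identical feature rows
        a = AbundanceMatrix(template.kmer_codes[:20], template.samples,
                            vals, template.k)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate input, negative NJ lengths
            trees = bootstrap_trees(a, n_replicates=5, seed=1)
        topologies = {frozenset(tree_splits(t)[1]) for t in trees}
        assert len(topologies) == 1

    def test_zero_replicates(self, rng):
        assert bootstrap_trees(abundance_fixture(rng), 0, seed=1) == []

    def test_seed_determinism(self, rng):
        a = abundance_fixture(rng)
        t1 = [write_newick(t) for t in bootstrap_trees(a, 10, seed=5)]
        t2 = [write_newick(t) for t in bootstrap_trees(a, 10, seed=5)]
        assert t1 == t2

    def test_metrics_supported(self, rng):
        a = abundance_fixture(rng)
        for metric in ("euclidean", "bray-curtis"):
            trees = bootstrap_trees(a, 3, seed=2, metric=metric)
            assert len(trees) == 3


class TestConsensus:
    def test_identical_trees_full_support(self, rng):
        a = abundance_fixture(rng)
        from kmerphylo import euclidean_distances

        tree = neighbor_joining(euclidean_distances(a))
        cons, splits = majority_consensus([tree] * 4)
        _, orig = tree_splits(tree)
        _, cons_splits = tree_splits(cons)
        assert cons_splits == orig
        for mask in orig:
            assert splits.counts[mask] == 4

    def test_two_of_three_support(self):
        t_ab = read_newick("((a,b),(c,d));")
        t_ac = read_newick("((a,c),(b,d));")
        cons, splits = majority_consensus([t_ab, t_ab, t_ac])
        taxa = splits.taxa
        assert splits.support_fraction(["a", "b"]) == pytest.approx(2 / 3)
        _, cons_splits = tree_splits(cons, taxa)
        assert cons_splits == {splits.mask_of(["a", "b"])}

    def test_consensus_splits_subset_of_union(self, rng):
        trees = []
        for _ in range(6):
            nodes, adj = random_additive_tree(5, rng)
            order = sorted(nodes)
            mat = path_lengths(adj, order)
            trees.append(neighbor_joining(DistanceMatrix(order, mat)))
        cons, _ = majority_consensus(trees)
        union = set()
        for t in trees:
            union |= tree_splits(t)[1]
        assert tree_splits(cons)[1] <= union

    def test_leaf_set_mismatch_rejected(self):
        t1 = read_newick("((a,b),(c,d));")
        t2 = read_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="leaf sets"):
            majority_consensus([t1, t2])

    def test_requires_trees(self):
        with pytest.raises(ValueError):
            majority_consensus([])


class TestNewickIO:
    def test_round_trip_preserves_topology(self, rng):
        nodes, adj = random_additive_tree(6, rng)
        order = sorted(nodes)
        tree = neighbor_joining(DistanceMatrix(order, path_lengths(adj, order)))
        text = write_newick(tree)
        back = read_newick(text)
        assert tree_splits(back)[1] == tree_splits(tree)[1]
        assert np.allclose(tree_path_distances(back, order),
                           tree_path_distances(tree, order), atol=1e-9)

    def test_support_comment_dialect(self):
        t_ab = read_newick("((a,b),(c,d));")
        cons, _ = majority_consensus([t_ab, t_ab])
        labeled = write_newick(cons)
        commented = write_newick(cons, support_as_comment=True)
        assert "1.0000" in labeled
        assert "[1.0000]" in commented
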