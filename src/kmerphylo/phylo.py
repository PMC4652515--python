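"""Neighbor-joining trees, feature bootstrap, and majority-rule consensus.

NJ follows the classic Saitou-Nei agglomeration and is exact on additive
distance matrices. Ties in the Q-criterion are broken by joining the
lexicographically smallest pair of node labels (an internal node inherits
the smaller label of the pair it replaced), so results are deterministic
and reproducible; this matters because consensus supports can shift at
ties. Bootstrap replicates resample k-mer *features* (matrix rows) with
replacement, recompute the distance matrix, and rebuild the tree; the
consensus is extended majority rule: all splits in > 50% of replicates,
greedily refined with compatible minority splits in descending frequency.

Trees are ``dendropy.Tree`` objects (unrooted), serialized as Newick with
split supports as internal node labels or bracketed comments.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .distance import DistanceMatrix
from .matrix import AbundanceMatrix


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix,
                     clamp_negative: bool = False) -> dendropy.Tree:
    """Build the unrooted NJ tree for a distance matrix.

    Negative branch lengths (possible on non-additive input) are kept but
    reported via a warning; ``clamp_negative=True`` sets them to zero and
    transfers the deficit to the sibling branch of the join (so the pair's
    summed length is preserved).
    """
    n = d.n_samples
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    if d.values.min() < 0:
        raise ValueError("negative distances in input")

    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = d.values
    labels: list[str] = list(d.samples)
    # children[v] = [(child, branch_length), ...] for internal nodes
    children: dict[int, list[tuple[int, float]]] = {}
    active = list(range(n))
    next_node = n
    n_negative = 0

    def pair_lengths(i, j, li, lj):
        nonlocal n_negative
        if li < 0 or lj < 0:
            n_negative += 1
            if clamp_negative:
                if li < 0:
                    lj += -li
                    li = 0.0
                elif lj < 0:
                    li += -lj
                    lj = 0.0
        return li, lj

    while len(active) > 3:
        idx = np.array(active)
        Dm = D[np.ix_(idx, idx)]
        m = len(active)
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        # evaluate on the upper triangle only: the two float orderings of
        # Q[a,b] and Q[b,a] can differ in the last bit
        iu = np.triu_indices(m, k=1)
        qvals = Q[iu]
        ties = np.flatnonzero(qvals == qvals.min())
        # deterministic tie-break on sorted label pairs
        best = min(
            (tuple(sorted((labels[idx[iu[0][t]]], labels[idx[iu[1][t]]]))),
             iu[0][t], iu[1][t])
            for t in ties
        )
        a, b = best[1], best[2]
        i, j = idx[a], idx[b]
        dij = Dm[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = pair_lengths(i, j, li, lj)

        u = next_node
        next_node += 1
        children[u] = [(i, li), (j, lj)]
        labels.append(min(labels[i], labels[j]))
        rest = [x for x in active if x not in (i, j)]
        for x in rest:
            D[u, x] = D[x, u] = 0.5 * (D[i, x] + D[j, x] - dij)
        active = rest + [u]

    # terminal star over the last three nodes
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for l in (la, lb, lc):
        if l < 0:
            n_negative += 1
    if clamp_negative:
        la, lb, lc = (max(0.0, v) for v in (la, lb, lc))
    center = next_node
    children[center] = [(a, la), (b, lb), (c, lc)]

    if n_negative and not clamp_negative:
        warnings.warn(
            f"NJ produced {n_negative} join(s) with a negative branch length "
            "(non-additive input); pass clamp_negative=True to zero them",
            stacklevel=2,
        )

    # assemble the dendropy tree
    ns = dendropy.TaxonNamespace(d.samples)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False

    def build(v: int, parent_node: dendropy.Node, length: float):
        node = parent_node.new_child(edge_length=float(length))
        if v < n:
            node.taxon = ns.get_taxon(labels[v])
        else:
            for child, child_len in children[v]:
                build(child, node, child_len)
        return node

    seed = tree.seed_node
    for child, child_len in children[center]:
        build(child, seed, child_len)
    return tree


def tree_path_distances(tree: dendropy.Tree,
                        samples: list[str]) -> np.ndarray:
    """Patristic (path-length) distance matrix in the given sample order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[samples[i]], taxa[samples[j]])
            out[i, j] = out[j, i] = dist
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_trees(
    a: AbundanceMatrix,
    n_replicates: int = 1000,
    seed: int | None = None,
    metric: str = "euclidean",
) -> list[dendropy.Tree]:
    """NJ trees from feature-bootstrap replicates.

    Each replicate draws row multiplicities from Multinomial(m, 1/m) —
    equivalent to resampling the m k-mer rows with replacement — recomputes
    the configured distance and reruns NJ. Fixed seed => identical list.
    """
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    if a.n_samples < 3:
        raise ValueError("need >= 3 samples")
    if a.n_kmers < 2:
        raise ValueError("need >= 2 features")
    rng = np.random.default_rng(seed)
    X = a.values
    m = a.n_kmers
    prob = np.full(m, 1.0 / m)
    trees = []
    for _ in range(n_replicates):
        w = rng.multinomial(m, prob).astype(np.float64)
        if metric == "euclidean":
            G = X.T @ (X * w[:, None])
            sq = np.diag(G)
            d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * G, 0.0)
            dvals = np.sqrt(d2)
            np.fill_diagonal(dvals, 0.0)
            dvals = 0.5 * (dvals + dvals.T)
            dm = DistanceMatrix(list(a.samples), dvals, "euclidean")
        elif metric in ("bray-curtis", "braycurtis"):
            dvals = squareform(pdist(X.T, metric="braycurtis", w=w))
            dm = DistanceMatrix(list(a.samples), dvals, "bray-curtis")
        else:
            raise ValueError(f"unknown metric {metric!r}")
        trees.append(neighbor_joining(dm))
    return trees


# ---------------------------------------------------------------------------
# splits and consensus
# ---------------------------------------------------------------------------

@dataclass
class SplitSet:
    """Leaf bipartitions with replicate support counts.

    Splits are encoded as bitmasks over ``taxa`` (sorted leaf labels),
    normalized to the side *not* containing the first taxon.
    """

    taxa: list[str]
    n_trees: int
    counts: dict[int, int]

    def normalize(self, mask: int) -> int:
        full = (1 << len(self.taxa)) - 1
        return mask ^ full if mask & 1 else mask

    def mask_of(self, group) -> int:
        pos = {t: i for i, t in enumerate(self.taxa)}
        mask = 0
        for label in group:
            mask |= 1 << pos[label]
        return self.normalize(mask)

    def support_count(self, group) -> int:
        """Replicates containing the split separating ``group`` from the
        rest; trivial splits (single leaf) are present in every tree."""
        mask = self.mask_of(group)
        size = bin(mask).count("1")
        if size in (1, len(self.taxa) - 1):
            return self.n_trees
        return self.counts.get(mask, 0)

    def support_fraction(self, group) -> float:
        return self.support_count(group) / self.n_trees


def _leaf_masks(tree: dendropy.Tree, pos: dict[str, int]) -> dict:
    masks = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << pos[node.taxon.label]
        else:
            masks[node] = 0
            for child in node.child_nodes():
                masks[node] |= masks[child]
    return masks


def tree_splits(tree: dendropy.Tree,
                taxa: list[str] | None = None) -> tuple[list[str], set[int]]:
    """Non-trivial bipartitions of an (un)rooted tree as normalized masks."""
    if taxa is None:
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    pos = {t: i for i, t in enumerate(taxa)}
    full = (1 << len(taxa)) - 1
    n = len(taxa)
    masks = _leaf_masks(tree, pos)
    splits = set()
    for node, mask in masks.items():
        if node.parent_node is None or node.is_leaf():
            continue
        if mask & 1:
            mask ^= full
        if 2 <= bin(mask).count("1") <= n - 2:
            splits.add(mask)
    return taxa, splits


def majority_consensus(
    trees: list[dendropy.Tree],
    min_freq: float = 0.5,
    extended: bool = True,
) -> tuple[dendropy.Tree, SplitSet]:
    """Extended majority-rule consensus of trees over one leaf set.

    Splits occurring in > ``min_freq`` of the input trees are retained;
    with ``extended`` (the default, mirroring PHYLIP consense) remaining
    splits are added greedily in descending frequency when compatible with
    those already accepted.
    """
    if not trees:
        raise ValueError("need >= 1 tree")
    taxa, _ = tree_splits(trees[0])
    counter: Counter[int] = Counter()
    for tree in trees:
        t_taxa, splits = tree_splits(tree, taxa=None)
        if t_taxa != taxa:
            raise ValueError("trees have different leaf sets")
        counter.update(splits)

    n_trees = len(trees)
    accepted: list[int] = []

    def compatible(mask: int) -> bool:
        # both masks exclude taxon 0 => compatible iff nested or disjoint
        return all(
            (mask & other) in (0, mask, other) for other in accepted
        )

    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    for mask, count in ordered:
        if count / n_trees > min_freq:
            accepted.append(mask)
        elif extended and compatible(mask):
            accepted.append(mask)

    split_set = SplitSet(taxa=taxa, n_trees=n_trees, counts=dict(counter))
    tree = _tree_from_splits(taxa, accepted,
                             {m: counter[m] / n_trees for m in accepted})
    return tree, split_set


def _tree_from_splits(taxa: list[str], masks: list[int],
                      support: dict[int, float]) -> dendropy.Tree:
    """Assemble the unrooted tree whose non-trivial splits are ``masks``.

    Masks exclude taxon 0, so they form a laminar family of clades on a
    tree rooted at taxon 0's attachment node.
    """
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = False
    seed = tree.seed_node

    leaf0 = seed.new_child()
    leaf0.taxon = ns.get_taxon(taxa[0])

    by_size = sorted(masks, key=lambda m: -bin(m).count("1"))
    node_of: dict[int, dendropy.Node] = {}
    parents: list[int] = []
    for mask in by_size:
        parent = seed
        best_size = None
        for cand in parents:
            if mask & cand == mask:
                size = bin(cand).count("1")
                if best_size is None or size < best_size:
                    best_size = size
                    parent = node_of[cand]
        node = parent.new_child()
        node.label = f"{support[mask]:.4f}"
        node.support = support[mask]
        node_of[mask] = node
        parents.append(mask)

    for i, label in enumerate(taxa[1:], start=1):
        bit = 1 << i
        parent = seed
        best_size = None
        for cand in parents:
            if cand & bit:
                size = bin(cand).count("1")
                if best_size is None or size < best_size:
                    best_size = size
                    parent = node_of[cand]
        leaf = parent.new_child()
        leaf.taxon = ns.get_taxon(label)
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path=None,
                 support_as_comment: bool = False) -> str:
    """Serialize as Newick; split supports are internal node labels by
    default, or PHYLIP-style bracketed comments with
    ``support_as_comment=True``."""
    work = tree.clone(depth=1)
    if support_as_comment:
        for node in work.preorder_node_iter():
            if not node.is_leaf() and node.label:
                node.comments.append(node.label)
                node.label = None
    text = work.as_string(schema="newick", suppress_rooting=True,
                          suppress_item_comments=False,
                          unquoted_underscores=True).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_newick(source) -> dendropy.Tree:
    """Parse Newick from a path or a literal string."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        return dendropy.Tree.get(path=str(source), schema="newick")
    return dendropy.Tree.get(data=source, schema="newick")


def ascii_tree(tree: dendropy.Tree) -> str:
    return tree.as_ascii_plot()
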