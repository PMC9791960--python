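"""Distance-based phylogenetics: Poisson-corrected distances, neighbor
joining, bootstrap supports, and clade assignment.

Protein distances are computed from a pre-made multiple alignment using
pairwise deletion (a site contributes to a pair only when neither sequence
has a gap there) and the Poisson multiple-hit correction d = -ln(1 - p).
Trees are built with the Saitou–Nei neighbor-joining algorithm; bootstrap
supports come from resampling alignment columns with replacement. Clades are
an operational partition obtained by cutting the longest internal edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "p_distance",
    "poisson_correct",
    "alignment_distances",
    "neighbor_joining",
    "bootstrap_support",
    "assign_clades",
]

GAP_CHARS = {"-", "."}


# ---------------------------------------------------------------------------
# Distances


def p_distance(aligned_i: str, aligned_j: str) -> float:
    """Proportion of differing sites among sites where neither row has a gap."""
    if len(aligned_i) != len(aligned_j):
        raise ValueError("aligned sequences must have equal length")
    diff = comparable = 0
    for a, b in zip(aligned_i.upper(), aligned_j.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        comparable += 1
        if a != b:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable sites (all-gap overlap)")
    return diff / comparable


def poisson_correct(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p); undefined at p >= 1."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p-distance {p} outside [0, 1): Poisson correction undefined")
    return -math.log1p(-p)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered taxon list."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        n = len(self.taxa)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite and nonnegative")


def alignment_distances(alignment: list[tuple[str, str]]) -> DistanceMatrix:
    """Poisson-corrected distance matrix from (name, aligned sequence) rows."""
    names = [n for n, _ in alignment]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names in alignment")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_correct(
                p_distance(alignment[i][1], alignment[j][1])
            )
    return DistanceMatrix(tuple(names), d)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """An unrooted tree stored rooted at a trifurcating internal node."""

    root: TreeNode

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.root.leaves())

    def _edges(self):
        """Yield (parent, child, length) over all edges."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, length in node.children:
                yield node, child, length
                stack.append(child)

    def n_edges(self) -> int:
        return sum(1 for _ in self._edges())

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge bipartitions, keyed by the canonical leaf-set side.

        The canonical side is the one *not* containing the lexicographically
        smallest taxon, so each unrooted split has a unique key.
        """
        all_taxa = self.taxa
        anchor = min(all_taxa)
        out: dict[frozenset[str], TreeNode] = {}
        for _parent, child, _length in self._edges():
            if child.is_leaf:
                continue
            below = frozenset(leaf.name for leaf in child.leaves())
            if 1 < len(below) < len(all_taxa) - 1:
                side = below if anchor not in below else all_taxa - below
                out[side] = child
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Pairwise path-length distances between leaves (tree metric)."""
        leaves = sorted(self.taxa)
        index = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def below(node, depth, acc):
            if node.is_leaf:
                acc.append((node.name, depth))
            for child, length in node.children:
                below(child, depth + length, acc)

        def recurse(node):
            # merge leaf-depth lists child by child, adding cross-child paths
            groups = []
            for child, length in node.children:
                acc: list[tuple[str, float]] = []
                below(child, length, acc)
                groups.append(acc)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for name_a, da in groups[gi]:
                        for name_b, db in groups[gj]:
                            i, j = index[name_a], index[name_b]
                            d[i, j] = d[j, i] = da + db
            for child, _ in node.children:
                recurse(child)

        recurse(self.root)
        return DistanceMatrix(tuple(leaves), d)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = "" if node.support is None else str(int(node.support))
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.6f}"

        return fmt(self.root, None) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k), attaching each
    joined node with the rate-corrected branch lengths; ties in Q are broken
    by taxon-pair order for determinism. Negative branch lengths are clamped
    to zero. Requires at least three taxa.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.taxa]
    d = matrix.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[i] = new
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return Tree(root)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    alignment: list[tuple[str, str]], n_replicates: int, seed: int
) -> Tree:
    """NJ tree from the full alignment with column-bootstrap supports.

    Each replicate resamples alignment columns with replacement using a
    random stream keyed by (seed, replicate index), so supports do not depend
    on taxon input order or on how many replicates ran before. With
    ``n_replicates == 0`` the tree is returned without supports.
    """
    alignment = sorted(alignment)
    tree = neighbor_joining(alignment_distances(alignment))
    if n_replicates == 0:
        return tree
    target = tree.bipartitions()
    counts = {side: 0 for side in target}
    length = len(alignment[0][1])
    names = [n for n, _ in alignment]
    rows = [s for _, s in alignment]
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, length, size=length)
        resampled = [
            (name, "".join(row[c] for c in cols)) for name, row in zip(names, rows)
        ]
        rep_tree = neighbor_joining(alignment_distances(resampled))
        rep_bips = set(rep_tree.bipartitions())
        for side in counts:
            if side in rep_bips:
                counts[side] += 1
    for side, node in target.items():
        node.support = round(100.0 * counts[side] / n_replicates)
    return tree


# ---------------------------------------------------------------------------
# Clade assignment


def assign_clades(tree: Tree, k: int) -> dict[str, int]:
    """Partition taxa into k clades by cutting the k-1 longest internal edges.

    Ties in edge length are broken by the lexicographic order of the edge's
    canonical bipartition. Clades are labeled 1..k by decreasing size (ties by
    smallest member). ``k == 1`` puts every taxon in clade 1.
    """
    taxa = sorted(tree.taxa)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(taxa):
        raise ValueError("k cannot exceed the number of taxa")

    # collect internal edges as (length, canonical side, child node id)
    all_taxa = frozenset(taxa)
    anchor = min(all_taxa)
    internal = []
    for _parent, child, length in tree._edges():
        if child.is_leaf:
            continue
        below = frozenset(leaf.name for leaf in child.leaves())
        side = below if anchor not in below else all_taxa - below
        internal.append((length, tuple(sorted(side)), below))
    internal.sort(key=lambda e: (-e[0], e[1]))
    n_cuts = min(k - 1, len(internal))

    # each cut splits off the leaf set below the cut edge; nested cuts are
    # resolved by assigning each taxon to the smallest cut set containing it
    cut_sets = [e[2] for e in internal[:n_cuts]]
    groups: dict[str, frozenset[str] | None] = {}
    for taxon in taxa:
        containing = [s for s in cut_sets if taxon in s]
        groups[taxon] = min(containing, key=len) if containing else None

    # once internal edges are exhausted, split single leaves off (longest
    # leaf edges first, ties by leaf name) until k groups exist
    extra_cuts = (k - 1) - n_cuts
    if extra_cuts > 0:
        leaf_edges = sorted(
            (
                (-length, child.name)
                for _parent, child, length in tree._edges()
                if child.is_leaf
            ),
        )
        sizes: dict[frozenset[str] | None, int] = {}
        for g in groups.values():
            sizes[g] = sizes.get(g, 0) + 1
        for _neg_len, leaf in leaf_edges:
            if extra_cuts == 0:
                break
            g = groups[leaf]
            if sizes.get(g, 0) < 2:
                continue
            sizes[g] -= 1
            groups[leaf] = frozenset({leaf})
            sizes[frozenset({leaf})] = 1
            extra_cuts -= 1

    distinct: list = []
    for g in groups.values():
        if g not in distinct:
            distinct.append(g)
    members = {
        g: sorted(t for t in taxa if groups[t] == g) for g in distinct
    }
    ordered = sorted(distinct, key=lambda g: (-len(members[g]), members[g][0]))
    labels: dict[str, int] = {}
    for label, g in enumerate(ordered, start=1):
        for t in members[g]:
            labels[t] = label
    return labels
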