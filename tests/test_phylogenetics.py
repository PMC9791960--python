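"""Distances, neighbor joining (vs exhaustive least-squares), bootstrap, clades."""

import itertools

import numpy as np
import pytest

from polyfam.phylogenetics import (
    DistanceMatrix,
    Tree,
    TreeNode,
    alignment_distances,
    assign_clades,
    bootstrap_support,
    neighbor_joining,
    p_distance,
    poisson_correct,
)

# ---------------------------------------------------------------------------
# independent oracle: enumerate all unrooted topologies, fit branch lengths
# by least squares on the path matrix, report the best-fitting topology


def _all_topologies(n):
    """Edge lists of all unrooted binary trees on leaves 0..n-1."""
    base = [(0, n), (1, n), (2, n)]
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_node in trees:
            for i, (u, v) in enumerate(edges):
                mid = next_node
                new_edges = edges[:i] + edges[i + 1 :] + [
                    (u, mid), (v, mid), (leaf, mid)
                ]
                nxt.append((new_edges, next_node + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _paths(edges, n):
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    rows, pairs = [], []
    for i, j in itertools.combinations(range(n), 2):
        # DFS path from i to j
        stack = [(i, None, [])]
        seen = {i}
        while stack:
            node, _, used = stack.pop()
            if node == j:
                row = np.zeros(len(edges))
                row[used] = 1
                rows.append(row)
                pairs.append((i, j))
                break
            for nbr, eidx in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, node, used + [eidx]))
    return np.array(rows), pairs


def _bipartitions_of_edges(edges, n, taxa):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    bips = set()
    for u, v in edges:
        if u < n or v < n:
            continue  # leaf edge
        # leaves on v's side when edge u-v removed
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(taxa[node])
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        all_t = frozenset(taxa)
        side = frozenset(side)
        if 1 < len(side) < n - 1:
            bips.add(side if taxa[0] not in side else all_t - side)
    return bips


def _best_fit_topology(matrix: DistanceMatrix):
    n = len(matrix.taxa)
    d_vec = np.array(
        [matrix.d[i, j] for i, j in itertools.combinations(range(n), 2)]
    )
    best = None
    for edges in _all_topologies(n):
        A, _ = _paths(edges, n)
        x, *_ = np.linalg.lstsq(A, d_vec, rcond=None)
        resid = np.linalg.norm(A @ x - d_vec)
        if best is None or resid < best[0] - 1e-12:
            best = (resid, edges)
    return best


def _random_additive(n, rng):
    edges = _all_topologies(n)[int(rng.integers(len(_all_topologies(n))))]
    lengths = rng.uniform(0.5, 3.0, size=len(edges))
    A, pairs = _paths(edges, n)
    d = np.zeros((n, n))
    for (i, j), row in zip(pairs, A):
        d[i, j] = d[j, i] = row @ lengths
    taxa = tuple(chr(97 + i) for i in range(n))
    return DistanceMatrix(taxa, d), edges


class TestDistances:
    def test_identical_rows_zero(self):
        assert p_distance("MKV", "MKV") == 0.0

    def test_half_different(self):
        assert p_distance("AR", "AK") == 0.5

    def test_pairwise_deletion(self):
        assert p_distance("A-RK", "AG-K") == 0.0  # only cols 1 and 4 comparable

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError, match="no comparable sites"):
            p_distance("--AA", "AA--")

    @pytest.mark.parametrize("p,d", [(0.0, 0.0), (0.5, 0.6931)])
    def test_poisson_values(self, p, d):
        assert poisson_correct(p) == pytest.approx(d, abs=1e-4)

    def test_poisson_saturation(self):
        with pytest.raises(ValueError):
            poisson_correct(1.0)


class TestNeighborJoining:
    def test_requires_three_taxa(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        lengths = {c.name: l for c, l in tree.root.children}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(4.0)

    def test_four_taxon_worked_example(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        assert set(tree.bipartitions()) == {frozenset({"C", "D"})}
        # edge lengths (A, B, internal, C, D) = (1, 2, 1, 3, 4)
        assert np.allclose(tree.leaf_distances().d, d)
        newick = tree.to_newick()
        for edge in ("A:1.000000", "B:2.000000", "C:3.000000", "D:4.000000"):
            assert edge in newick

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_recovered_exactly(self, n):
        """NJ reproduces topology and path lengths; oracle: exhaustive
        topology enumeration with least-squares branch fitting."""
        rng = np.random.default_rng(n)
        for _ in range(3):
            dm, true_edges = _random_additive(n, rng)
            tree = neighbor_joining(dm)
            rec = tree.leaf_distances()
            assert rec.taxa == tuple(sorted(dm.taxa))
            idx = [dm.taxa.index(t) for t in rec.taxa]
            assert np.allclose(rec.d, dm.d[np.ix_(idx, idx)], atol=1e-9)
            resid, best_edges = _best_fit_topology(dm)
            assert resid < 1e-9
            assert _bipartitions_of_edges(best_edges, n, dm.taxa) == set(
                tree.bipartitions()
            )

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(77)
        dm, _ = _random_additive(6, rng)
        ours = neighbor_joining(dm)
        sk_tree = sk_nj(SkDM(dm.d, ids=list(dm.taxa)))
        sk_bips = set()
        all_taxa = frozenset(dm.taxa)
        anchor = min(all_taxa)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_taxa) - 1:
                sk_bips.add(side if anchor not in side else all_taxa - side)
        assert sk_bips == set(ours.bipartitions())


class TestBootstrap:
    def _two_clade_alignment(self):
        a = "AAAAAAAAAACCCCCCCCCC"
        b = "TTTTTTTTTTCCCCCCCCCC"
        return [("a1", a), ("a2", a), ("b1", b), ("b2", b)]

    def test_clean_split_gets_full_support(self):
        tree = bootstrap_support(self._two_clade_alignment(), 50, seed=1)
        supports = [
            node.support for node in tree.bipartitions().values()
        ]
        assert supports == [100]

    def test_zero_replicates_leaves_tree_unsupported(self):
        tree = bootstrap_support(self._two_clade_alignment(), 0, seed=1)
        assert all(n.support is None for n in tree.bipartitions().values())

    def test_seed_determinism_and_order_invariance(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, 20, seed=5)
        t2 = bootstrap_support(aln[::-1], 20, seed=5)
        assert t1.to_newick() == t2.to_newick()


class TestAssignClades:
    def _cluster_matrix(self, k=4, size=2, within=0.1, between=2.0):
        n = k * size
        d = np.full((n, n), between)
        for c in range(k):
            block = slice(c * size, (c + 1) * size)
            d[block, block] = within
        np.fill_diagonal(d, 0.0)
        taxa = tuple(f"t{c}_{i}" for c in range(k) for i in range(size))
        return DistanceMatrix(taxa, d), [
            {f"t{c}_{i}" for i in range(size)} for c in range(k)
        ]

    def test_single_clade(self):
        dm, _ = self._cluster_matrix()
        tree = neighbor_joining(dm)
        labels = assign_clades(tree, 1)
        assert set(labels.values()) == {1}

    def test_recovers_planted_clusters(self):
        dm, clusters = self._cluster_matrix(k=4, size=3)
        tree = neighbor_joining(dm)
        labels = assign_clades(tree, 4)
        groups = {}
        for taxon, lab in labels.items():
            groups.setdefault(lab, set()).add(taxon)
        assert sorted(map(frozenset, groups.values())) == sorted(
            map(frozenset, clusters)
        )

    def test_singleton_clades_at_k_equals_n(self):
        aln = [("a", "AAAAWWWW"), ("b", "ATAAWWWW"), ("c", "TTAAWWWW"), ("d", "TTTAWWWW")]
        tree = neighbor_joining(alignment_distances(aln))
        labels = assign_clades(tree, 4)
        assert sorted(labels.values()) == [1, 2, 3, 4]

    def test_k_beyond_taxa_rejected(self):
        dm, _ = self._cluster_matrix()
        tree = neighbor_joining(dm)
        with pytest.raises(ValueError):
            assign_clades(tree, len(tree.taxa) + 1)
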