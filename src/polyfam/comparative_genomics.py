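"""Collinearity, duplication typing, and homoeolog-triad census.

Anchors are homologous gene pairs annotated with their rank (index in the
full gene order) along each chromosome. Collinear blocks are maximal chains
of anchors whose ranks increase together (or decrease on one side, for
inverted blocks) with bounded rank gaps, extracted best-first by dynamic
programming. Duplicate pairs are typed tandem (near-adjacent on one
chromosome), segmental (inside a detected block), or dispersed.

Homoeologs are grouped by single-linkage over reciprocal-best cross-subgenome
hits restricted to identical chromosome numbers, and each group's subgenome
composition (nA, nB, nD, plus unplaced copies) is classified into the
standard census categories: complete triads (1:1:1), homoeolog-specific
duplication (n:1:1 type), loss of one homoeolog (1:1:0 type), other ratios,
orphans/singletons, and uncategorized.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .formats_io import DomainTableRow, GeneFeature

__all__ = [
    "AnchorPair",
    "SyntenyBlock",
    "HomoeologGroup",
    "TriadSummary",
    "build_anchors",
    "chain_collinear_blocks",
    "classify_duplication",
    "group_homoeologs",
    "classify_ratio",
    "summarize_triads",
    "census_from_domain_table",
]

CATEGORIES = (
    "1:1:1",
    "n:1:1-type",
    "loss-of-one",
    "other",
    "orphan",
    "uncategorized",
)


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class SyntenyBlock:
    anchors: tuple[AnchorPair, ...]
    orientation: str  # "same" or "inverted"

    @property
    def score(self) -> int:
        return len(self.anchors)

    def gene_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a.gene_a, a.gene_b)) for a in self.anchors}


@dataclass(frozen=True)
class HomoeologGroup:
    group_id: int
    members: tuple[str, ...]
    counts: tuple[int, int, int, int]  # (nA, nB, nD, nU)

    @property
    def category(self) -> str:
        return classify_ratio(self.counts)


@dataclass(frozen=True)
class TriadSummary:
    """Per-category group counts, gene counts, and percent of all genes."""

    group_counts: dict[str, int]
    gene_counts: dict[str, int]
    percents: dict[str, float]
    total_genes: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "n_groups": [self.group_counts.get(c, 0) for c in CATEGORIES],
                "n_genes": [self.gene_counts.get(c, 0) for c in CATEGORIES],
                "percent_of_genes": [self.percents.get(c, 0.0) for c in CATEGORIES],
            }
        )


# ---------------------------------------------------------------------------
# Anchors and collinear blocks


def build_anchors(
    homolog_pairs: list[tuple[str, str]],
    features_a: list[GeneFeature],
    features_b: list[GeneFeature],
) -> list[AnchorPair]:
    """Rank-annotated anchors from homolog calls and two gene orders.

    Ranks index the *full* gene order along each chromosome (all genes, not
    only family members). Self-pairs are dropped. Pairs whose genes lack a
    feature are ignored.
    """

    def ranks(features: list[GeneFeature]) -> dict[str, tuple[str, int]]:
        per_chrom: dict[str, list[GeneFeature]] = defaultdict(list)
        for f in features:
            per_chrom[f.chromosome].append(f)
        out = {}
        for chrom, feats in per_chrom.items():
            for rank, f in enumerate(sorted(feats, key=lambda x: (x.start, x.gene_id))):
                out[f.gene_id] = (chrom, rank)
        return out

    ranks_a, ranks_b = ranks(features_a), ranks(features_b)
    anchors = []
    for gene_a, gene_b in homolog_pairs:
        if gene_a == gene_b:
            continue
        if gene_a not in ranks_a or gene_b not in ranks_b:
            continue
        ca, ra = ranks_a[gene_a]
        cb, rb = ranks_b[gene_b]
        anchors.append(AnchorPair(gene_a, gene_b, ca, cb, ra, rb))
    return anchors


def _best_chain(
    anchors: list[AnchorPair], max_gap: int, inverted: bool
) -> list[AnchorPair]:
    """Longest chain with strictly monotone ranks and bounded rank gaps."""
    items = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
    n = len(items)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            da = items[i].rank_a - items[j].rank_a
            if inverted:
                db = items[j].rank_b - items[i].rank_b
            else:
                db = items[i].rank_b - items[j].rank_b
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if n == 0:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -items[i].rank_a))
    chain = []
    while end != -1:
        chain.append(items[end])
        end = prev[end]
    return chain[::-1]


def chain_collinear_blocks(
    anchors: list[AnchorPair], min_anchors: int = 5, max_gap: int = 25
) -> list[SyntenyBlock]:
    """Best-first extraction of maximal collinear chains per chromosome pair.

    Both orientations are considered; the longer chain wins each round, used
    anchors are removed, and extraction repeats until no chain reaches
    ``min_anchors``.
    """
    by_pair: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for a in anchors:
        by_pair[(a.chrom_a, a.chrom_b)].append(a)
    blocks: list[SyntenyBlock] = []
    for pair_key in sorted(by_pair):
        pool = by_pair[pair_key]
        while True:
            fwd = _best_chain(pool, max_gap, inverted=False)
            rev = _best_chain(pool, max_gap, inverted=True)
            chain, orient = (
                (fwd, "same") if len(fwd) >= len(rev) else (rev, "inverted")
            )
            if len(chain) < min_anchors:
                break
            blocks.append(SyntenyBlock(tuple(chain), orient))
            used = set(chain)
            pool = [a for a in pool if a not in used]
    return blocks


def classify_duplication(
    pair: AnchorPair, blocks: list[SyntenyBlock], tandem_window: int = 5
) -> str:
    """'tandem', 'segmental', or 'dispersed'; tandem takes precedence."""
    if pair.chrom_a == pair.chrom_b and abs(pair.rank_a - pair.rank_b) <= tandem_window:
        return "tandem"
    key = frozenset((pair.gene_a, pair.gene_b))
    for block in blocks:
        if key in block.gene_pairs():
            return "segmental"
    return "dispersed"


# ---------------------------------------------------------------------------
# Homoeolog grouping and triad census


def group_homoeologs(
    gene_ids: list[str],
    features: dict[str, GeneFeature],
    cross_subgenome_hits: list[tuple[str, str]],
) -> list[HomoeologGroup]:
    """Single-linkage groups over cross-subgenome hits on matching chromosomes.

    Only pairs from different subgenomes that share a chromosome number can
    link; every family gene lands in exactly one group (possibly a
    singleton).
    """
    parent = {g: g for g in gene_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for a, b in cross_subgenome_hits:
        if a not in parent or b not in parent:
            continue
        fa, fb = features[a], features[b]
        if fa.subgenome == fb.subgenome:
            continue
        if fa.chromosome_number is None or fb.chromosome_number is None:
            continue
        if fa.chromosome_number != fb.chromosome_number:
            continue
        union(a, b)

    components: dict[str, list[str]] = defaultdict(list)
    for g in gene_ids:
        components[find(g)].append(g)
    groups = []
    for gid, members in enumerate(sorted(components.values(), key=lambda m: m[0]), 1):
        counts = [0, 0, 0, 0]
        for g in members:
            sub = features[g].subgenome
            counts["ABDU".index(sub) if sub in "ABDU" else 3] += 1
        groups.append(HomoeologGroup(gid, tuple(sorted(members)), tuple(counts)))
    return groups


def classify_ratio(counts: tuple[int, int, int, int]) -> str:
    """Census category for a group's (nA, nB, nD, nU) subgenome composition.

    Complete triads, homoeolog-specific duplications (n:1:1 type) and
    loss-of-one groups require every copy to be placed (nU == 0); a single
    gene is an orphan; groups spanning at least two subgenomes fall under
    "other"; anything else (e.g. several copies confined to one subgenome, or
    only unplaced copies) is uncategorized.
    """
    na, nb, nd, nu = counts
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    abd = (na, nb, nd)
    if nu == 0:
        if abd == (1, 1, 1):
            return "1:1:1"
        if sorted(abd) == [1, 1, max(abd)] and max(abd) > 1:
            return "n:1:1-type"
        if sorted(abd) == [0, 1, 1]:
            return "loss-of-one"
    if na + nb + nd + nu == 1:
        return "orphan"
    if sum(1 for c in abd if c > 0) >= 2:
        return "other"
    return "uncategorized"


def summarize_triads(
    groups: list[HomoeologGroup], total_genes: int | None = None
) -> TriadSummary:
    """Per-category counts and gene percentages (one decimal)."""
    group_counts: dict[str, int] = defaultdict(int)
    gene_counts: dict[str, int] = defaultdict(int)
    for g in groups:
        cat = g.category
        group_counts[cat] += 1
        gene_counts[cat] += len(g.members)
    n_genes = sum(gene_counts.values())
    if total_genes is None:
        total_genes = n_genes
    elif total_genes != n_genes:
        raise ValueError(
            f"groups hold {n_genes} genes but total_genes={total_genes}"
        )
    percents = {
        cat: round(100.0 * gene_counts[cat] / total_genes, 1) for cat in gene_counts
    }
    return TriadSummary(dict(group_counts), dict(gene_counts), percents, total_genes)


def census_from_domain_table(rows: list[DomainTableRow]) -> TriadSummary:
    """Triad census treating each domain-table row as one homoeologous group."""
    groups = [
        HomoeologGroup(i, row.triad_gene_ids, row.subgenome_counts())
        for i, row in enumerate(rows, 1)
    ]
    return summarize_triads(groups)
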