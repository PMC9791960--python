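"""Family-member identification: similarity search plus domain confirmation.

A candidate protein joins the family catalog when (i) it matches at least one
query sequence by exact local alignment (affine-gap Smith–Waterman, BLOSUM62)
with a Karlin–Altschul E-value below the threshold, and (ii) it carries at
least one Cys4-His-Cys3 zinc-finger motif in the configured span. Accepted
genes are then renamed sequentially along the genome: chromosomes in
numerical order, subgenomes alphabetically within a chromosome number,
physical position within a chromosome, unplaced genes last.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .formats_io import GeneFeature, SequenceRecord

__all__ = [
    "AlignmentHit",
    "DomainHit",
    "CatalogEntry",
    "GeneCatalog",
    "MotifConfig",
    "smith_waterman",
    "smith_waterman_score",
    "estimate_evalue",
    "scan_phd_motif",
    "identify_family",
    "assign_names",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (gap open 11, extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    raw_score: float
    bitscore: float
    evalue: float


@dataclass(frozen=True)
class DomainHit:
    """One Cys4-His-Cys3 motif occurrence; span is 0-based half-open."""

    protein_id: str
    start: int
    end: int
    zinc_ligand_positions: tuple[int, ...]


@dataclass(frozen=True)
class MotifConfig:
    """Spacer ranges between the eight zinc ligands (C-C-C-C-H-C-C-C).

    The defaults follow the canonical PHD consensus
    C-x(1,3)-C-x(8,21)-C-x(2,4)-C-x(4,6)-H-x(1,2)-C-x(10,46)-C-x(2,3)-C
    with the total span clamped to 50-80 residues.
    """

    spacers: tuple[tuple[int, int], ...] = (
        (1, 3), (8, 21), (2, 4), (4, 6), (1, 2), (10, 46), (2, 3),
    )
    span_min: int = 50
    span_max: int = 80

    def __post_init__(self):
        if len(self.spacers) != 7:
            raise ValueError("exactly 7 spacer ranges are required")
        for lo, hi in self.spacers:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid spacer range ({lo}, {hi})")


LIGANDS = "CCCCHCCC"


@dataclass
class CatalogEntry:
    assigned_name: str
    gene_id: str
    feature: GeneFeature
    domain_hits: tuple[DomainHit, ...]


@dataclass
class GeneCatalog:
    """Named family members in naming order, plus an unplaced side channel."""

    entries: list[CatalogEntry] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "name": e.assigned_name,
                    "gene_id": e.gene_id,
                    "chrom": e.feature.chromosome,
                    "start": e.feature.start + 1,  # 1-based on output
                    "end": e.feature.end,
                    "strand": e.feature.strand,
                    "n_domains": len(e.domain_hits),
                    "domain_spans": ";".join(
                        f"{h.start}-{h.end}" for h in e.domain_hits
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "name", "gene_id", "chrom", "start", "end", "strand",
                "n_domains", "domain_spans",
            ],
        )


# ---------------------------------------------------------------------------
# Smith-Waterman


def _encode(seq: str, alphabet: str, x_tolerant: bool) -> np.ndarray:
    index = {aa: i for i, aa in enumerate(alphabet)}
    seq = seq.upper()
    codes = np.empty(len(seq), dtype=np.int64)
    for i, aa in enumerate(seq):
        if aa not in index or (aa in "BZX*" and not x_tolerant):
            if x_tolerant and "X" in index:
                codes[i] = index["X"]
                continue
            raise ValueError(f"unknown residue {aa!r} at position {i}")
        codes[i] = index[aa]
    return codes


def smith_waterman_score(
    query: str,
    target: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    x_tolerant: bool = False,
) -> float:
    """Optimal local-alignment score under affine gaps (Gotoh).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. The inner
    recurrences are vectorized over the target axis; the horizontal-gap state
    is reduced to a running prefix maximum, which is exact because opening a
    gap out of a gap-ended cell is never optimal when gap_open >= gap_extend.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    if gap_open < gap_extend:
        raise ValueError("gap_open must be >= gap_extend")
    matrix = _BLOSUM62 if matrix is None else matrix
    alphabet = str(matrix.alphabet)
    q = _encode(query, alphabet, x_tolerant)
    t = _encode(target, alphabet, x_tolerant)
    S = np.asarray(matrix, dtype=float)

    m, n = len(q), len(t)
    neg_inf = -np.inf
    H_prev = np.zeros(n + 1)
    F_prev = np.full(n + 1, neg_inf)
    offsets = gap_extend * np.arange(1, n + 1)
    best = 0.0
    for i in range(m):
        srow = S[q[i], t]
        F = np.maximum(H_prev[1:] - gap_open, F_prev[1:] - gap_extend)
        diag = H_prev[:-1] + srow
        Hp = np.maximum(0.0, np.maximum(diag, F))
        # horizontal gaps: E[j] = max_{k<j} Hp[k] - open - (j-1-k)*extend
        A = Hp + offsets
        M = np.maximum.accumulate(A)
        E = np.full(n, neg_inf)
        if n > 1:
            E[1:] = M[:-1] - gap_open - gap_extend * np.arange(1, n)
        H = np.maximum(Hp, E)
        best = max(best, float(H.max()))
        H_prev = np.concatenate(([0.0], H))
        F_prev = np.concatenate(([neg_inf], F))
    return best


def estimate_evalue(
    raw_score: float, m: int, n: int, k: float = KA_K, lam: float = KA_LAMBDA
) -> float:
    """Karlin–Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return k * m * n * math.exp(-lam * raw_score)


def smith_waterman(
    query: SequenceRecord | str,
    target: SequenceRecord | str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    database_length: int | None = None,
    x_tolerant: bool = False,
) -> AlignmentHit:
    """Local alignment of two sequences, returning scores and an E-value.

    ``database_length`` defaults to the target length; pass the total residue
    count of the search database when screening a proteome.
    """
    q_id, q_seq = _record_parts(query)
    t_id, t_seq = _record_parts(target)
    score = smith_waterman_score(
        q_seq, t_seq, matrix=matrix, gap_open=gap_open,
        gap_extend=gap_extend, x_tolerant=x_tolerant,
    )
    n = database_length if database_length is not None else len(t_seq)
    bits = (KA_LAMBDA * score - math.log(KA_K)) / math.log(2.0)
    return AlignmentHit(q_id, t_id, score, bits, estimate_evalue(score, len(q_seq), n))


def _record_parts(rec) -> tuple[str, str]:
    if isinstance(rec, SequenceRecord):
        return rec.id, rec.sequence
    return "", str(rec)


# ---------------------------------------------------------------------------
# Motif scan


def _match_at(seq: str, start: int, cfg: MotifConfig) -> tuple[int, ...] | None:
    """Smallest-positions motif match anchored at ``start``, or None.

    Depth-first search over spacer lengths in ascending order with failure
    memoization; enforces the total-span window at the final ligand.
    """
    n = len(seq)
    if start >= n or seq[start] != LIGANDS[0]:
        return None
    max_end = start + cfg.span_max  # exclusive bound on ligand positions
    failed: set[tuple[int, int]] = set()

    def search(idx: int, pos: int) -> list[int] | None:
        # ligand idx placed at pos; place ligand idx+1
        if idx == len(LIGANDS) - 1:
            span = pos - start + 1
            return [pos] if cfg.span_min <= span <= cfg.span_max else None
        if (idx, pos) in failed:
            return None
        lo, hi = cfg.spacers[idx]
        for gap in range(lo, hi + 1):
            nxt = pos + gap + 1
            if nxt >= n or nxt >= max_end:
                break
            if seq[nxt] != LIGANDS[idx + 1]:
                continue
            rest = search(idx + 1, nxt)
            if rest is not None:
                return [pos] + rest
        failed.add((idx, pos))
        return None

    result = search(0, start)
    return tuple(result) if result is not None else None


def scan_phd_motif(
    protein: SequenceRecord | str, cfg: MotifConfig | None = None
) -> list[DomainHit]:
    """Non-overlapping Cys4-His-Cys3 motif occurrences, leftmost-shortest first.

    A nucleotide-looking sequence (ACGTN alphabet only) triggers a warning
    and an empty result.
    """
    cfg = cfg or MotifConfig()
    pid, seq = _record_parts(protein)
    seq = seq.upper()
    if seq and set(seq) <= set("ACGTN"):
        warnings.warn(
            f"sequence {pid or '<anonymous>'} looks like a nucleotide sequence; "
            "no motif scan performed"
        )
        return []
    hits: list[DomainHit] = []
    pos = 0
    while pos < len(seq):
        if seq[pos] != "C":
            pos += 1
            continue
        ligands = _match_at(seq, pos, cfg)
        if ligands is None:
            pos += 1
            continue
        hits.append(DomainHit(pid, ligands[0], ligands[-1] + 1, ligands))
        pos = ligands[-1] + 1
    return hits


# ---------------------------------------------------------------------------
# Catalog assembly


def assign_names(
    accepted: list[tuple[str, GeneFeature, tuple[DomainHit, ...]]],
    prefix: str,
) -> list[CatalogEntry]:
    """Sequential names along the genome.

    Sort key: (chromosome number, subgenome letter, start, gene id); genes on
    unplaced scaffolds sort last, ordered by gene id.
    """

    def key(item):
        _gene_id, feature, _hits = item
        num = feature.chromosome_number
        if num is None:
            return (1, "", "", 0, item[0])
        return (0, num, feature.subgenome, feature.start, item[0])

    ordered = sorted(accepted, key=key)
    return [
        CatalogEntry(f"{prefix}{i}", gene_id, feature, hits)
        for i, (gene_id, feature, hits) in enumerate(ordered, start=1)
    ]


def identify_family(
    proteome: list[SequenceRecord],
    queries: list[SequenceRecord],
    features: list[GeneFeature],
    evalue_threshold: float = 1e-5,
    prefix: str = "FAM",
    motif_config: MotifConfig | None = None,
    transcript_parents: dict[str, str] | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> GeneCatalog:
    """Two-stage family identification: similarity gate plus motif confirmation.

    When several proteins share a parent gene (``transcript_parents`` maps
    protein/mRNA id to gene id), the lexicographically first protein id is the
    gene's representative. Accepted proteins without a genome feature are
    recorded on the catalog's ``unplaced`` list, not dropped silently.

    The result is deterministic and independent of the input order of
    ``proteome``.
    """
    motif_config = motif_config or MotifConfig()
    transcript_parents = transcript_parents or {}
    feature_by_gene = {f.gene_id: f for f in features}

    # representative protein per gene (first splice variant by id)
    by_gene: dict[str, SequenceRecord] = {}
    for rec in sorted(proteome, key=lambda r: r.id):
        gene = transcript_parents.get(rec.id, rec.id)
        if gene not in by_gene:
            by_gene[gene] = rec

    database_length = sum(len(r.sequence) for r in proteome)
    accepted: list[tuple[str, GeneFeature, tuple[DomainHit, ...]]] = []
    unplaced: list[str] = []
    for gene_id in sorted(by_gene):
        rec = by_gene[gene_id]
        hits = scan_phd_motif(rec, motif_config)
        if not hits:
            continue
        passed = False
        for qry in queries:
            hit = smith_waterman(
                qry, rec, database_length=database_length,
                gap_open=gap_open, gap_extend=gap_extend,
            )
            if hit.evalue < evalue_threshold:
                passed = True
                break
        if not passed:
            continue
        feature = feature_by_gene.get(gene_id)
        if feature is None:
            unplaced.append(gene_id)
            continue
        accepted.append((gene_id, feature, tuple(hits)))

    catalog = GeneCatalog(entries=assign_names(accepted, prefix), unplaced=unplaced)
    return catalog
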