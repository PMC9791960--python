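"""Readers and writers for the file formats the pipeline touches.

Sequence files are plain FASTA (wrapped at 60 columns on output), gene models
are GFF3 (1-based inclusive on disk, converted once at read time to the
internal 0-based half-open convention), trees are Newick with integer
bootstrap labels on internal nodes, and tables are TSV with a header row.

All readers reject malformed input instead of repairing it; parse errors
carry the offending line number or record id.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "GeneFeature",
    "DomainTableRow",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_gff3_transcripts",
    "parse_domain_table",
    "packaged_domain_table",
    "write_gff3",
    "write_newick",
    "read_tsv",
]

CHROM_RE = re.compile(r"^(\d+)([A-Z])$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A FASTA record: id, free-text description, uppercase residues."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus. ``start``/``end`` are 0-based half-open internally."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    @property
    def subgenome(self) -> str:
        """Subgenome letter parsed from the chromosome suffix ('U' if unplaced)."""
        m = CHROM_RE.match(self.chromosome)
        return m.group(2) if m else "U"

    @property
    def chromosome_number(self) -> int | None:
        m = CHROM_RE.match(self.chromosome)
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class DomainTableRow:
    """One row of the packaged domain-architecture table.

    ``genomes_field`` is the raw subgenome string (letters A/B/D plus 'U' for
    unplaced copies; parenthesized letters mark duplicated placements, e.g.
    "A(DD)UU").
    """

    domain_type: str
    triad_gene_ids: tuple[str, ...]
    gene_number: int
    chromosome_field: str
    genomes_field: str

    def subgenome_counts(self) -> tuple[int, int, int, int]:
        """(nA, nB, nD, nU) from the genomes string, parentheses stripped."""
        letters = self.genomes_field.replace("(", "").replace(")", "")
        return (
            letters.count("A"),
            letters.count("B"),
            letters.count("D"),
            letters.count("U"),
        )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order.

    Duplicate ids and empty sequences are format errors naming the record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: empty sequence for record {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, desc, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def _parse_gff3_lines(path, keep_types: set[str]):
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if cols[2] not in keep_types:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            yield lineno, cols, start1, end1, attrs


def read_gff3(path) -> list[GeneFeature]:
    """Read ``gene`` features, sorted by (chromosome, start).

    Disk coordinates are 1-based inclusive; the returned features use the
    internal 0-based half-open convention.
    """
    feats: list[GeneFeature] = []
    for lineno, cols, start1, end1, attrs in _parse_gff3_lines(path, {"gene"}):
        gene_id = attrs.get("ID")
        if not gene_id:
            raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
        feats.append(
            GeneFeature(gene_id, cols[0], start1 - 1, end1, cols[6])
        )
    feats.sort(key=lambda f: (f.chromosome, f.start, f.gene_id))
    return feats


def read_gff3_transcripts(path) -> dict[str, str]:
    """Map mRNA ID -> parent gene ID (for splice-variant representative choice)."""
    parents: dict[str, str] = {}
    for lineno, _cols, _s, _e, attrs in _parse_gff3_lines(path, {"mRNA"}):
        mrna, gene = attrs.get("ID"), attrs.get("Parent")
        if not mrna or not gene:
            raise FormatError(f"{path}:{lineno}: mRNA feature without ID/Parent")
        parents[mrna] = gene
    return parents


# ---------------------------------------------------------------------------
# Domain-architecture table (packaged fixture)


def parse_domain_table(path) -> list[DomainTableRow]:
    """Parse the domain-architecture TSV (domain_type, genes, gene_number, chr, genomes)."""
    rows: list[DomainTableRow] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["domain_type", "genes", "gene_number", "chr", "genomes"]
        if header != expected:
            raise FormatError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(handle, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            dom, genes_s, n_s, chrom, genomes = cols
            genes = tuple(genes_s.split("/"))
            if len(genes) != int(n_s):
                raise FormatError(
                    f"{path}:{lineno}: gene_number {n_s} != {len(genes)} listed genes"
                )
            for g in genes:
                if g in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate gene id {g!r}")
                seen.add(g)
            rows.append(DomainTableRow(dom, genes, int(n_s), chrom, genomes))
    return rows


def packaged_domain_table() -> list[DomainTableRow]:
    """The wheat PHD-finger domain-architecture table shipped with the package."""
    ref = resources.files("polyfam").joinpath("data/table1_domains.tsv")
    with resources.as_file(ref) as path:
        return parse_domain_table(path)


def write_gff3(
    features: Iterable[GeneFeature],
    path,
    transcripts: dict[str, str] | None = None,
    source: str = "polyfam",
) -> None:
    """Write gene (and optional mRNA) features as GFF3, 1-based inclusive.

    ``transcripts`` maps mRNA id -> parent gene id; each mRNA inherits its
    parent's coordinates. Reading the file back with :func:`read_gff3`
    returns the same gene features.
    """
    feats = sorted(features, key=lambda f: (f.chromosome, f.start, f.gene_id))
    children: dict[str, list[str]] = {}
    for mrna, gene in (transcripts or {}).items():
        children.setdefault(gene, []).append(mrna)
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for f in feats:
            start1, end1 = f.start + 1, f.end
            handle.write(
                f"{f.chromosome}\t{source}\tgene\t{start1}\t{end1}\t.\t"
                f"{f.strand}\t.\tID={f.gene_id}\n"
            )
            for mrna in sorted(children.get(f.gene_id, [])):
                handle.write(
                    f"{f.chromosome}\t{source}\tmRNA\t{start1}\t{end1}\t.\t"
                    f"{f.strand}\t.\tID={mrna};Parent={f.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree, path_or_handle) -> None:
    """Serialize a tree (phylogenetics.Tree) with 6-decimal branch lengths.

    Internal node labels are integer bootstrap supports when present.
    """
    text = tree.to_newick()
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text + "\n")
    else:
        with _open_text(path_or_handle, "wt") as handle:
            handle.write(text + "\n")


# ---------------------------------------------------------------------------
# Generic TSV helpers (thin pandas wrappers, kept here so every on-disk table
# goes through one place)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
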