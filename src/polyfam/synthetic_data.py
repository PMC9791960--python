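"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators are provided:

* :func:`generate_family_genome` — a three-subgenome genome whose family
  genes form homoeologous groups drawn from a configurable A:B:D ratio
  mixture, each family protein carrying a planted Cys4-His-Cys3 motif;
* :func:`evolve_codon_pair` — codon-sequence pairs diverged under a
  continuous-time single-nucleotide substitution process with a known
  nonsynonymous/synonymous acceptance ratio (omega) and branch length;
* :func:`generate_expression_matrix` — TPM matrices with lognormal baseline
  expression, planted differentially expressed genes, replicate noise, and
  optional exact zeros;
* :func:`generate_qpcr_table` — Ct tables with planted expression fold
  changes and Gaussian technical noise.

All generators are bit-deterministic for a fixed seed; sub-streams are keyed
by (seed, fixed offset) so adding one generator never perturbs another.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .family_identification import MotifConfig
from .formats_io import GeneFeature, SequenceRecord, write_fasta, write_gff3
from .molecular_evolution import CODON_TO_AA, STOP_CODONS

__all__ = [
    "FamilySimulationConfig",
    "SimulationTruth",
    "SyntheticGenome",
    "generate_family_genome",
    "evolve_codon_pair",
    "generate_expression_matrix",
    "generate_qpcr_table",
]

# residues used for non-ligand positions of family proteins: no Cys/His, so
# the planted motif is the only Cys4-His-Cys3 match in the sequence
_FILLER = "ADEFGIKLMNPQRSTVWY"
_ALL_AA = "ACDEFGHIKLMNPQRSTVWY"

RATIO_CATEGORIES = ("1:1:1", "n:1:1", "1:1:0", "other", "orphan")

_SENSE_CODONS = tuple(sorted(CODON_TO_AA))

# codons per amino acid, for reverse translation
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_aa, ())
_AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in set(CODON_TO_AA.values())
}


@dataclass(frozen=True)
class FamilySimulationConfig:
    """Parameters of the synthetic polyploid genome.

    The default ratio mixture follows the homoeolog-retention profile
    observed for the wheat PHD family (predominantly complete triads, a few
    loss-of-one groups, rare subgenome-specific duplications and orphans).
    """

    seed: int = 0
    n_groups: int = 20
    ratio_mixture: dict = field(
        default_factory=lambda: {
            "1:1:1": 0.81,
            "n:1:1": 0.01,
            "1:1:0": 0.10,
            "other": 0.04,
            "orphan": 0.04,
        }
    )
    subgenomes: tuple[str, ...] = ("A", "B", "D")
    chromosomes_per_subgenome: int = 2
    n_background_genes: int = 10
    motif_spacer_ranges: tuple[tuple[int, int], ...] = MotifConfig().spacers
    protein_length_range: tuple[int, int] = (150, 300)
    homoeolog_mutation_rate: float = 0.03

    def __post_init__(self):
        total = sum(self.ratio_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ratio_mixture proportions sum to {total}, not 1")
        unknown = set(self.ratio_mixture) - set(RATIO_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown ratio categories {sorted(unknown)}")
        if self.n_groups < 0 or self.n_background_genes < 0:
            raise ValueError("counts must be nonnegative")
        if self.chromosomes_per_subgenome < 1:
            raise ValueError("need at least one chromosome per subgenome")
        for lo, hi in self.motif_spacer_ranges:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid spacer range ({lo}, {hi})")
        lo, hi = self.protein_length_range
        if lo > hi or lo < 100:
            raise ValueError("protein_length_range must satisfy 100 <= min <= max")


@dataclass
class SimulationTruth:
    """Ground truth emitted next to the synthetic files."""

    family_gene_ids: set[str] = field(default_factory=set)
    group_assignments: dict[str, int] = field(default_factory=dict)
    group_ratio_category: dict[int, str] = field(default_factory=dict)
    planted_motifs: dict[str, tuple[int, ...]] = field(default_factory=dict)
    background_gene_ids: set[str] = field(default_factory=set)
    de_gene_ids: dict[str, set[str]] = field(default_factory=dict)
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_omega: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "family_gene_ids": sorted(self.family_gene_ids),
            "group_assignments": self.group_assignments,
            "group_ratio_category": {
                str(k): v for k, v in self.group_ratio_category.items()
            },
            "planted_motifs": {k: list(v) for k, v in self.planted_motifs.items()},
            "background_gene_ids": sorted(self.background_gene_ids),
            "de_gene_ids": {k: sorted(v) for k, v in self.de_gene_ids.items()},
            "planted_log2fc": self.planted_log2fc,
            "planted_omega": self.planted_omega,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticGenome:
    """In-memory result of :func:`generate_family_genome`."""

    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    features: list[GeneFeature]
    queries: list[SequenceRecord]
    transcripts: dict[str, str]
    truth: SimulationTruth

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.fa",
            "cds": outdir / "cds.fa",
            "gff3": outdir / "genome.gff3",
            "queries": outdir / "queries.fa",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        write_gff3(self.features, paths["gff3"], transcripts=self.transcripts)
        write_fasta(self.queries, paths["queries"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


# ---------------------------------------------------------------------------
# protein/CDS construction helpers


def _sample_motif(rng: np.random.Generator, spacers) -> tuple[str, tuple[int, ...]]:
    """Motif string and relative ligand positions with total span in [50, 80]."""
    ligands = "CCCCHCCC"
    while True:
        gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in spacers]
        span = 8 + sum(gaps)
        if 50 <= span <= 80:
            break
    positions = [0]
    for gap in gaps:
        positions.append(positions[-1] + gap + 1)
    chars = list(rng.choice(list(_FILLER), size=span))
    for lig, pos in zip(ligands, positions):
        chars[pos] = lig
    return "".join(chars), tuple(positions)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _plant_motif(
    rng: np.random.Generator, length: int, spacers
) -> tuple[str, int, tuple[int, ...]]:
    motif, rel = _sample_motif(rng, spacers)
    if length < len(motif) + 20:
        length = len(motif) + 20
    offset = int(rng.integers(10, length - len(motif) - 9))
    before = _random_protein(rng, offset, _FILLER)
    after = _random_protein(rng, length - offset - len(motif), _FILLER)
    seq = before + motif + after
    return seq, offset, tuple(offset + p for p in rel)


def _mutate_outside(
    rng: np.random.Generator, seq: str, protected: set[int], rate: float
) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < rate:
            chars[i] = rng.choice(list(_FILLER))
    return "".join(chars)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))] for aa in protein
    ]
    stop = sorted(STOP_CODONS)[int(rng.integers(len(STOP_CODONS)))]
    return "".join(codons) + stop


def _descend_cds(
    rng: np.random.Generator,
    ancestor_cds: str,
    ancestor_protein: str,
    derived_protein: str,
    synonymous_rate: float = 0.05,
) -> str:
    """Derive a copy's CDS from the group ancestor CDS.

    Nonsynonymous protein changes pick a random codon of the new residue;
    unchanged positions keep the ancestral codon except for a low rate of
    synonymous codon swaps, so homoeologous CDS pairs show modest, dateable
    synonymous divergence.
    """
    codons = []
    for i, (old_aa, new_aa) in enumerate(zip(ancestor_protein, derived_protein)):
        codon = ancestor_cds[3 * i : 3 * i + 3]
        if new_aa != old_aa:
            options = _AA_TO_CODONS[new_aa]
            codon = options[int(rng.integers(len(options)))]
        elif rng.random() < synonymous_rate:
            options = _AA_TO_CODONS[old_aa]
            codon = options[int(rng.integers(len(options)))]
        codons.append(codon)
    return "".join(codons) + ancestor_cds[-3:]


def _category_counts(
    rng: np.random.Generator, category: str, n_sub: int
) -> list[int]:
    """Per-subgenome gene counts implementing one ratio category."""
    counts = [1] * n_sub
    if category == "1:1:1":
        return counts
    if category == "n:1:1":
        counts[int(rng.integers(n_sub))] = 2
        return counts
    if category == "1:1:0":
        counts[int(rng.integers(n_sub))] = 0
        return counts
    if category == "other":
        # e.g. 0:1:n patterns: one subgenome lost, another duplicated
        zero, dup = rng.choice(n_sub, size=2, replace=False)
        counts[int(zero)] = 0
        counts[int(dup)] = 2
        return counts
    if category == "orphan":
        counts = [0] * n_sub
        counts[int(rng.integers(n_sub))] = 1
        return counts
    raise ValueError(f"unknown category {category!r}")


def generate_family_genome(config: FamilySimulationConfig) -> SyntheticGenome:
    """Generate a synthetic polyploid genome with planted family genes.

    Homoeologs of one group sit on the same chromosome number of different
    subgenomes and are high-identity copies of a common ancestor protein
    whose planted motif is preserved; per-group ancestors are emitted as the
    query set. Background genes are motif-free random proteins. Gene
    coordinates are non-overlapping and strictly increasing per chromosome.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = SimulationTruth()
    n_sub = len(config.subgenomes)

    categories = list(config.ratio_mixture)
    probs = np.array([config.ratio_mixture[c] for c in categories])
    lo_len, hi_len = config.protein_length_range

    # genes keyed by chromosome label, as (gene_id, protein, order_key)
    genes_by_chrom: dict[str, list[tuple[str, str]]] = {
        f"{num}{sub}": []
        for sub in config.subgenomes
        for num in range(1, config.chromosomes_per_subgenome + 1)
    }
    proteins: list[SequenceRecord] = []
    queries: list[SequenceRecord] = []

    for group in range(1, config.n_groups + 1):
        category = categories[int(rng.choice(len(categories), p=probs))]
        counts = _category_counts(rng, category, n_sub)
        chrom_num = int(rng.integers(1, config.chromosomes_per_subgenome + 1))
        length = int(rng.integers(lo_len, hi_len + 1))
        ancestor, _offset, ligands = _plant_motif(
            rng, length, config.motif_spacer_ranges
        )
        queries.append(
            SequenceRecord(f"QRY{group:03d}", f"group {group} ancestor", ancestor)
        )
        truth.group_ratio_category[group] = category
        protected = set(ligands)
        ancestor_cds = _reverse_translate(rng, ancestor)
        copy_idx = 0
        for sub, count in zip(config.subgenomes, counts):
            for _ in range(count):
                copy_idx += 1
                gene_id = f"FAM{group:03d}{sub}{copy_idx}"
                seq = _mutate_outside(
                    rng, ancestor, protected, config.homoeolog_mutation_rate
                )
                cds = _descend_cds(rng, ancestor_cds, ancestor, seq)
                genes_by_chrom[f"{chrom_num}{sub}"].append((gene_id, seq, cds))
                truth.family_gene_ids.add(gene_id)
                truth.group_assignments[gene_id] = group
                truth.planted_motifs[gene_id] = ligands

    # background genes: random full-alphabet proteins, rejection-sampled to
    # be motif-free so specificity against truth is exact
    from .family_identification import scan_phd_motif

    motif_cfg = MotifConfig(spacers=config.motif_spacer_ranges)
    for chrom in sorted(genes_by_chrom):
        for i in range(config.n_background_genes):
            gene_id = f"BG{chrom}{i:03d}"
            while True:
                seq = _random_protein(
                    rng, int(rng.integers(lo_len, hi_len + 1)), _ALL_AA
                )
                if not scan_phd_motif(seq, motif_cfg):
                    break
            genes_by_chrom[chrom].append((gene_id, seq, _reverse_translate(rng, seq)))
            truth.background_gene_ids.add(gene_id)

    # lay out coordinates: shuffle gene order per chromosome, then strictly
    # increasing, non-overlapping spans
    features: list[GeneFeature] = []
    cds_records: list[SequenceRecord] = []
    transcripts: dict[str, str] = {}
    for chrom in sorted(genes_by_chrom):
        entries = genes_by_chrom[chrom]
        order = rng.permutation(len(entries))
        pos = 0
        for idx in order:
            gene_id, seq, cds = entries[idx]
            pos += int(rng.integers(500, 2000))
            gene_len = 3 * (len(seq) + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(GeneFeature(gene_id, chrom, pos, pos + gene_len, strand))
            proteins.append(SequenceRecord(f"{gene_id}.1", "", seq))
            cds_records.append(SequenceRecord(f"{gene_id}.1", "", cds))
            transcripts[f"{gene_id}.1"] = gene_id
            pos += gene_len

    proteins.sort(key=lambda r: r.id)
    cds_records.sort(key=lambda r: r.id)
    return SyntheticGenome(proteins, cds_records, features, queries, transcripts, truth)


# ---------------------------------------------------------------------------
# codon-pair evolution


def _codon_neighbors():
    """codon -> list of (neighbor, kind) over single-nucleotide changes."""
    out: dict[str, list[tuple[str, str]]] = {}
    for codon in _SENSE_CODONS:
        nbrs = []
        for pos, base in itertools.product(range(3), "ACGT"):
            if codon[pos] == base:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                kind = "stop"
            elif CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                kind = "syn"
            else:
                kind = "nonsyn"
            nbrs.append((alt, kind))
        out[codon] = nbrs
    return out


_NEIGHBORS = _codon_neighbors()


def _evolve_codon(
    rng: np.random.Generator, codon: str, time: float, omega: float
) -> str:
    """Gillespie simulation of one codon for the given duration.

    Each single-nucleotide change fires at rate 1/3 (synonymous) or omega/3
    (nonsynonymous); changes to stop codons are forbidden. At omega == 1 and
    no stop constraint this is one expected substitution per nucleotide site
    per unit time.
    """
    t = 0.0
    while True:
        rates = np.array(
            [
                (1.0 if kind == "syn" else omega) / 3.0
                for _alt, kind in _NEIGHBORS[codon]
                if kind != "stop"
            ]
        )
        targets = [alt for alt, kind in _NEIGHBORS[codon] if kind != "stop"]
        total = rates.sum()
        if total <= 0:
            return codon
        t += rng.exponential(1.0 / total)
        if t >= time:
            return codon
        codon = targets[int(rng.choice(len(targets), p=rates / total))]


def evolve_codon_pair(
    seed: int, n_codons: int, branch_length: float, omega: float
) -> tuple[str, str]:
    """A pair of codon sequences diverged by ``branch_length`` at ratio omega.

    A random sense-codon ancestor evolves independently down two branches of
    length ``branch_length / 2`` each; ``branch_length`` is the expected
    number of accepted substitutions per nucleotide site between the pair at
    omega = 1. Returns (seq_a, seq_b).
    """
    if n_codons < 30:
        raise ValueError("n_codons must be >= 30")
    if branch_length < 0 or omega < 0:
        raise ValueError("branch_length and omega must be nonnegative")
    rng = np.random.default_rng([seed, 2])
    half = branch_length / 2.0
    a_parts, b_parts = [], []
    for _ in range(n_codons):
        ancestor = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        a_parts.append(_evolve_codon(rng, ancestor, half, omega))
        b_parts.append(_evolve_codon(rng, ancestor, half, omega))
    return "".join(a_parts), "".join(b_parts)


# ---------------------------------------------------------------------------
# expression and qPCR


def generate_expression_matrix(
    seed: int,
    n_genes: int = 200,
    conditions: tuple[str, ...] = ("control", "treated"),
    replicates: int = 3,
    de_fraction: float = 0.1,
    lfc_magnitude: float = 2.0,
    dispersion: float = 0.25,
    zero_inflation: float | dict[str, float] = 0.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """TPM matrix (genes x samples) with planted differential expression.

    Baseline per-gene expression is lognormal (meanlog 3, sdlog 1.5 on the
    natural-log TPM scale); replicate noise is lognormal with sdlog
    ``dispersion``. In every non-control condition a fraction
    ``de_fraction`` of genes is shifted by +/- ``lfc_magnitude`` log2 units.
    ``zero_inflation`` (scalar, or per-sample dict) sets values to exact 0.
    """
    if replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    log_base = rng.normal(3.0, 1.5, size=n_genes)
    truth = SimulationTruth()
    columns = {}
    n_de = int(round(de_fraction * n_genes))
    for cond_idx, cond in enumerate(conditions):
        shift = np.zeros(n_genes)
        if cond_idx > 0 and n_de > 0:
            de_idx = rng.choice(n_genes, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            shift[de_idx] = signs * lfc_magnitude * np.log(2.0)
            truth.de_gene_ids[cond] = {genes[i] for i in de_idx}
            truth.planted_log2fc[cond] = {
                genes[i]: float(s * lfc_magnitude) for i, s in zip(de_idx, signs)
            }
        else:
            truth.de_gene_ids[cond] = set()
            truth.planted_log2fc[cond] = {}
        for rep in range(1, replicates + 1):
            sample = f"{cond}_rep{rep}"
            noise = rng.normal(0.0, dispersion, size=n_genes)
            values = np.exp(log_base + shift + noise)
            rate = (
                zero_inflation.get(sample, 0.0)
                if isinstance(zero_inflation, dict)
                else zero_inflation
            )
            if rate > 0:
                zeros = rng.random(n_genes) < rate
                values[zeros] = 0.0
            columns[sample] = values
    tpm = pd.DataFrame(columns, index=genes)
    return tpm, truth


def generate_qpcr_table(
    seed: int,
    genes: tuple[str, ...],
    treatments: tuple[str, ...],
    timepoints: tuple = (0, 1, 6, 12),
    planted_fold_changes: dict | None = None,
    ct_noise_sd: float = 0.2,
    reference_gene: str = "beta_actin",
    control_treatment: str = "control",
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Ct table with planted fold changes: columns gene, treatment,
    timepoint, replicate, ct.

    The reference gene is always emitted for every condition. A planted fold
    f for (gene, treatment, timepoint) lowers the target Ct by log2(f)
    relative to the control treatment at the same timepoint; Gaussian noise
    of sd ``ct_noise_sd`` is added per technical replicate.
    """
    if reference_gene in genes:
        raise ValueError("reference gene must not be listed among target genes")
    planted = planted_fold_changes or {}
    rng = np.random.default_rng([seed, 4])
    baseline = {g: float(rng.uniform(24.0, 28.0)) for g in genes}
    ref_ct = 20.0
    rows = []
    truth = SimulationTruth()
    for treatment in (control_treatment,) + tuple(
        t for t in treatments if t != control_treatment
    ):
        for timepoint in timepoints:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": reference_gene,
                        "treatment": treatment,
                        "timepoint": timepoint,
                        "replicate": rep,
                        "ct": ref_ct + rng.normal(0.0, ct_noise_sd),
                    }
                )
            for gene in genes:
                fold = 1.0
                if treatment != control_treatment:
                    fold = float(planted.get((gene, treatment, timepoint), 1.0))
                for rep in range(1, n_replicates + 1):
                    ct_val = (
                        baseline[gene]
                        - np.log2(fold)
                        + rng.normal(0.0, ct_noise_sd)
                    )
                    rows.append(
                        {
                            "gene": gene,
                            "treatment": treatment,
                            "timepoint": timepoint,
                            "replicate": rep,
                            "ct": float(ct_val),
                        }
                    )
    return pd.DataFrame(rows), truth
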