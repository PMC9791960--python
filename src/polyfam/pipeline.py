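"""End-to-end orchestration of the family-characterization stages.

The pipeline runs, in dependency order: family identification, protein
statistics, phylogeny (when an alignment is supplied), homoeolog grouping
and triad census, collinearity and duplication typing, Ka/Ks with clock
dating, expression binning/DEG calling, and qPCR quantification. Every stage
is optional; outputs are TSV/Newick/JSON files in the run directory, and a
run report records per-stage record counts and the parameter set.

:func:`make_demo` builds a complete synthetic workspace (genome, expression
matrix, Ct table, alignment) and runs the pipeline on it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    comparative_genomics as cg,
    expression_analysis as ea,
    family_identification as fi,
    formats_io as io,
    molecular_evolution as me,
    phylogenetics as phylo,
    synthetic_data as syn,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_demo"]


@dataclass
class PipelineConfig:
    """All inputs and stage parameters, with the documented defaults."""

    # inputs
    proteome: str | None = None
    cds: str | None = None
    gff3: str | None = None
    queries: str | None = None
    alignment: str | None = None
    tpm: str | None = None
    ct_table: str | None = None
    outdir: str = "polyfam_run"
    # stage toggles
    run_identify: bool = True
    run_properties: bool = True
    run_tree: bool = True
    run_synteny: bool = True
    run_triads: bool = True
    run_kaks: bool = True
    run_expression: bool = True
    run_qpcr: bool = True
    # parameters (defaults follow the published analysis settings)
    evalue_threshold: float = 1e-5
    name_prefix: str = "FAM"
    bootstrap_replicates: int = 1000
    n_clades: int = 4
    min_anchors: int = 5
    max_gap: int = 25
    tandem_window: int = 5
    lambda_rate: float = 6.5e-9
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    pseudocount: float = 1.0
    reference_gene: str = "beta_actin"
    control_treatment: str = "control"
    control_samples: tuple[str, ...] = ()
    treated_samples: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("control_samples", "treated_samples"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["control_samples"] = list(self.control_samples)
        data["treated_samples"] = list(self.treated_samples)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "counts": self.counts,
                    "parameters": self.parameters,
                    "warnings": self.warnings,
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _cross_subgenome_hits(
    catalog: fi.GeneCatalog, proteins_by_gene: dict[str, str]
) -> list[tuple[str, str]]:
    """Reciprocal-best cross-subgenome hits among catalog genes.

    Best hits are computed per (gene, other subgenome) by Smith-Waterman
    score, restricted to genes on the same chromosome number.
    """
    entries = catalog.entries
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for e1 in entries:
        for e2 in entries:
            if e1.gene_id >= e2.gene_id:
                continue
            f1, f2 = e1.feature, e2.feature
            if f1.subgenome == f2.subgenome:
                continue
            if f1.chromosome_number != f2.chromosome_number:
                continue
            score = fi.smith_waterman_score(
                proteins_by_gene[e1.gene_id], proteins_by_gene[e2.gene_id]
            )
            for a, b in ((e1.gene_id, e2.gene_id), (e2.gene_id, e1.gene_id)):
                sub_b = (f2 if a == e1.gene_id else f1).subgenome
                key = (a, sub_b)
                if key not in best or score > best[key][0]:
                    best[key] = (score, b)
    hits = []
    for (a, _sub), (_score, b) in best.items():
        fa = next(e.feature for e in entries if e.gene_id == a)
        back = best.get((b, fa.subgenome))
        if back and back[1] == a and a < b:
            hits.append((a, b))
    return sorted(hits)


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=dataclasses.asdict(config))

    catalog = None
    proteins_by_gene: dict[str, str] = {}
    features: list[io.GeneFeature] = []

    if config.run_identify:
        try:
            if not (config.proteome and config.gff3 and config.queries):
                raise ValueError("identify stage needs proteome, gff3 and queries")
            proteome = io.read_fasta(config.proteome)
            queries = io.read_fasta(config.queries)
            features = io.read_gff3(config.gff3)
            transcripts = io.read_gff3_transcripts(config.gff3)
            catalog = fi.identify_family(
                proteome,
                queries,
                features,
                evalue_threshold=config.evalue_threshold,
                prefix=config.name_prefix,
                transcript_parents=transcripts,
            )
            rep_by_gene = {}
            for rec in sorted(proteome, key=lambda r: r.id):
                gene = transcripts.get(rec.id, rec.id)
                rep_by_gene.setdefault(gene, rec.sequence)
            proteins_by_gene = rep_by_gene
            catalog.to_dataframe().to_csv(outdir / "catalog.tsv", sep="\t", index=False)
            report.counts["catalog"] = len(catalog)
            if catalog.unplaced:
                report.warnings.append(
                    f"{len(catalog.unplaced)} family genes without coordinates"
                )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("identify", exc) from exc

    if config.run_properties and catalog is not None:
        try:
            seqs = {e.assigned_name: proteins_by_gene[e.gene_id] for e in catalog.entries}
            stats, extremes = _properties(seqs)
            stats.to_csv(outdir / "protein_stats.tsv", sep="\t", index=False)
            extremes.to_csv(outdir / "protein_extremes.tsv", sep="\t", index=False)
            report.counts["protein_stats"] = len(stats)
        except Exception as exc:
            raise StageError("properties", exc) from exc

    if config.run_tree and config.alignment:
        try:
            aln = [(r.id, r.sequence) for r in io.read_fasta(config.alignment)]
            tree = phylo.bootstrap_support(
                aln, config.bootstrap_replicates, seed=config.seed
            )
            io.write_newick(tree, outdir / "tree.nwk")
            clades = phylo.assign_clades(tree, config.n_clades)
            pd.DataFrame(
                sorted(clades.items()), columns=["taxon", "clade"]
            ).to_csv(outdir / "clades.tsv", sep="\t", index=False)
            report.counts["tree_taxa"] = len(aln)
        except Exception as exc:
            raise StageError("tree", exc) from exc

    groups: list[cg.HomoeologGroup] = []
    if config.run_triads and catalog is not None:
        try:
            hits = _cross_subgenome_hits(catalog, proteins_by_gene)
            feats = {e.gene_id: e.feature for e in catalog.entries}
            groups = cg.group_homoeologs(catalog.gene_ids(), feats, hits)
            summary = cg.summarize_triads(groups)
            summary.to_dataframe().to_csv(outdir / "triad_census.tsv", sep="\t", index=False)
            rows = [
                {
                    "group_id": g.group_id,
                    "members": ";".join(g.members),
                    "nA": g.counts[0],
                    "nB": g.counts[1],
                    "nD": g.counts[2],
                    "nU": g.counts[3],
                    "category": g.category,
                }
                for g in groups
            ]
            pd.DataFrame(rows).to_csv(outdir / "homoeolog_groups.tsv", sep="\t", index=False)
            report.counts["homoeolog_groups"] = len(groups)
        except Exception as exc:
            raise StageError("triads", exc) from exc

    pairs: list[tuple[str, str]] = []
    if groups:
        feats = {e.gene_id: e.feature for e in catalog.entries}
        for g in groups:
            for a, b in zip(*np.triu_indices(len(g.members), k=1)):
                ga, gb = g.members[a], g.members[b]
                if feats[ga].subgenome != feats[gb].subgenome:
                    pairs.append((ga, gb))

    if config.run_synteny and catalog is not None:
        try:
            anchors = cg.build_anchors(pairs, features, features)
            blocks = cg.chain_collinear_blocks(
                anchors, min_anchors=config.min_anchors, max_gap=config.max_gap
            )
            block_rows = [
                {
                    "block_id": i,
                    "chrom_a": b.anchors[0].chrom_a,
                    "chrom_b": b.anchors[0].chrom_b,
                    "n_anchors": b.score,
                    "orientation": b.orientation,
                }
                for i, b in enumerate(blocks, 1)
            ]
            pd.DataFrame(
                block_rows,
                columns=["block_id", "chrom_a", "chrom_b", "n_anchors", "orientation"],
            ).to_csv(outdir / "synteny_blocks.tsv", sep="\t", index=False)
            pair_rows = [
                {
                    "gene_a": a.gene_a,
                    "gene_b": a.gene_b,
                    "type": cg.classify_duplication(
                        a, blocks, tandem_window=config.tandem_window
                    ),
                }
                for a in anchors
            ]
            pd.DataFrame(
                pair_rows, columns=["gene_a", "gene_b", "type"]
            ).to_csv(outdir / "duplicate_pairs.tsv", sep="\t", index=False)
            report.counts["synteny_blocks"] = len(blocks)
            report.counts["duplicate_pairs"] = len(pair_rows)
        except Exception as exc:
            raise StageError("synteny", exc) from exc

    if config.run_kaks and pairs and config.cds:
        try:
            cds = {r.id: r.sequence for r in io.read_fasta(config.cds)}
            # representative CDS per gene: first transcript id
            by_gene: dict[str, str] = {}
            for tid in sorted(cds):
                gene = tid.rsplit(".", 1)[0]
                by_gene.setdefault(gene, cds[tid])
            rows = []
            for a, b in pairs:
                if a not in by_gene or b not in by_gene:
                    continue
                ca, cb = by_gene[a], by_gene[b]
                if len(ca) != len(cb):
                    report.warnings.append(f"unalignable CDS pair {a}/{b}")
                    continue
                res = me.ka_ks(
                    me.codon_alignment_from_cds(ca, cb),
                    lambda_rate=config.lambda_rate,
                )
                rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "S": res.S,
                        "N": res.N,
                        "Sd": res.Sd,
                        "Nd": res.Nd,
                        "Ka": res.Ka,
                        "Ks": res.Ks,
                        "omega": res.omega,
                        "selection": (
                            me.classify_selection(res.omega)
                            if res.omega is not None
                            else ""
                        ),
                        "T_mya": res.T_mya,
                        "flags": ";".join(res.flags),
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
            report.counts["kaks_pairs"] = len(rows)
        except Exception as exc:
            raise StageError("kaks", exc) from exc

    if config.run_expression and config.tpm:
        try:
            tpm = pd.read_csv(config.tpm, sep="\t", index_col=0)
            bins = ea.census_bins(tpm)
            bins.to_csv(outdir / "expression_bins.tsv", sep="\t")
            order = ea.cluster_order(tpm, pseudocount=config.pseudocount)
            ea.log2_tpm(tpm, config.pseudocount).loc[order].to_csv(
                outdir / "heatmap_matrix.tsv", sep="\t"
            )
            report.counts["expression_genes"] = len(tpm)
            if config.control_samples and config.treated_samples:
                degs = ea.call_degs(
                    tpm,
                    list(config.control_samples),
                    list(config.treated_samples),
                    fc_threshold=config.fc_threshold,
                    fdr_threshold=config.fdr_threshold,
                    pseudocount=config.pseudocount,
                )
                degs.to_csv(outdir / "degs.tsv", sep="\t")
                report.counts["degs"] = int(degs["is_deg"].sum())
        except Exception as exc:
            raise StageError("expression", exc) from exc

    if config.run_qpcr and config.ct_table:
        try:
            ct = pd.read_csv(config.ct_table, sep="\t")
            qpcr = ea.analyze_qpcr(
                ct,
                reference_gene=config.reference_gene,
                control_treatment=config.control_treatment,
            )
            qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
            report.counts["qpcr_rows"] = len(qpcr)
        except Exception as exc:
            raise StageError("qpcr", exc) from exc

    report.write(outdir / "run_report.json")
    return report


def _properties(seqs: dict[str, str]):
    from .protein_properties import summarize_properties

    return summarize_properties(seqs)


# ---------------------------------------------------------------------------
# demo workspace


def simulate_protein_alignment(
    seed: int, n_taxa: int = 8, length: int = 150, clade_divergence: float = 0.4,
    within_divergence: float = 0.05,
) -> list[tuple[str, str]]:
    """Gap-free protein alignment of two clades, for tree-stage demos.

    Two clade ancestors separated by ``clade_divergence`` (expected
    substitutions/site) each spawn ``n_taxa // 2`` leaves at
    ``within_divergence``. Substitution-only, so rows are aligned by
    construction.
    """
    rng = np.random.default_rng([seed, 5])
    aa = list("ACDEFGHIKLMNPQRSTVWY")

    def mutate(seq: str, rate: float) -> str:
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < rate:
                chars[i] = rng.choice(aa)
        return "".join(chars)

    root = "".join(rng.choice(aa, size=length))
    anc1 = mutate(root, clade_divergence / 2)
    anc2 = mutate(root, clade_divergence / 2)
    aln = []
    for i in range(n_taxa // 2):
        aln.append((f"cladeA_{i + 1}", mutate(anc1, within_divergence)))
    for i in range(n_taxa - n_taxa // 2):
        aln.append((f"cladeB_{i + 1}", mutate(anc2, within_divergence)))
    return aln


def make_demo(outdir, seed: int = 42, n_groups: int = 10) -> tuple[PipelineConfig, RunReport]:
    """Generate a complete synthetic workspace and run the pipeline on it."""
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    genome = syn.generate_family_genome(
        syn.FamilySimulationConfig(seed=seed, n_groups=n_groups)
    )
    paths = genome.write(inputs)

    tpm, _truth = syn.generate_expression_matrix(
        seed, n_genes=100, conditions=("control", "stress"), replicates=3,
        de_fraction=0.1, lfc_magnitude=3.0,
    )
    tpm.to_csv(inputs / "tpm.tsv", sep="\t")

    ct, _ = syn.generate_qpcr_table(
        seed,
        genes=("FAM001A1", "FAM002A1"),
        treatments=("control", "cold", "heat"),
        planted_fold_changes={("FAM001A1", "cold", 6): 4.0},
        ct_noise_sd=0.1,
    )
    ct.to_csv(inputs / "ct.tsv", sep="\t", index=False)

    aln = simulate_protein_alignment(seed)
    io.write_fasta(
        [io.SequenceRecord(n, "", s) for n, s in aln], inputs / "alignment.fa"
    )

    config = PipelineConfig(
        proteome=str(paths["proteins"]),
        cds=str(paths["cds"]),
        gff3=str(paths["gff3"]),
        queries=str(paths["queries"]),
        alignment=str(inputs / "alignment.fa"),
        tpm=str(inputs / "tpm.tsv"),
        ct_table=str(inputs / "ct.tsv"),
        outdir=str(outdir / "results"),
        bootstrap_replicates=100,
        n_clades=2,
        min_anchors=3,
        control_samples=("control_rep1", "control_rep2", "control_rep3"),
        treated_samples=("stress_rep1", "stress_rep2", "stress_rep3"),
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    report = run_pipeline(config)
    return config, report
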