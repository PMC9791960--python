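"""Expression binning, differential-expression calling, DEG-set
intersections, heatmap ordering, and relative qPCR quantification.

TPM matrices are analysed on the log2(TPM + 1) scale. Per-sample expression
bins follow fixed boundaries (high: TPM > 10; medium: 1 < TPM <= 10; low:
0 < TPM <= 1; none: TPM == 0). Differentially expressed genes (DEGs) are
called per contrast with a Welch t-test on log2(TPM + 1), Benjamini–Hochberg
FDR across genes, and the decision rule |log2 fold change| > 1 and
FDR < 0.05. qPCR data are quantified with the 2^(-ddCt) method against a
reference gene and a control condition, with one-way ANOVA significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BINS",
    "log2_tpm",
    "bin_expression",
    "census_bins",
    "benjamini_hochberg",
    "call_degs",
    "intersect_deg_sets",
    "cluster_order",
    "ddct_fold_change",
    "one_way_anova",
    "significance_stars",
    "analyze_qpcr",
]

BINS = ("high", "medium", "low", "none")


def log2_tpm(tpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return np.log2(tpm + pseudocount)


def bin_expression(tpm_value: float) -> str:
    """Expression bin with exact boundary semantics (10 -> medium, 1 -> low)."""
    if tpm_value < 0:
        raise ValueError("TPM must be nonnegative")
    if tpm_value == 0:
        return "none"
    if tpm_value <= 1:
        return "low"
    if tpm_value <= 10:
        return "medium"
    return "high"


def census_bins(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-sample counts of each expression bin (rows: bins, columns: samples)."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = {}
    for sample in tpm.columns:
        binned = tpm[sample].map(bin_expression)
        out[sample] = [int((binned == b).sum()) for b in BINS]
    return pd.DataFrame(out, index=list(BINS))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    tpm: pd.DataFrame,
    control_samples: list[str],
    treated_samples: list[str],
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DEG table for one control-vs-treated contrast.

    ``fc_threshold`` is on the log2 scale: a gene is a DEG when
    |log2fc| > fc_threshold and FDR < fdr_threshold. Requires at least two
    replicates on each side (Welch t-test).
    """
    if len(control_samples) < 2 or len(treated_samples) < 2:
        raise ValueError("each side of the contrast needs >= 2 replicates")
    log = log2_tpm(tpm[list(control_samples) + list(treated_samples)], pseudocount)
    ctrl = log[list(control_samples)].to_numpy()
    trt = log[list(treated_samples)].to_numpy()
    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    t, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    fdr = benjamini_hochberg(p)
    is_deg = (np.abs(log2fc) > fc_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {
            "gene": tpm.index,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "is_deg": is_deg,
        }
    ).set_index("gene")


def intersect_deg_sets(named_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for all 2^k - 1 regions of a Venn diagram.

    Keys are sorted tuples of the set names a region belongs to; counts over
    all regions sum to the size of the union.
    """
    names = sorted(named_sets)
    if len(names) > 6:
        raise ValueError("at most 6 sets are supported")
    regions: dict[tuple[str, ...], int] = {}
    universe = set().union(*named_sets.values()) if named_sets else set()
    membership: dict[tuple[str, ...], int] = {}
    for item in universe:
        key = tuple(n for n in names if item in named_sets[n])
        membership[key] = membership.get(key, 0) + 1
    # emit every region, populated or not
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[combo] = membership.get(combo, 0)
    return regions


def cluster_order(tpm: pd.DataFrame, pseudocount: float = 1.0) -> list[str]:
    """Gene ordering for heatmaps: average-linkage on 1 - Pearson correlation.

    Constant rows (zero variance on the log scale) get correlation 0 with
    everything. Leaf order is made deterministic by seeding the input in
    gene-id order.
    """
    if len(tpm) < 2:
        raise ValueError("need at least 2 genes to cluster")
    tpm = tpm.sort_index()
    log = log2_tpm(tpm, pseudocount).to_numpy()
    centered = log - log.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(link)
    return [tpm.index[i] for i in leaves]


# ---------------------------------------------------------------------------
# qPCR


def ddct_fold_change(
    ct: pd.DataFrame,
    gene: str,
    treatment: str,
    timepoint,
    reference_gene: str,
    control_treatment: str,
) -> tuple[float, float]:
    """(ddCt, fold change) for one gene/treatment/timepoint cell.

    dCt = Ct_gene - Ct_reference per replicate; ddCt is the mean treated dCt
    minus the mean control dCt at the same timepoint; fold = 2^(-ddCt).
    Expects columns gene, treatment, timepoint, replicate, ct.
    """

    def dct(trt) -> np.ndarray:
        sel = (ct["treatment"] == trt) & (ct["timepoint"] == timepoint)
        tgt = ct[sel & (ct["gene"] == gene)].sort_values("replicate")
        ref = ct[sel & (ct["gene"] == reference_gene)].sort_values("replicate")
        if ref.empty:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for "
                f"treatment={trt!r}, timepoint={timepoint!r}"
            )
        if tgt.empty:
            raise ValueError(
                f"gene {gene!r} missing for treatment={trt!r}, timepoint={timepoint!r}"
            )
        if len(tgt) != len(ref):
            raise ValueError("target and reference replicate counts differ")
        return tgt["ct"].to_numpy() - ref["ct"].to_numpy()

    ddct = float(dct(treatment).mean() - dct(control_treatment).mean())
    return ddct, 2.0 ** (-ddct)


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate inputs (zero within-group variance everywhere with equal
    means) are flagged with (nan, nan).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(a.var() == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def analyze_qpcr(
    ct: pd.DataFrame,
    reference_gene: str,
    control_treatment: str,
) -> pd.DataFrame:
    """Full ddCt analysis over every (gene, treatment, timepoint) cell.

    ANOVA compares replicate dCt values across treatments within a timepoint
    (control included). Returns a tidy table with ddct, fold, anova_p, stars.
    """
    rows = []
    genes = sorted(set(ct["gene"]) - {reference_gene})
    treatments = sorted(set(ct["treatment"]) - {control_treatment})
    for gene in genes:
        for timepoint in sorted(set(ct["timepoint"])):
            # replicate dCt per treatment for the ANOVA
            dct_groups = []
            for trt in [control_treatment] + treatments:
                sel = (ct["treatment"] == trt) & (ct["timepoint"] == timepoint)
                tgt = ct[sel & (ct["gene"] == gene)].sort_values("replicate")
                ref = ct[sel & (ct["gene"] == reference_gene)].sort_values("replicate")
                if tgt.empty or ref.empty:
                    continue
                dct_groups.append(list(tgt["ct"].to_numpy() - ref["ct"].to_numpy()))
            anova_p = float("nan")
            if len(dct_groups) >= 2 and all(len(g) >= 2 for g in dct_groups):
                _, anova_p = one_way_anova(dct_groups)
            for trt in treatments:
                try:
                    ddct, fold = ddct_fold_change(
                        ct, gene, trt, timepoint, reference_gene, control_treatment
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "gene": gene,
                        "treatment": trt,
                        "timepoint": timepoint,
                        "ddct": ddct,
                        "fold_change": fold,
                        "anova_p": anova_p,
                        "stars": significance_stars(anova_p),
                    }
                )
    return pd.DataFrame(rows)
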