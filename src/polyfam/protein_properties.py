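"""ExPASy-style physicochemical statistics for protein sequences.

Five statistics are computed per protein: average molecular weight, theoretical
isoelectric point (Bjellqvist pKa set, bisection on net charge), instability
index (Guruprasad dipeptide weights), aliphatic index, and the Kyte–Doolittle
grand average of hydropathy (GRAVY). A protein is called "stable" when its
instability index is strictly below 40.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV, kd

__all__ = [
    "ProteinStats",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "gravy",
    "aliphatic_index",
    "instability_index",
    "protein_stats",
    "summarize_properties",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ExPASy average residue masses (Da); a peptide adds one water.
WATER_MASS = 18.0153
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist pKa values (the ExPASy defaults).
PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


@dataclass(frozen=True)
class ProteinStats:
    length: int
    mw: float
    pi: float
    instability_index: float
    aliphatic_index: float
    gravy: float

    @property
    def is_stable(self) -> bool:
        return self.instability_index < 40.0


def _validate(seq: str, min_len: int = 1) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise ValueError(f"sequence must have at least {min_len} residues")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)} in sequence")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    seq = _validate(seq)
    return sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def net_charge(seq: str, ph: float) -> float:
    """Net charge of the peptide at the given pH (Henderson–Hasselbalch)."""
    seq = _validate(seq)
    pos = [PKA_POSITIVE["Nterm"]] + [
        PKA_POSITIVE[aa] for aa in seq if aa in ("K", "R", "H")
    ]
    neg = [PKA_NEGATIVE["Cterm"]] + [
        PKA_NEGATIVE[aa] for aa in seq if aa in ("D", "E", "C", "Y")
    ]
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - pka)) for pka in pos)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pka - ph)) for pka in neg)
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    seq = _validate(seq)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value over residues."""
    seq = _validate(seq)
    return sum(kd[aa] for aa in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """AI = X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent."""
    seq = _validate(seq)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(seq: str) -> float:
    """II = (10/L) * sum of Guruprasad DIWV weights over the L-1 dipeptides."""
    seq = _validate(seq, min_len=2)
    total = sum(DIWV[seq[i]][seq[i + 1]] for i in range(len(seq) - 1))
    return 10.0 * total / len(seq)


def protein_stats(seq: str) -> ProteinStats:
    seq = _validate(seq, min_len=2)
    return ProteinStats(
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        instability_index=instability_index(seq),
        aliphatic_index=aliphatic_index(seq),
        gravy=gravy(seq),
    )


def summarize_properties(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein statistics plus an extremes report.

    Returns ``(stats, extremes)``: ``stats`` has one row per protein (columns
    name, length, mw, pi, instability_index, aliphatic_index, gravy,
    is_stable); ``extremes`` holds the argmin/argmax row for each statistic.
    """
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    rows = []
    for name, seq in items:
        st = protein_stats(seq)
        rows.append(
            {
                "name": name,
                "length": st.length,
                "mw": st.mw,
                "pi": st.pi,
                "instability_index": st.instability_index,
                "aliphatic_index": st.aliphatic_index,
                "gravy": st.gravy,
                "is_stable": st.is_stable,
            }
        )
    stats = pd.DataFrame(rows)
    if stats.empty:
        raise ValueError("no sequences given")
    ext_rows = []
    for col in ("length", "mw", "pi", "instability_index", "aliphatic_index", "gravy"):
        for kind, idx in (("min", stats[col].idxmin()), ("max", stats[col].idxmax())):
            ext_rows.append(
                {
                    "statistic": col,
                    "extreme": kind,
                    "name": stats.loc[idx, "name"],
                    "value": stats.loc[idx, col],
                }
            )
    return stats, pd.DataFrame(ext_rows)
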