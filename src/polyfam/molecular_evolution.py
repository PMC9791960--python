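"""Nei–Gojobori (1986) Ka/Ks estimation and molecular-clock dating.

The NG86 estimator counts, for each codon, the fraction of possible
single-nucleotide changes that are synonymous (fractional "synonymous sites"),
averages observed differences over all minimal mutational pathways between the
two codons of a pair, applies the Jukes–Cantor multiple-hit correction to the
resulting proportions, and reports omega = Ka/Ks. Divergence times follow the
molecular clock T = Ks / (2 * lambda), with lambda in substitutions per
synonymous site per year, reported in millions of years (Mya).

Conventions (exposed as arguments where they matter):

* the standard nuclear genetic code;
* single-nucleotide changes that create a stop codon are excluded from the
  site-count denominator, and mutational pathways passing through a stop
  codon are dropped with the remaining pathways re-weighted equally;
* site counts are averaged over the two sequences of a pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "SaturationError",
    "ng86_site_counts",
    "ng86_pathway_differences",
    "ka_ks",
    "divergence_time",
    "classify_selection",
    "codon_alignment_from_cds",
]

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
BASES = "ACGT"


class SaturationError(ValueError):
    """Synonymous or nonsynonymous divergence beyond the Jukes–Cantor range."""


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free pair of equal-length coding sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if len(a) % 3:
            raise ValueError("aligned length must be a multiple of 3")
        for seq, name in ((a, "seq_a"), (b, "seq_b")):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"{name} contains internal stop codon at {i}")
                if codon not in CODON_TO_AA:
                    raise ValueError(f"{name} contains invalid codon {codon!r} at {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class KaKsResult:
    """NG86 counts, Jukes–Cantor rates, omega and clock dating for one pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    omega: float | None
    T_mya: float | None
    flags: tuple[str, ...] = ()


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one sense codon.

    At each of the three positions, the synonymous fraction is taken over the
    single-nucleotide changes that do not create a stop codon; s + n == 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def ng86_pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    All orderings of the differing positions are enumerated; each stop-free
    pathway gets equal weight. Raises if every pathway crosses a stop codon.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in CODON_TO_AA:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_valid = 0
    for order in itertools.permutations(diff):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            sd_total += sd
            nd_total += nd
            n_valid += 1
    if n_valid == 0:
        raise SaturationError(
            f"all mutational pathways between {codon_a} and {codon_b} cross a stop"
        )
    return sd_total / n_valid, nd_total / n_valid


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: Jukes-Cantor undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ka_ks(
    alignment: CodonAlignment,
    lambda_rate: float | None = 6.5e-9,
) -> KaKsResult:
    """NG86 Ka/Ks for one codon-aligned pair, with optional clock dating.

    Saturated pairs (pS or pN >= 3/4, mirroring deep-divergence comparisons
    that cannot be dated) are returned with the corresponding rate set to
    ``None`` and a ``"saturated"`` flag rather than raising.
    """
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    flags: list[str] = []
    for ca, cb in alignment.codons():
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        try:
            d_s, d_n = ng86_pathway_differences(ca, cb)
        except SaturationError:
            flags.append("blocked_pathway")
            continue
        sd += d_s
        nd += d_n
    S, N = (s_a + s_b) / 2.0, (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0

    Ks = Ka = omega = t_mya = None
    if sd == 0.0 and nd == 0.0:
        Ks = Ka = 0.0
        flags.append("identical")
    else:
        try:
            Ks = _jukes_cantor(pS)
        except SaturationError:
            flags.append("saturated")
        try:
            Ka = _jukes_cantor(pN)
        except SaturationError:
            flags.append("saturated")
    if Ka is not None and Ks is not None:
        if Ks > 0:
            omega = Ka / Ks
        else:
            flags.append("ks_zero")
    if Ks is not None and lambda_rate is not None:
        t_mya = divergence_time(Ks, lambda_rate)
    return KaKsResult(S, N, sd, nd, pS, pN, Ks, Ka, omega, t_mya, tuple(flags))


def divergence_time(ks: float, lambda_rate: float = 6.5e-9) -> float:
    """Molecular-clock age in Mya: T = Ks / (2 * lambda) / 1e6.

    ``lambda_rate`` is the synonymous substitution rate per site per year
    (default 6.5e-9, the grass clock rate).
    """
    if ks < 0:
        raise ValueError("Ks must be nonnegative")
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    return ks / (2.0 * lambda_rate) / 1e6


def classify_selection(omega: float, eps: float = 1e-6) -> str:
    """'purifying' (<1), 'neutral' (==1 within eps), or 'positive' (>1)."""
    if not math.isfinite(omega) or omega < 0:
        raise ValueError(f"omega must be finite and nonnegative, got {omega}")
    if abs(omega - 1.0) <= eps:
        return "neutral"
    return "purifying" if omega < 1.0 else "positive"


def codon_alignment_from_cds(cds_a: str, cds_b: str) -> CodonAlignment:
    """Pair two same-length CDSs (terminal stop codons trimmed if present)."""

    def trim(seq: str) -> str:
        seq = seq.upper()
        if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
            return seq[:-3]
        return seq

    return CodonAlignment(trim(cds_a), trim(cds_b))
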