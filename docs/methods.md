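# Methods

This note documents the models and procedures `polyfam` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design decisions taken where several conventions exist.

## Family identification

Candidates are screened by exact local alignment rather than a heuristic
seeded search: affine-gap Smith–Waterman (Gotoh) under BLOSUM62 with gap
open 11 and extend 1 (a gap of length L costs 11 + (L − 1)). The inner
recurrences are vectorized along the target axis; the horizontal-gap state
collapses to a running prefix maximum, which is exact whenever
gap-open ≥ gap-extend. Significance uses the Karlin–Altschul expectation
E = K·m·n·exp(−λS) with the standard gapped-BLOSUM62 parameters K = 0.041,
λ = 0.267, where n is the total residue count of the searched proteome. The
decision gate is E < 10⁻⁵, configurable.

Acceptance into the catalog additionally requires at least one
Cys₄-His-Cys₃ motif. The scanner matches the spaced pattern
C-x(1,3)-C-x(8,21)-C-x(2,4)-C-x(4,6)-H-x(1,2)-C-x(10,46)-C-x(2,3)-C with the
total span clamped to 50–80 residues; spacers are configuration-exposed.
Matching is leftmost with the smallest feasible ligand positions
(depth-first over spacer lengths in ascending order with failure
memoization), and hits are non-overlapping. Motif confirmation is evaluated
before the alignment gate — the accepted set is the conjunction, so the
order only affects speed. Sequences over the DNA alphabet produce a warning
and no hits.

When several proteins share a parent gene, the lexicographically first
transcript id is the gene's representative: the "first splice variant"
convention made reproducible without relying on annotation order. Accepted
genes lacking a genome feature are reported on an explicit `unplaced` side
channel rather than dropped. Names are assigned along the genome with sort
key (chromosome number, subgenome letter, start, gene id); genes on
unplaced scaffolds sort last by id. Ties at identical start positions break
by gene id.

A profile-HMM stage is deliberately out of scope; the single motif scan
plus alignment gate reproduces the two-stage search-then-confirm decision
rule with components that are exactly testable against brute-force oracles.

## Protein statistics

Molecular weight sums the ExPASy average residue masses plus one water
(18.0153 Da). The theoretical pI solves net-charge(pH) = 0 by bisection on
[0, 14] to |q| < 10⁻⁴, with Henderson–Hasselbalch charges over the termini
and D, E, C, Y, H, K, R side chains using the Bjellqvist pKa set (N-term
7.5 generic, C-term 3.55, D 4.05, E 4.45, H 5.98, C 9.0, Y 10.0, K 10.0,
R 12.0). Note that some implementations add residue-specific terminal pKa
adjustments; with the generic termini used here, values can differ from
such tools by up to ~0.2 pH units. The instability index uses the
Guruprasad DIWV dipeptide weights (imported from Biopython's data tables),
II = (10/L)·Σ DIWV over the L − 1 dipeptides, with stability defined as
II < 40 (II = 40 is unstable). The aliphatic index is
X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent, and GRAVY is the
mean Kyte–Doolittle hydropathy. Unknown residues (B, Z, X) raise an error;
there is no silent imputation.

## Phylogeny

Distances come from a pre-made protein multiple alignment (alignment itself
is out of scope): p-distance with pairwise deletion (a site counts for a
pair only if neither row has a gap; an all-gap overlap is an error), then
the Poisson correction d = −ln(1 − p), undefined at p ≥ 1. Pairwise deletion
maximizes usable sites and is the documented choice where tools differ.

Neighbor joining is the Saitou–Nei algorithm: join the pair minimizing
Q(i,j) = (r − 2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), attach with the
rate-corrected split lengths, reduce the matrix, and solve the final three
taxa in closed form. Ties in Q break by taxon order; negative branch
lengths clamp to zero. On additive (tree-metric) inputs the algorithm
returns the generating topology with exact branch lengths; the test suite
verifies this against exhaustive topology enumeration with least-squares
branch fitting for up to six taxa, and against scikit-bio's implementation.

Bootstrap supports resample alignment columns with replacement, rebuild the
tree per replicate, and report the percentage of replicates containing each
internal bipartition of the full-data tree. Each replicate's random stream
is keyed by (seed, replicate index), and the alignment is sorted by taxon
name first, so supports are invariant to input order. The published setting
of 1000 replicates is the pipeline default; tests and the demo use 50–100.

Clade assignment is an operationalization of the visual k-clade partition of
a published tree: cut the k − 1 longest internal edges (ties by the
lexicographic order of the edge's bipartition). When fewer than k − 1
internal edges exist (k close to the number of taxa), remaining cuts split
single leaves off, longest leaf edges first, so k = n yields singletons.
Clades are labeled 1..k by decreasing size.

## Collinearity, duplications, and the triad census

Anchors are homologous gene pairs annotated with ranks in the *complete*
gene order of each chromosome (family and background genes alike), so rank
gaps measure skipped genes. Chains must be strictly monotone in both ranks
(decreasing on one side for inverted blocks) with per-step gaps ≤ max_gap;
the longest chain per chromosome pair is found by quadratic dynamic
programming, extracted, its anchors removed, and the process repeated while
chains reach min_anchors. Defaults min_anchors = 5 and max_gap = 25 follow
the conventional collinearity-detection settings; both are exposed. A
brute-force subset-enumeration oracle validates the chainer on instances of
up to 12 anchors.

Duplicate pairs are typed: **tandem** if on one chromosome within
tandem_window = 5 ranks (tandem takes precedence), **segmental** if inside
a detected block, else **dispersed**.

Homoeologs group by single-linkage over reciprocal-best cross-subgenome
hits, restricted to identical chromosome numbers — the dominant pattern in
allopolyploid wheat, where group 3 homoeologs sit on 3A/3B/3D. Each group's
composition (nA, nB, nD, plus nU unplaced copies) is classified:

* (1,1,1) with no unplaced copies → **1:1:1** (a complete triad);
* exactly one subgenome with n > 1, others 1, no unplaced → **n:1:1-type**;
* exactly one subgenome at 0, others 1, no unplaced → **loss-of-one**;
* a single gene → **orphan**;
* otherwise, ≥ 2 subgenomes represented → **other ratios** (e.g. 0:1:n, or
  any group containing unplaced copies alongside two subgenomes);
* otherwise (e.g. several copies confined to one subgenome) →
  **uncategorized**.

The ordering matters: groups with unplaced members never count as triads,
duplications, or losses. This rule set reproduces the published census of
the packaged 86-group table exactly (69 triad groups / 207 genes / 84.8%;
1 group / 4 genes / 1.6% duplications; 8 groups / 16 genes / 6.6% losses;
3 groups / 11 genes other; 4 orphans; 2 genes uncategorized). Percentages
are per gene over the full catalog, one decimal.

The packaged table's "Genomes" strings are parsed by stripping parentheses
(which mark duplicated placements, e.g. "A(DD)UU") and counting subgenome
letters, with "U" counting as unplaced.

## Ka/Ks and dating

The Nei–Gojobori (1986) estimator, standard nuclear code:

* **Sites.** For each codon and position, the synonymous fraction of the
  three possible single-nucleotide changes, excluding changes that create a
  stop codon from the denominator; s + n = 3 per codon exactly, and counts
  are averaged over the two sequences of a pair.
* **Differences.** For each differing codon pair, the synonymous and
  nonsynonymous step counts are averaged over all orderings of the
  differing positions (1, 2, or 6 pathways), with pathways that pass
  through a stop codon excluded and the remainder re-weighted equally; a
  codon pair whose pathways are all blocked is flagged and skipped.
* **Correction.** pS = Sd/S and pN = Nd/N get the Jukes–Cantor correction
  d = −¾·ln(1 − 4p/3). Proportions ≥ ¾ are reported as saturated (flag, no
  value) rather than raised — mirroring deep comparisons whose synonymous
  sites are exhausted. ω = Ka/Ks, with Ks = 0 flagged instead of divided.
* **Selection.** ω < 1 purifying, ω > 1 positive, |ω − 1| ≤ 10⁻⁶ neutral
  (a float-equality guard only).
* **Dating.** T = Ks / (2λ) / 10⁶ Mya with λ = 6.5 × 10⁻⁹ synonymous
  substitutions per site per year, the grass molecular-clock rate. The
  formula is linear, so hand-checkable: Ks = 0.013 → 1.0 Mya,
  Ks = 0.1661 → 12.78 Mya.

A test verifies pathway averaging against an independent exhaustive
enumeration for all 61 × 61 sense-codon pairs to 10⁻¹².

## Expression and qPCR

All transforms use log₂(TPM + 1) (pseudocount 1). Expression bins follow
exact boundary semantics: high TPM > 10, medium 1 < TPM ≤ 10, low
0 < TPM ≤ 1, none TPM = 0.

DEG calling is per contrast: log₂ fold change as the difference of mean
log₂(TPM + 1); two-sided Welch t-test per gene (≥ 2 replicates per side
required); Benjamini–Hochberg adjustment across genes within the contrast;
a gene is a DEG when |log₂FC| > 1 and FDR < 0.05. The fold-change threshold
is read on the log₂ scale (i.e. > 2-fold in either direction): a literal
"fold > 1" would flag every slightly up-regulated gene regardless of
magnitude, contradicting the sparse tails such volcano criteria produce.
The t-test/BH combination is a transparent stand-in reproducing the
decision rule, not a count-model DE engine; on null synthetic data the
average false-discovery proportion stays at or below 0.05.

Venn regions are exclusive membership counts over up to six named DEG sets;
region counts sum to the union size. Heatmap ordering is average-linkage
hierarchical clustering on 1 − Pearson correlation of log-scale rows, with
constant rows assigned zero correlation and genes pre-sorted by id so the
leaf order is deterministic.

qPCR: ΔCt = Ct_target − Ct_reference per replicate, ΔΔCt = mean treated ΔCt
minus mean control ΔCt at the same timepoint (per-timepoint control rather
than a time-zero baseline; switchable by passing a different control),
fold = 2^(−ΔΔCt). One-way ANOVA compares replicate ΔCt across treatments
within a timepoint; stars follow p < 0.05 (*) and p < 0.01 (**). Zero
within-group variance with equal means yields an undefined F, flagged as
NaN.

## Synthetic data

The generators define the study conditions for every property test:

* **Genome.** Homoeologous groups drawn from a ratio mixture defaulting to
  the retention profile of the worked family (81% triads, 10% loss-of-one,
  4% other, 4% orphans, 1% duplications); three subgenomes A/B/D, two
  chromosomes each, 10 background genes per chromosome, proteins of 150–300
  residues. Group members are copies of a common ancestor mutated at 3% of
  non-ligand positions, placed on the same chromosome number of their
  subgenomes with non-overlapping, strictly increasing coordinates. Family
  filler residues exclude C and H so the planted motif is the unique match;
  background proteins use the full alphabet and are rejection-sampled to be
  motif-free. Group-ancestor proteins are emitted as the query set. CDSs
  descend from a per-group ancestor CDS: nonsynonymous changes pick a
  random codon of the new residue and 5% of conserved positions swap
  synonymously, giving homoeolog pairs modest, dateable Ks. Because
  homology is planted noise-free, identification tests expect sensitivity
  and specificity of exactly 1 — real proteomes, with degenerate motifs and
  partial domains, would not behave this way, and the tests say nothing
  about that regime.
* **Codon pairs.** A continuous-time single-nucleotide process on sense
  codons: each change fires at rate 1/3 (synonymous) or ω/3
  (nonsynonymous); changes to stops are forbidden; no
  transition/transversion bias or codon-usage preference (the NG86 counting
  model makes the same simplifications, so recovery is a clean consistency
  check, not a robustness study). The two sequences evolve independently
  from a uniform-random sense-codon ancestor for branch_length/2 each.
* **Expression.** Lognormal baseline (meanlog 3, sdlog 1.5 on the natural
  scale), chosen to span all four bin thresholds; lognormal replicate noise
  (sdlog 0.25 default); planted ± log₂-shifts in treated conditions;
  optional exact zeros per sample. Down-shifted genes at a low baseline are
  compressed by the +1 pseudocount — the power guarantees in the tests
  apply to the planted up-shifts.
* **qPCR.** Reference gene at Ct 20, targets at uniform 24–28 baseline; a
  planted fold f lowers the treated Ct by log₂ f; Gaussian technical noise;
  triplicates. With zero noise the ΔΔCt analysis inverts the planted fold
  exactly.

All generators are bit-deterministic for a fixed seed; sub-streams are
keyed by (seed, fixed offset) so adding a generator never perturbs the
output of another.

## Problem sizes

Default verification sizes, chosen to keep the whole suite fast while
leaving estimator noise well inside the asserted bands: the synthetic test
genome uses 10 groups (~30 family genes, 60 background); ω recovery uses
200 pairs × 500 codons at neutrality and 30 × 300 per planted ω for
monotonicity; the null-FDP check averages 100 simulations of 200 genes;
NJ exactness enumerates all topologies up to 6 taxa; bootstrap demos use
50–100 replicates (the pipeline default remains 1000).

## Known limitations

* The E-value uses fixed Karlin–Altschul parameters rather than
  composition-corrected ones; it reproduces the decision rule, not BLAST
  statistics in detail.
* The motif scanner is a hard pattern gate, not a profile score: remote
  family members with degenerate ligand spacing are missed by design.
* NG86 ignores transition/transversion bias and codon usage; ω is
  conservative under strong bias.
* The DEG caller assumes approximately log-normal TPM noise;
  count-level overdispersion modeling is out of scope.
* Cross-species collinearity uses the same chainer as within-genome
  analysis; no synteny-quality weighting is applied.
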