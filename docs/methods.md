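# Methods

This note documents the models and procedures `erfminer` implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Family classification

A candidate set is formed as the union of a homology screen and a
profile-domain screen, restricted to proteins whose AP2 domain was
independently confirmed (`merge_candidates`).  Domain hits are consumed from
a TSV with domtblout-compatible columns (protein_id, domain, start, end,
score); `erfminer` does not re-implement profile-HMM search.  A minimal
sliding-window consensus scanner (`scan_domains`, identity ≥ 0.7 against a
fixed consensus block) exists only so synthetic tests can run without an
external domain scanner.

Subfamily rules are purely architectural where the architecture is
informative: AP2 + B3 → RAV, two or more AP2 domains → AP2, no AP2 domain →
not a family member.  A single AP2 domain is ambiguous (ERF, a minority of
AP2-subfamily members, or the soloist) and is resolved by the **nearest
labelled reference**: the panel entry with the maximal global alignment
score.  This replaces a bootstrapped maximum-likelihood tree with a
deterministic, desk-scale assignment; the panel labels are assumed to encode
the tree's clades.  Known limitation: a nearest-reference rule cannot
express clade support, and the soloist call rests entirely on the panel
containing a soloist exemplar.  A RAV-labelled nearest reference without B3
evidence is demoted to ERF and re-assigned among ERF references only.

Alignment scoring defaults: BLOSUM62, gap open −10, gap extension −1 (first
gap residue costs the open score), all overridable per call.  Ties between
equally scoring references break to the lexicographically smallest reference
id, which makes the call invariant to panel order.

Motif patterns (regular expressions over the protein alphabet):

| motif   | pattern          | role        |
|---------|------------------|-------------|
| EAR     | `[LF]DLN[LF].P`  | repression  |
| R/K-LFGV| `[RK]LFGV`       | repression  |
| EDLL    | `EDLL`           | activation  |

The whole sequence is scanned (the literature places these motifs in the
C-terminal region but does not define a hard boundary) and each hit is
annotated with the third of the protein it starts in.  The broader LxLxL
EAR variant is available (`EAR_LXLXL_PATTERN`) but off by default.  X
residues never match the residue classes; the single wildcard position
matches any residue.

Protein properties: length in residues; molecular weight as the sum of
average residue masses plus one water (18.0153 Da), with X contributing
length but zero mass; isoelectric point by bisection on the
Henderson–Hasselbalch net-charge equation with the EMBOSS pKa set
(N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1), to 0.01 pH units.  Different pKa sets shift pI by a few tenths of
a unit; only orderings and ranges should be compared across tools.

## Gene structure

GFF3 is parsed with gffutils; coordinates stay 1-based inclusive
throughout.  Intron counts use exon rows (not CDS rows) of one selected
transcript — the longest by summed exon length, ties to the smallest
transcript id — because gene-structure figures draw UTR-containing exons.
Genes with direct exon children and no mRNA row are accepted as a single
implicit transcript.  Intron classes partition the counts: 0 intron-less,
1–3 intron-poor, ≥ 4 intron-rich.

## Duplication and molecular evolution

Paralog pairs can be proposed by global-alignment identity ≥ 0.70 with
mutual coverage ≥ 0.75 (identity = matches over aligned columns, coverage =
aligned columns over each sequence length), or supplied directly.
Duplication typing consumes collinear blocks as input: membership of a
within-species block ⇒ segmental; otherwise same chromosome with ≤ 5
intervening gene models (configurable) ⇒ tandem; everything else, including
unplaced genes, ⇒ dispersed.  Cross-species conservation is the plain
intersection of per-species syntenic gene sets.

Ka/Ks is Nei–Gojobori (1986) with Jukes–Cantor correction, chosen because
it is exactly verifiable against brute-force enumeration:

* synonymous site counts per codon are the fractions of the nine possible
  single-nucleotide changes that preserve the amino acid, averaged over the
  two sequences; a change that produces a stop codon counts as
  nonsynonymous;
* codons differing at k positions average step classifications over all k!
  single-step pathway orderings, excluding pathways through stop codons;
  when every pathway is blocked, the codon's k differences are split in
  proportion to its site fractions (a documented fallback that keeps S + N
  exact);
* pS = Sd/S, pN = Nd/N, K = −(3/4)·ln(1 − 4p/3).  A log argument ≤ 0 is
  reported as saturated (NaN), never a negative rate; Ka/Ks is NaN when
  Ks is 0 or saturated.

Pairs must arrive aligned (equal length, in frame, no internal stops); a
shared trailing stop codon is dropped.  Absolute values from other models
(γ-MYN, maximum likelihood) will differ, particularly at high divergence.
Divergence times use T = Ks/(2λ)·10⁻⁶ with λ = 6.1 × 10⁻⁹ per site per
year, reported in Mya to two decimals.

## Expression screening

FPKM_g = c_g·10⁹/(ℓ_g·Σc) and TPM_g = 10⁶·(c_g/ℓ_g)/Σ(c/ℓ); all-zero
columns normalize to zero with a logged warning.  Units per dataset follow
the study designs: the six-stage dataset is FPKM, the ethephon and
pollination datasets TPM.  Every printed threshold is applied exactly as
printed: the ≥ 20 expression filter is inclusive; dominance (> 5, < 0.2)
and ripening-correlation (> 2, < 0.5) ratios are strict; |log₂FC| ≥ 1 is
inclusive.  Expression-level groups use half-open bins [0, 20), [20, 300),
[300, ∞) — the literature's "B: 20–300, C: ≤ 20" overlaps at 20 and its
upper bound for A is just the observed maximum, so a proper partition was
imposed.  Zero-denominator ratios with positive numerators classify to the
positive side (infinite ratio); 0/0 is "none".

Fold changes use a pseudocount of 1 on the mean abundances, which bounds
log₂FC for zero-expression sides and is configurable.  The optional
significance test is Welch's t on log₂(x + pseudocount) with
Benjamini–Hochberg adjustment across genes (< 0.05); the adjustment
procedure behind the stage dataset's published criterion is not named, and
BH is the field default.  The intersection screen itself uses the
fold-change-only rule, matching the criterion stated for the ethephon and
pollination datasets.  The expression filter is applied to the full matrix
of each dataset before DEG calling.

Screen comparisons (riper vs less ripe): stage 6 vs 5 in flesh and peel;
ethephon vs control at days 4 and 6 in flesh and receptacle; 100 % vs 60 %
ripeness in pollinated and parthenocarpic fruit, flesh and receptacle.  The
stage-dataset pair is read as peel 6 vs 5 for tissue consistency (that
dataset has peel and flesh, not receptacle).  A gene is a key candidate iff
it is differentially regulated, in either direction, in at least one
comparison of every dataset's comparison group.

2⁻ΔΔCT is the textbook relative quantification against a reference gene and
calibrator sample.  Co-expression is Spearman rank correlation with average
ranks for ties; constant genes yield NA rows/columns.

## Promoters

Promoters are the 2000 bp (default) upstream of the start codon — the CDS
start, not the transcription start site.  Minus-strand promoters are the
reverse complement of [cds_start + 1, cds_start + 2000]; windows clipped at
contig edges are flagged truncated rather than padded.  Cis-elements are
IUPAC patterns scanned on both strands with overlapping matches all
reported (over-reporting is reversible downstream; the behaviour of web
scanners is not reproducible exactly).  Genome N bases match only the
pattern letter N.  The shipped behaviour makes no attempt to reproduce any
particular web catalog; the element set is the user's.

## Synthetic data

The generators are pure functions of `SimConfig`; one seed determines every
byte of output.

*Family*: one labelled exemplar per subgroup (15 ERF subgroups + AP2 + RAV
+ soloist) built from a random backbone with fixed 65-aa AP2 and 60-aa B3
consensus blocks planted at recorded coordinates; each of the 119 proteins
(95/20/3/1 by default) is a 5 %-mutated copy of its exemplar, so the
nearest-reference assignment has a large margin.  Six of the 20 AP2s carry
a single AP2 domain; EAR/EDLL/R-K-LFGV motifs are planted into designated
sequences (one ERF receives EAR in both the middle and C-terminal regions).
The B3 consensus deliberately contains the R/K-LFGV motif, as it does in
real RAV proteins.

*Annotation*: three 12-gene chromosomes with mixed strands, exon counts
cycling 1–7 plus one planted 12-exon gene, one gene 500 bp from the contig
edge (promoter truncation), an adjacent tandem pair, a cross-chromosome
pair registered in a within-species collinear block, a distant same-
chromosome pair (dispersed), and five per-species ortholog tables with a
planted four-gene intersection.

*Codon pairs*: for target Ks the expected synonymous-difference proportion
is the Jukes–Cantor inverse pS = (3/4)(1 − e^(−4Ks/3)); Poisson(pS·S)
substitution events each apply one random synonymous single-nucleotide
change to a distinct codon (never creating a stop), and likewise for Ka on
disjoint codons.  One event per codon keeps the planted difference counts
exactly recoverable; targets whose expected event count exceeds the
mutable-codon capacity raise an error.  Defaults: 200 pairs of 300 codons
at (Ks, Ka) = (0.1, 0).

*Expression*: negative-binomial counts (dispersion 0.01 — tightly
controlled bulk replicates; 3 replicates per condition) over 119 family
genes plus 2000 background genes so that column totals, and hence the ≥ 20
FPKM/TPM filter, are on a realistic scale.  Planted multiplicative effects
on the mean: 8× tissue dominance (3 flesh-, 9 peel-dominant genes), 4× on
stages 4–6 for ripening correlation (9 positive, 27 negative), 6× ripening
shifts defining 7 key genes (6 ERFs + 1 RAV; 3 up, 4 down) applied at
stage 6, at ethephon days 4 and 6, and at 100 % ripeness, plus
single-dataset 4× DEGs and a stages+ethephon-only group that stress the
intersection.  Ground-truth dominance/correlation/DE labels are derived by
applying the threshold rules to the noise-free expected-abundance matrix —
the analytic truth of the multiplicative model — so recovery tests measure
the effect of sampling noise and normalization, not label bookkeeping.
Expression-level groups (A/B/C) are descriptive bins of noisy maxima and
are reported but not treated as planted truth: the maximum over 36 noisy
samples is upward-biased relative to the noise-free maximum near bin
boundaries.

What the generator does **not** emulate: read-level artefacts (mapping
bias, multi-mapping, length-dependent dispersion), isoform mixtures,
correlated biological replicates, batch effects, or realistic genome
evolution.  Passing recovery tests therefore demonstrates the correctness
of the rules and their thresholds under clean sampling noise, not
robustness to real-data artefacts.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path: 10,000 random codon pairs for oracle agreement, 200 replicate pairs
for estimator consistency, the full 119-protein family, and
36/36/24-sample count matrices with 2119 genes.  Bisection tolerance for pI
is 0.01 pH; TPM column sums are exact to machine precision; BH agreement
with its step-up definition is exact to 1e-12.  Degenerate inputs are
errors, not silent defaults: empty panels, missing tissues/stages, negative
abundances, counts-unit input to FPKM/TPM-only rules, out-of-range
p-values, frame-violating or internally stopped CDS pairs.
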