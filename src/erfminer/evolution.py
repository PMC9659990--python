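"""Paralog detection, duplication typing, NG86 Ka/Ks and duplication dating.

The substitution-rate estimator is Nei & Gojobori's (1986) unweighted pathway
method with Jukes-Cantor multiple-hit correction:

* each codon contributes fractional synonymous site counts — at every codon
  position the fraction of the three possible single-nucleotide changes that
  preserve the encoded amino acid (changes producing a stop codon count as
  nonsynonymous); site counts are averaged over the two sequences;
* codons differing at k positions average synonymous/nonsynonymous step
  counts over all k! orderings of single-step mutational pathways, excluding
  pathways that pass through a stop codon (if every pathway does, the codon's
  k differences are split in proportion to its site fractions);
* proportions pS = Sd/S and pN = Nd/N are corrected as
  K = -(3/4) ln(1 - (4/3) p); a log argument <= 0 is reported as saturated
  (NaN), never as a negative rate.

Duplication dates follow the molecular clock T = Ks / (2 lambda) with
lambda = 6.1e-9 substitutions per synonymous site per year, reported in
millions of years (Mya).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "CodonPair",
    "RateEstimate",
    "DuplicationCall",
    "CollinearBlockTable",
    "DEFAULT_CLOCK_RATE",
    "ng86_kaks",
    "divergence_time",
    "find_paralog_pairs",
    "classify_duplication",
    "conserved_across",
    "gene_order_from_models",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
BASES = "ACGT"

#: Synonymous-substitution clock rate, per site per year.
DEFAULT_CLOCK_RATE = 6.1e-9


@dataclass(frozen=True)
class CodonPair:
    """Two in-frame, gap-free, equal-length coding sequences."""

    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self):
        a, b = self.cds_a.upper(), self.cds_b.upper()
        object.__setattr__(self, "cds_a", a)
        object.__setattr__(self, "cds_b", b)
        if len(a) != len(b):
            raise ValueError(
                f"CDS lengths differ: {self.id_a} ({len(a)}) vs "
                f"{self.id_b} ({len(b)})"
            )
        if len(a) % 3 != 0:
            raise ValueError("CDS length is not a multiple of 3")
        if set(a + b) - set(BASES):
            raise ValueError("CDS contains non-ACGT characters")
        n = len(a) // 3
        for i in range(n):
            ca, cb = a[3 * i:3 * i + 3], b[3 * i:3 * i + 3]
            internal = i < n - 1
            if internal and (ca in STOP_CODONS or cb in STOP_CODONS):
                raise ValueError(f"internal stop codon at codon {i + 1}")

    def codons(self) -> list[tuple[str, str]]:
        """Aligned codon columns, dropping a shared trailing stop codon."""
        a, b = self.cds_a, self.cds_b
        out = [
            (a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)
        ]
        if out and (out[-1][0] in STOP_CODONS or out[-1][1] in STOP_CODONS):
            out = out[:-1]
        return out


@dataclass(frozen=True)
class RateEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float  # NaN when saturated
    ka: float
    ratio: float  # Ka/Ks; NaN when Ks is 0 or saturated
    t_mya: float  # divergence time at the default clock rate


@dataclass(frozen=True)
class DuplicationCall:
    pair: tuple[str, str]
    type: str  # tandem | segmental | dispersed
    evidence: str


@lru_cache(maxsize=None)
def _site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_differences(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences per codon pair."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    k = len(diffs)
    if k == 0:
        return 0.0, 0.0
    totals: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = ca
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            totals.append((sd, nd))
    if not totals:
        # all pathways blocked by stop codons: split differences in
        # proportion to the pair-averaged site fractions
        sa, _ = _site_fractions(ca)
        sb, _ = _site_fractions(cb)
        s_frac = (sa + sb) / 2.0 / 3.0
        return k * s_frac, k * (1.0 - s_frac)
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def ng86_kaks(pair: CodonPair, clock_rate: float = DEFAULT_CLOCK_RATE) -> RateEstimate:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    codons = pair.codons()
    if not codons:
        raise ValueError("no codons to compare")
    s_a = s_b = sd = nd = 0.0
    for ca, cb in codons:
        sa, _ = _site_fractions(ca)
        sb, _ = _site_fractions(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = _pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    total_sites = 3.0 * len(codons)
    S = (s_a + s_b) / 2.0
    N = total_sites - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    ks = _jukes_cantor(pS)
    ka = _jukes_cantor(pN)
    if math.isnan(ks) or ks == 0.0 or math.isnan(ka):
        ratio = math.nan
    else:
        ratio = ka / ks
    return RateEstimate(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, ks=ks, ka=ka, ratio=ratio,
        t_mya=divergence_time(ks, clock_rate),
    )


def divergence_time(ks: float, clock_rate: float = DEFAULT_CLOCK_RATE) -> float:
    """T = Ks / (2 lambda) x 1e-6, in Mya; NaN Ks (saturation) propagates."""
    if math.isnan(ks) or ks < 0:
        return math.nan
    return ks / (2.0 * clock_rate) * 1e-6


# --------------------------------------------------------------------------
# paralog pairs and duplication typing

def find_paralog_pairs(
    proteins: Sequence,
    min_identity: float = 0.70,
    min_coverage: float = 0.75,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> list[tuple[str, str, float]]:
    """All unordered protein pairs passing global-alignment identity/coverage.

    Identity is matches over aligned (both non-gap) columns; coverage is the
    aligned-column count over each sequence's length, and both coverages must
    pass.  Pairs are reported once, with ids sorted, as
    ``(id_a, id_b, identity)``.
    """
    records = [(p.id, p.sequence) for p in proteins]
    if len(records) < 2:
        raise ValueError("need at least two proteins")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    out: list[tuple[str, str, float]] = []
    for (ida, sa), (idb, sb) in itertools.combinations(records, 2):
        aln = aligner.align(sa, sb)[0]
        blocks_a, blocks_b = aln.aligned
        matches = aligned = 0
        for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
            aligned += a1 - a0
            matches += sum(
                1 for x, y in zip(sa[a0:a1], sb[b0:b1]) if x == y
            )
        if aligned == 0:
            continue
        identity = matches / aligned
        cov_a, cov_b = aligned / len(sa), aligned / len(sb)
        if identity >= min_identity and min(cov_a, cov_b) >= min_coverage:
            out.append((*sorted((ida, idb)), identity))
    out.sort()
    return out


@dataclass
class CollinearBlockTable:
    """Collinear (syntenic) block membership, consumed as input."""

    rows: pd.DataFrame  # block_id, species_a, gene_a, species_b, gene_b

    REQUIRED = ("block_id", "species_a", "gene_a", "species_b", "gene_b")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValueError(f"block table missing columns: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path) -> "CollinearBlockTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def within_species_pairs(self) -> set[frozenset[str]]:
        same = self.rows[self.rows.species_a == self.rows.species_b]
        return {
            frozenset((a, b))
            for a, b in zip(same.gene_a, same.gene_b)
        }

    def focal_genes_by_species(self, focal_species: str) -> dict[str, set[str]]:
        """Per partner species, focal-species genes in cross-species pairs."""
        out: dict[str, set[str]] = {}
        for _, r in self.rows.iterrows():
            if r.species_a == focal_species and r.species_b != focal_species:
                out.setdefault(r.species_b, set()).add(r.gene_a)
            elif r.species_b == focal_species and r.species_a != focal_species:
                out.setdefault(r.species_a, set()).add(r.gene_b)
        return out


def classify_duplication(
    pair: tuple[str, str],
    gene_order: Mapping[str, Sequence[str]],
    blocks: CollinearBlockTable | None,
    max_gap: int = 5,
    unplaced: Iterable[str] = (),
) -> DuplicationCall:
    """Type one paralog pair as tandem, segmental or dispersed.

    Block membership (within-species collinear block) implies segmental;
    otherwise same chromosome with at most ``max_gap`` intervening gene
    models is tandem; anything else — including unplaced genes — is
    dispersed.
    """
    a, b = sorted(pair)
    unplaced = set(unplaced)
    if blocks is not None and frozenset((a, b)) in blocks.within_species_pairs():
        return DuplicationCall((a, b), "segmental", "within-species collinear block")
    if a in unplaced or b in unplaced:
        return DuplicationCall((a, b), "dispersed", "unplaced")
    index: dict[str, tuple[str, int]] = {}
    for chrom, genes in gene_order.items():
        for i, g in enumerate(genes):
            index[g] = (chrom, i)
    for g in (a, b):
        if g not in index:
            raise KeyError(f"gene {g!r} absent from annotation")
    (ca, ia), (cb, ib) = index[a], index[b]
    if ca == cb:
        intervening = abs(ia - ib) - 1
        if intervening <= max_gap:
            return DuplicationCall(
                (a, b), "tandem",
                f"same chromosome, {intervening} intervening genes",
            )
        return DuplicationCall(
            (a, b), "dispersed",
            f"same chromosome, {intervening} intervening genes, no block",
        )
    return DuplicationCall((a, b), "dispersed", "different chromosomes, no block")


def conserved_across(
    ortholog_tables: Mapping[str, Iterable[str]],
) -> set[str]:
    """Focal-species genes syntenic with every listed species (intersection)."""
    if not ortholog_tables:
        raise ValueError("need at least one species table")
    sets = [set(v) for v in ortholog_tables.values()]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def gene_order_from_models(models: Iterable) -> dict[str, list[str]]:
    """Per-chromosome gene ids ordered by start coordinate (from GeneModels)."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append((m.start, m.gene_id))
    return {
        chrom: [g for _, g in sorted(items)]
        for chrom, items in by_chrom.items()
    }
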