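"""Promoter extraction and cis-regulatory element scanning.

Promoters are the regions upstream of the start codon (the CDS start, not the
transcription start site), 2000 bp by default, strand-aware: minus-strand
promoters are the reverse complement of the window downstream of the CDS start
on the forward strand.  Cis-elements are IUPAC nucleotide patterns from a user
catalog, scanned on both strands with all (possibly overlapping) matches
reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .family import ConfigurationError
from .structure import GeneModel

__all__ = [
    "Promoter",
    "extract_promoters",
    "scan_cis_elements",
    "reverse_complement",
    "promoter_to_genome",
    "iupac_to_regex",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # 1-based inclusive, genomic, start <= end
    end: int
    sequence: str  # promoter-oriented (5'->3' toward the start codon)
    truncated: bool


def extract_promoters(
    genome: Mapping[str, str],
    models: Iterable[GeneModel],
    length: int = 2000,
) -> dict[str, Promoter]:
    """Extract the ``length``-bp region upstream of each gene's start codon.

    Plus strand: genomic interval [cds_start - length, cds_start - 1];
    minus strand: [cds_start + 1, cds_start + length], reverse-complemented.
    Windows clipped at contig edges are flagged ``truncated``.
    """
    out: dict[str, Promoter] = {}
    for m in models:
        if m.cds_start is None:
            raise ValueError(f"gene {m.gene_id!r} has no CDS start")
        if m.chromosome not in genome:
            raise KeyError(f"chromosome {m.chromosome!r} missing from genome")
        chrom_seq = genome[m.chromosome]
        chrom_len = len(chrom_seq)
        if m.strand == "+":
            start = m.cds_start - length
            end = m.cds_start - 1
            truncated = start < 1
            start = max(start, 1)
            seq = chrom_seq[start - 1:end] if end >= start else ""
        else:
            start = m.cds_start + 1
            end = m.cds_start + length
            truncated = end > chrom_len
            end = min(end, chrom_len)
            seq = (
                reverse_complement(chrom_seq[start - 1:end])
                if end >= start else ""
            )
        out[m.gene_id] = Promoter(
            m.gene_id, m.chromosome, m.strand, start, end, seq.upper(),
            truncated,
        )
    return out


def promoter_to_genome(promoter: Promoter, position: int) -> int:
    """Genomic coordinate of a 1-based position within the promoter sequence."""
    if not 1 <= position <= len(promoter.sequence):
        raise ValueError("position outside promoter")
    if promoter.strand == "+":
        return promoter.start + position - 1
    return promoter.end - position + 1


def iupac_to_regex(pattern: str) -> str:
    """Expand an IUPAC nucleotide pattern to a regex.

    Genome N bases never match any code except the pattern letter N, which
    matches every base (including N).
    """
    parts: list[str] = []
    for ch in pattern.upper():
        if ch == "N":
            parts.append("[ACGTN]")
            continue
        bases = ambiguous_dna_values.get(ch)
        if bases is None:
            raise ConfigurationError(f"invalid IUPAC code {ch!r} in {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def _scan_one_strand(sequence: str, rx: re.Pattern, width: int) -> list[int]:
    """0-based start positions of all (overlapping) matches."""
    return [m.start() for m in rx.finditer(sequence)]


def scan_cis_elements(
    promoters: Mapping[str, Promoter],
    catalog: pd.DataFrame,
    both_strands: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan promoters for every catalog element.

    ``catalog`` needs columns element / category / pattern (IUPAC).  Returns
    the hit table (gene_id, element, category, position, strand) — position
    is the 1-based start of the matched window on the promoter sequence as
    stored (minus-strand hits are positions of the window's leftmost base) —
    and a genes x categories count table.
    """
    for col in ("element", "category", "pattern"):
        if col not in catalog.columns:
            raise ConfigurationError(f"catalog missing column {col!r}")
    compiled: list[tuple[str, str, re.Pattern, int]] = []
    for _, row in catalog.iterrows():
        body = iupac_to_regex(str(row["pattern"]))
        # lookahead so overlapping matches are all reported
        rx = re.compile(f"(?=({body}))")
        compiled.append(
            (str(row["element"]), str(row["category"]), rx, len(str(row["pattern"])))
        )
    records: list[dict] = []
    for gene_id in sorted(promoters):
        prom = promoters[gene_id]
        seq = prom.sequence
        rc = reverse_complement(seq)
        L = len(seq)
        for element, category, rx, width in compiled:
            for pos0 in _scan_one_strand(seq, rx, width):
                records.append({
                    "gene_id": gene_id, "element": element,
                    "category": category, "position": pos0 + 1, "strand": "+",
                })
            if both_strands:
                for pos0 in _scan_one_strand(rc, rx, width):
                    # leftmost base of the window on the stored sequence
                    records.append({
                        "gene_id": gene_id, "element": element,
                        "category": category,
                        "position": L - pos0 - width + 1, "strand": "-",
                    })
    hits = pd.DataFrame(
        records, columns=["gene_id", "element", "category", "position", "strand"]
    )
    if hits.empty:
        counts = pd.DataFrame(index=sorted(promoters))
    else:
        counts = (
            hits.pivot_table(
                index="gene_id", columns="category", values="element",
                aggfunc="count", fill_value=0,
            )
            .reindex(sorted(promoters), fill_value=0)
            .astype(int)
        )
        counts.columns.name = None
    counts.index.name = "gene_id"
    return hits, counts
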