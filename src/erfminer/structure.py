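"""Gene models from GFF3: exon/intron structure and intron-richness classes.

Intron counts come from exon rows of one selected transcript (the longest by
summed exon length, by default), and genes are binned as intron-less (0),
intron-poor (1-3) or intron-rich (>= 4 introns).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal

import gffutils

__all__ = [
    "GeneModel",
    "IntronClass",
    "read_gff3",
    "write_gff3",
    "count_introns",
    "intron_class",
    "classify_gene",
]

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A gene with its transcripts' ordered exon intervals (1-based inclusive).

    ``cds_start`` is the chromosomal position of the first base of the start
    codon (the maximum CDS end for minus-strand genes); it anchors promoter
    extraction.
    """

    gene_id: str
    chromosome: str
    strand: str  # "+" or "-"
    transcripts: list[tuple[str, list[Interval]]] = field(default_factory=list)
    cds_start: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        for tid, exons in self.transcripts:
            exons.sort(key=lambda iv: iv[0])
            prev_end = 0
            for s, e in exons:
                if s > e:
                    raise ValueError(
                        f"gene {self.gene_id!r} transcript {tid!r}: "
                        f"interval [{s}, {e}] has start > end"
                    )
                if s <= prev_end:
                    raise ValueError(
                        f"gene {self.gene_id!r} transcript {tid!r}: "
                        "overlapping or unsorted exons"
                    )
                prev_end = e

    @property
    def start(self) -> int:
        return min(s for _, exons in self.transcripts for s, _ in exons)

    @property
    def end(self) -> int:
        return max(e for _, exons in self.transcripts for _, e in exons)


@dataclass(frozen=True)
class IntronClass:
    gene_id: str
    intron_count: int
    klass: str  # intron-less | intron-poor | intron-rich


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from a GFF3 file (gene / mRNA / exon / CDS rows).

    Genes without an mRNA child but with direct exon children are accepted as
    a single implicit transcript named ``<gene_id>.t1``.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: list[tuple[str, list[Interval]]] = []
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        if mrnas:
            for mrna in mrnas:
                exons = [
                    (f.start, f.end)
                    for f in db.children(mrna, featuretype="exon")
                ]
                transcripts.append((mrna.id, sorted(exons)))
        else:
            exons = [
                (f.start, f.end)
                for f in db.children(gene, featuretype="exon")
            ]
            if exons:
                transcripts.append((f"{gene.id}.t1", sorted(exons)))
        cds = [
            (f.start, f.end)
            for f in db.children(gene, featuretype="CDS")
        ]
        cds_start: int | None = None
        if cds:
            cds_start = (
                min(s for s, _ in cds) if gene.strand == "+"
                else max(e for _, e in cds)
            )
        models.append(
            GeneModel(gene.id, gene.seqid, gene.strand, transcripts, cds_start)
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene / mRNA / exon / CDS rows, CDS == exon)."""
    lines = ["##gff-version 3"]
    for m in models:
        lines.append(
            "\t".join([
                m.chromosome, "erfminer", "gene", str(m.start), str(m.end),
                ".", m.strand, ".", f"ID={m.gene_id}",
            ])
        )
        for tid, exons in m.transcripts:
            t_start, t_end = exons[0][0], exons[-1][1]
            lines.append(
                "\t".join([
                    m.chromosome, "erfminer", "mRNA", str(t_start), str(t_end),
                    ".", m.strand, ".", f"ID={tid};Parent={m.gene_id}",
                ])
            )
            for i, (s, e) in enumerate(exons, 1):
                lines.append(
                    "\t".join([
                        m.chromosome, "erfminer", "exon", str(s), str(e),
                        ".", m.strand, ".",
                        f"ID={tid}.exon{i};Parent={tid}",
                    ])
                )
                lines.append(
                    "\t".join([
                        m.chromosome, "erfminer", "CDS", str(s), str(e),
                        ".", m.strand, "0",
                        f"ID={tid}.cds{i};Parent={tid}",
                    ])
                )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _select_transcript(
    model: GeneModel,
    transcript_policy: Literal["longest", "named"] = "longest",
    transcript_id: str | None = None,
) -> tuple[str, list[Interval]]:
    if not model.transcripts:
        raise ValueError(f"gene {model.gene_id!r} has no transcripts")
    if transcript_policy == "named":
        for tid, exons in model.transcripts:
            if tid == transcript_id:
                return tid, exons
        raise ValueError(
            f"transcript {transcript_id!r} not found in gene {model.gene_id!r}"
        )
    # longest summed exon length; ties -> lexicographically smallest id
    return min(
        model.transcripts,
        key=lambda t: (-sum(e - s + 1 for s, e in t[1]), t[0]),
    )


def count_introns(
    model: GeneModel,
    transcript_policy: Literal["longest", "named"] = "longest",
    transcript_id: str | None = None,
) -> int:
    """Intron count of the selected transcript (exon count minus one)."""
    _tid, exons = _select_transcript(model, transcript_policy, transcript_id)
    return len(exons) - 1


def intron_class(intron_count: int) -> str:
    """0 introns -> intron-less; 1-3 -> intron-poor; >= 4 -> intron-rich."""
    if intron_count < 0:
        raise ValueError("intron count cannot be negative")
    if intron_count == 0:
        return "intron-less"
    if intron_count <= 3:
        return "intron-poor"
    return "intron-rich"


def classify_gene(
    model: GeneModel,
    transcript_policy: Literal["longest", "named"] = "longest",
    transcript_id: str | None = None,
) -> IntronClass:
    n = count_introns(model, transcript_policy, transcript_id)
    return IntronClass(model.gene_id, n, intron_class(n))
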