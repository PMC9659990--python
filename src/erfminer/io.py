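"""Readers and writers for the plain-text interchange formats.

FASTA goes through Biopython; tables are TSV with a header line, UTF-8, LF
line endings.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .evolution import CollinearBlockTable
from .family import DomainHit, ProteinRecord, ReferencePanel

__all__ = [
    "read_fasta",
    "read_proteins",
    "read_panel",
    "read_domain_hits",
    "read_matrix_tsv",
    "read_design_tsv",
    "read_lengths_tsv",
    "read_catalog_tsv",
    "read_blocks_tsv",
    "read_pairs_tsv",
    "write_tsv",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA file as an id -> sequence mapping (uppercased)."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def read_proteins(path: str | os.PathLike) -> list[ProteinRecord]:
    return [
        ProteinRecord(pid, seq) for pid, seq in read_fasta(path).items()
    ]


def read_panel(path: str | os.PathLike) -> ReferencePanel:
    """Reference panel FASTA with labels encoded as ``id|subgroup``."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"panel entry {rec.id!r} lacks an 'id|subgroup' label"
            )
        rid, label = rec.id.rsplit("|", 1)
        entries.append((rid, str(rec.seq).upper(), label))
    return ReferencePanel(entries)


def read_domain_hits(path: str | os.PathLike) -> list[DomainHit]:
    """Domain hits from a domtblout-compatible TSV
    (protein_id, domain, start, end, score)."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainHit(str(r.protein_id), str(r.domain), int(r.start), int(r.end),
                  float(r.score))
        for r in df.itertuples()
    ]


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_lengths_tsv(path: str | os.PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_catalog_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Cis-element catalog: element, category, pattern (IUPAC)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_blocks_tsv(path: str | os.PathLike) -> CollinearBlockTable:
    return CollinearBlockTable.from_tsv(path)


def read_pairs_tsv(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Gene pairs: two-column TSV (id_a, id_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = df.columns[:2]
    return [tuple(r) for r in df[cols].itertuples(index=False)]


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
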