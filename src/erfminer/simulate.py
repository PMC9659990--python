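"""Synthetic fixtures with planted ground truth for every pipeline stage.

Every generator is a pure function of :class:`SimConfig` — the same seed
yields byte-identical files.  The fixtures emulate:

* a protein family with planted domain architectures in the 95/20/3/1
  ERF/AP2/RAV/soloist proportions, a labelled reference panel, and planted
  EAR/EDLL/R-K-LFGV motifs;
* an annotated toy genome (multi-exon genes, tandem neighbours, collinear
  block pairs, mixed strands, one promoter-truncating gene near a contig
  edge);
* codon-sequence pairs with controlled synonymous/nonsynonymous divergence
  (substitution events Poisson-distributed over synonymous or nonsynonymous
  single-nucleotide changes, never through stop codons);
* negative-binomial replicate count matrices for the three transcriptome
  designs (six stages x two tissues; ethephon vs control x three days x two
  tissues; parthenocarpic vs pollinated x two ripeness levels x two
  tissues), with planted tissue-dominant, ripening-correlated and key
  intersection genes plus a background transcriptome so FPKM/TPM totals are
  realistic.

Dominance/correlation/DEG ground-truth labels are derived by applying the
pipeline's threshold rules to the noise-free expected-abundance matrix — the
analytic truth of the planted multiplicative model.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .evolution import BASES, CODON_AA, STOP_CODONS, CodonPair
from .expression import (
    ExpressionMatrix,
    call_degs,
    classify_dominance,
    classify_ripening_correlation,
    compute_fpkm,
    compute_tpm,
    filter_expressed,
    group_by_level,
    intersect_screen,
    standard_comparisons,
    standard_groups,
    _select_samples,
)
from .family import (
    AMINO_ACIDS,
    DomainHit,
    ERF_SUBGROUPS,
    ProteinRecord,
    ReferencePanel,
)
from .structure import GeneModel, write_gff3

__all__ = [
    "SimConfig",
    "FamilyFixture",
    "AnnotationFixture",
    "CodonFixture",
    "ExpressionFixture",
    "AP2_CONSENSUS",
    "B3_CONSENSUS",
    "make_family_fixture",
    "make_annotation_fixture",
    "make_codon_fixture",
    "make_expression_fixture",
]

#: Fixed consensus blocks planted as domains (65 aa AP2-like, 60 aa B3-like),
#: so the fallback consensus scanner and the emitted domain-hit table agree.
AP2_CONSENSUS = (
    "SGYRGVRQRTWGKWVAEIREPRKKSRIWLGTFDTAEEAARAYDEAARAMYGPLARLNFPELLAG"
    "K"
)
B3_CONSENSUS = (
    "KLFGVNLSESDVGRLNRLVIPKQHAEKHFPLQSGNVSVPTSLLVFDSESKSWKFRYSYWN"
)

SPECIES = ("Atha", "Vvin", "Slyc", "Fhis", "Fmac")
FOCAL_SPECIES = "Fcar"


@dataclass
class SimConfig:
    """All knobs of the synthetic study; the seed fully determines outputs."""

    seed: int = 0

    # family fixture
    n_erf: int = 95
    n_ap2: int = 20
    n_rav: int = 3
    n_soloist: int = 1
    n_single_domain_ap2: int = 6  # AP2-subfamily members with one AP2 domain
    protein_mutation_rate: float = 0.05

    # annotation fixture
    ann_chromosomes: int = 3
    genes_per_chromosome: int = 12
    promoter_length: int = 2000

    # codon fixture
    kaks_targets: tuple[tuple[float, float], ...] = ((0.1, 0.0),)
    codon_pairs_per_target: int = 200
    n_codons: int = 300

    # expression fixture
    replicates: int = 3
    dispersion: float = 0.01
    n_background: int = 2000
    depth_factor: float = 30.0
    dominance_effect: float = 8.0
    correlation_effect: float = 4.0
    key_effect: float = 6.0
    deg_effect: float = 4.0
    n_key_up: int = 3
    n_key_down: int = 4
    n_flesh_dominant: int = 3
    n_peel_dominant: int = 9
    n_positive_correlated: int = 9
    n_negative_correlated: int = 27
    n_ethephon_only: int = 6
    n_pollination_only: int = 5
    n_stages_ethephon: int = 4

    def __post_init__(self):
        for name in (
            "n_erf", "n_ap2", "n_rav", "n_soloist", "n_single_domain_ap2",
            "replicates", "n_background",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_single_domain_ap2 > self.n_ap2:
            raise ValueError("more single-domain AP2s than AP2 members")
        for ks, ka in self.kaks_targets:
            if ks < 0 or ka < 0:
                raise ValueError("Ka/Ks targets must be non-negative")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_fasta(records, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def _random_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ==========================================================================
# family fixture

@dataclass
class FamilyFixture:
    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    panel: ReferencePanel
    truth: dict

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(
            [(p.id, p.sequence) for p in self.proteins],
            outdir / "proteins.faa",
        )
        _write_fasta(
            [(f"{rid}|{label}", seq) for rid, seq, label in self.panel.entries],
            outdir / "panel.faa",
        )
        rows = [
            {
                "protein_id": h.protein_id, "domain": h.domain,
                "start": h.start, "end": h.end, "score": round(h.score, 2),
            }
            for h in self.hits
        ]
        pd.DataFrame(rows).to_csv(
            outdir / "domains.tsv", sep="\t", index=False, lineterminator="\n"
        )
        _dump_json(self.truth, outdir / "family_truth.json")


def _plant(seq: str, insert: str, pos0: int) -> str:
    """Overwrite residues at 0-based pos0 with ``insert``."""
    return seq[:pos0] + insert + seq[pos0 + len(insert):]


def make_family_fixture(config: SimConfig) -> FamilyFixture:
    """Proteins with planted domain architectures, panel and motif truth."""
    rng = np.random.default_rng(config.seed)
    ap2 = AP2_CONSENSUS
    b3 = B3_CONSENSUS

    exemplars: dict[str, str] = {}
    for label in ERF_SUBGROUPS:
        backbone = _random_seq(rng, AMINO_ACIDS, 240)
        exemplars[label] = _plant(backbone, ap2, 60)
    backbone = _random_seq(rng, AMINO_ACIDS, 300)
    exemplars["AP2"] = _plant(_plant(backbone, ap2, 40), ap2, 160)
    backbone = _random_seq(rng, AMINO_ACIDS, 280)
    exemplars["RAV"] = _plant(_plant(backbone, ap2, 40), b3, 170)
    backbone = _random_seq(rng, AMINO_ACIDS, 240)
    exemplars["soloist"] = _plant(backbone, ap2, 80)
    panel = ReferencePanel(
        [(f"AT_{label}", exemplars[label], label)
         for label in ERF_SUBGROUPS + ("AP2", "RAV", "soloist")]
    )

    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth_proteins: dict[str, dict] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"FCG_{counter:05d}"

    def score() -> float:
        return float(np.round(rng.uniform(80.0, 120.0), 1))

    # ERFs, round-robin across the 15 subgroups
    erf_ids: list[str] = []
    for i in range(config.n_erf):
        label = ERF_SUBGROUPS[i % len(ERF_SUBGROUPS)]
        pid = new_id()
        seq = _mutate(rng, exemplars[label], config.protein_mutation_rate)
        proteins.append(ProteinRecord(pid, seq))
        hits.append(DomainHit(pid, "AP2", 61, 60 + len(ap2), score()))
        truth_proteins[pid] = {
            "subfamily": "ERF", "subgroup": label, "motifs": [],
        }
        erf_ids.append(pid)

    # AP2 subfamily: two tandem AP2 domains, a few with one
    ap2_ids: list[str] = []
    for i in range(config.n_ap2):
        pid = new_id()
        seq = _mutate(rng, exemplars["AP2"], config.protein_mutation_rate)
        single = i < config.n_single_domain_ap2
        if single:
            seq = _plant(seq, _random_seq(rng, AMINO_ACIDS, len(ap2)), 160)
            hits.append(DomainHit(pid, "AP2", 41, 40 + len(ap2), score()))
        else:
            hits.append(DomainHit(pid, "AP2", 41, 40 + len(ap2), score()))
            hits.append(DomainHit(pid, "AP2", 161, 160 + len(ap2), score()))
        proteins.append(ProteinRecord(pid, seq))
        truth_proteins[pid] = {
            "subfamily": "AP2", "subgroup": "AP2", "motifs": [],
            "single_domain": single,
        }
        ap2_ids.append(pid)

    # RAVs: AP2 + B3
    rav_ids: list[str] = []
    for _ in range(config.n_rav):
        pid = new_id()
        seq = _mutate(rng, exemplars["RAV"], config.protein_mutation_rate)
        proteins.append(ProteinRecord(pid, seq))
        hits.append(DomainHit(pid, "AP2", 41, 40 + len(ap2), score()))
        hits.append(DomainHit(pid, "B3", 171, 170 + len(b3), score()))
        truth_proteins[pid] = {
            "subfamily": "RAV", "subgroup": "RAV", "motifs": [],
        }
        rav_ids.append(pid)

    # soloist
    for _ in range(config.n_soloist):
        pid = new_id()
        seq = _mutate(rng, exemplars["soloist"], config.protein_mutation_rate)
        proteins.append(ProteinRecord(pid, seq))
        hits.append(DomainHit(pid, "AP2", 81, 80 + len(ap2), score()))
        truth_proteins[pid] = {
            "subfamily": "soloist", "subgroup": "soloist", "motifs": [],
        }

    # planted regulatory motifs (EAR in six ERFs + two AP2s, one ERF with an
    # extra middle-region EAR; EDLL in four ERFs; R/K-LFGV in two RAVs)
    by_id = {p.id: i for i, p in enumerate(proteins)}

    def plant_motif(pid: str, motif: str, text: str, pos0: int) -> None:
        i = by_id[pid]
        proteins[i] = ProteinRecord(pid, _plant(proteins[i].sequence, text, pos0))
        truth_proteins[pid]["motifs"].append(
            {"motif": motif, "start": pos0 + 1, "end": pos0 + len(text),
             "matched_text": text}
        )

    ear_erfs = erf_ids[:min(6, len(erf_ids))]
    for pid in ear_erfs:
        plant_motif(pid, "EAR", "LDLNLAP", len(proteins[by_id[pid]]) - 20)
    if ear_erfs:
        plant_motif(ear_erfs[0], "EAR", "FDLNFQP", 130)  # middle region too
    for pid in ap2_ids[:2]:
        plant_motif(pid, "EAR", "LDLNLAP", len(proteins[by_id[pid]]) - 20)
    for pid in erf_ids[6:10]:
        plant_motif(pid, "EDLL", "EDLL", len(proteins[by_id[pid]]) - 30)
    for j, pid in enumerate(rav_ids[:2]):
        plant_motif(pid, "RKLFGV", "RLFGV" if j == 0 else "KLFGV",
                    len(proteins[by_id[pid]]) - 15)

    truth = {
        "proteins": truth_proteins,
        "counts": {
            "ERF": config.n_erf, "AP2": config.n_ap2,
            "RAV": config.n_rav, "soloist": config.n_soloist,
        },
    }
    return FamilyFixture(proteins, hits, panel, truth)


# ==========================================================================
# annotation fixture

@dataclass
class AnnotationFixture:
    genome: dict[str, str]
    models: list[GeneModel]
    blocks: pd.DataFrame
    ortholog_tables: dict[str, set[str]]
    truth: dict

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(sorted(self.genome.items()), outdir / "genome.fna")
        write_gff3(self.models, outdir / "genes.gff3")
        self.blocks.to_csv(
            outdir / "blocks.tsv", sep="\t", index=False, lineterminator="\n"
        )
        rows = [
            {"species": sp, "focal_gene": g}
            for sp in sorted(self.ortholog_tables)
            for g in sorted(self.ortholog_tables[sp])
        ]
        pd.DataFrame(rows).to_csv(
            outdir / "orthologs.tsv", sep="\t", index=False, lineterminator="\n"
        )
        _dump_json(self.truth, outdir / "annotation_truth.json")


def make_annotation_fixture(config: SimConfig) -> AnnotationFixture:
    """Toy genome + GFF3 with planted structure, tandem and block pairs."""
    rng = np.random.default_rng(config.seed + 1)
    exon_cycle = [1, 1, 2, 4, 3, 6, 1, 5, 2, 1, 7, 3]
    models: list[GeneModel] = []
    genome: dict[str, str] = {}
    truth_genes: dict[str, dict] = {}
    gidx = 0
    for c in range(config.ann_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = 3000
        ids_on_chrom: list[str] = []
        for g in range(config.genes_per_chromosome):
            gidx += 1
            gene_id = f"FCA_{gidx:04d}"
            if c == 0 and g == 0:
                n_exons = 12  # planted intron-rich gene: 12 exons, 11 introns
            else:
                n_exons = exon_cycle[g % len(exon_cycle)]
            if c == 1 and g == 0:
                cursor = 500  # planted promoter truncation at the contig edge
            strand = "+" if (gidx % 2 == 1) else "-"
            exons: list[tuple[int, int]] = []
            pos = cursor
            for _ in range(n_exons):
                length = int(rng.integers(150, 401))
                exons.append((pos, pos + length - 1))
                pos = pos + length + int(rng.integers(80, 301))
            gene_end = exons[-1][1]
            cds_start = exons[0][0] if strand == "+" else gene_end
            models.append(GeneModel(
                gene_id, chrom, strand,
                [(f"{gene_id}.t1", exons)], cds_start,
            ))
            truth_genes[gene_id] = {
                "chromosome": chrom, "strand": strand,
                "n_exons": n_exons, "n_introns": n_exons - 1,
            }
            ids_on_chrom.append(gene_id)
            cursor = gene_end + int(rng.integers(1200, 2501))
        genome[chrom] = _random_seq(rng, BASES, cursor + 2500)

    by_chrom: dict[str, list[str]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m.gene_id)
    chr1, chr2, chr3 = (by_chrom.get(f"chr{i}", []) for i in (1, 2, 3))

    tandem_pair = tuple(sorted(chr3[4:6])) if len(chr3) >= 6 else None
    dispersed_pair = (
        tuple(sorted((chr1[1], chr1[9]))) if len(chr1) >= 10 else None
    )
    segmental_pair = (
        tuple(sorted((chr1[2], chr2[2])))
        if len(chr1) >= 3 and len(chr2) >= 3 else None
    )

    block_rows: list[dict] = []
    if segmental_pair:
        block_rows.append({
            "block_id": "B001", "species_a": FOCAL_SPECIES,
            "gene_a": segmental_pair[0], "species_b": FOCAL_SPECIES,
            "gene_b": segmental_pair[1],
        })
    all_ids = [m.gene_id for m in models]
    conserved = sorted(all_ids[:4])
    ortholog_tables: dict[str, set[str]] = {}
    for si, sp in enumerate(SPECIES):
        extra = set(all_ids[4 + si:4 + si + 3])
        ortholog_tables[sp] = set(conserved) | extra
        for g in sorted(ortholog_tables[sp]):
            block_rows.append({
                "block_id": f"X{si:02d}", "species_a": FOCAL_SPECIES,
                "gene_a": g, "species_b": sp,
                "gene_b": f"{sp}_{g}",
            })
    blocks = pd.DataFrame(
        block_rows,
        columns=["block_id", "species_a", "gene_a", "species_b", "gene_b"],
    )

    truth = {
        "genes": truth_genes,
        "intron_rich_gene": models[0].gene_id,
        "truncated_promoter_gene": chr2[0] if chr2 else None,
        "tandem_pair": tandem_pair,
        "dispersed_pair": dispersed_pair,
        "segmental_pair": segmental_pair,
        "conserved_across_all": conserved,
        "promoter_length": config.promoter_length,
    }
    return AnnotationFixture(genome, models, blocks, ortholog_tables, truth)


# ==========================================================================
# codon fixture

_SENSE_CODONS = sorted(CODON_AA)


def _substitution_candidates(codon: str, synonymous: bool) -> list[tuple[int, str]]:
    """Single-nucleotide changes of one codon that are (non)synonymous and
    never create a stop codon."""
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            if (CODON_AA[alt] == CODON_AA[codon]) == synonymous:
                out.append((pos, base))
    return out


@dataclass
class CodonFixture:
    pairs: list[CodonPair]
    truth: dict

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = []
        for p in self.pairs:
            records.append((p.id_a, p.cds_a))
            records.append((p.id_b, p.cds_b))
        _write_fasta(records, outdir / "codon_pairs.fna")
        _dump_json(self.truth, outdir / "codon_truth.json")


def make_codon_fixture(config: SimConfig) -> CodonFixture:
    """Codon pairs with controlled synonymous/nonsynonymous divergence.

    For target Ks the expected proportion of synonymous differences is the
    Jukes-Cantor inverse pS = (3/4)(1 - exp(-4 Ks / 3)); the number of
    substitution events is Poisson(pS * S) and each event applies one random
    synonymous single-nucleotide change to a distinct codon (likewise for
    Ka on nonsynonymous sites, on disjoint codons).
    """
    from .evolution import _site_fractions  # site counting shared with NG86

    rng = np.random.default_rng(config.seed + 2)
    pairs: list[CodonPair] = []
    truth_pairs: list[dict] = []
    for t, (ks, ka) in enumerate(config.kaks_targets):
        p_s = 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))
        p_n = 0.75 * (1.0 - math.exp(-4.0 * ka / 3.0))
        for r in range(config.codon_pairs_per_target):
            codons = [
                _SENSE_CODONS[i]
                for i in rng.integers(len(_SENSE_CODONS), size=config.n_codons)
            ]
            s_sites = sum(_site_fractions(c)[0] for c in codons)
            n_sites = 3 * config.n_codons - s_sites
            syn_ok = [i for i, c in enumerate(codons)
                      if _substitution_candidates(c, True)]
            non_ok = [i for i, c in enumerate(codons)
                      if _substitution_candidates(c, False)]
            # one event per codon: the target is unreachable when the
            # expected event count exceeds the mutable-codon capacity
            if p_s * s_sites > len(syn_ok) or p_n * n_sites > len(non_ok):
                raise ValueError(
                    "divergence target unreachable on this sequence length"
                )
            n_syn = int(rng.poisson(p_s * s_sites))
            n_non = int(rng.poisson(p_n * n_sites))
            if n_syn > len(syn_ok) or n_non > len(non_ok) - n_syn:
                raise ValueError(
                    "divergence target unreachable on this sequence length"
                )
            chosen_syn = rng.choice(syn_ok, size=n_syn, replace=False)
            remaining = [i for i in non_ok if i not in set(chosen_syn)]
            chosen_non = rng.choice(remaining, size=n_non, replace=False)
            derived = list(codons)
            for i in chosen_syn:
                cands = _substitution_candidates(codons[i], True)
                pos, base = cands[rng.integers(len(cands))]
                derived[i] = derived[i][:pos] + base + derived[i][pos + 1:]
            for i in chosen_non:
                cands = _substitution_candidates(codons[i], False)
                pos, base = cands[rng.integers(len(cands))]
                derived[i] = derived[i][:pos] + base + derived[i][pos + 1:]
            pair = CodonPair(
                f"pair{t}_{r}_a", f"pair{t}_{r}_b",
                "".join(codons), "".join(derived),
            )
            pairs.append(pair)
            truth_pairs.append({
                "id_a": pair.id_a, "id_b": pair.id_b,
                "target_ks": ks, "target_ka": ka,
                "planted_synonymous": int(n_syn),
                "planted_nonsynonymous": int(n_non),
            })
    return CodonFixture(pairs, {"pairs": truth_pairs})


# ==========================================================================
# expression fixture

_ROLE_FIELDS = (
    "key_up", "key_down", "flesh_dominant", "peel_dominant",
    "positive_correlated", "negative_correlated",
    "ethephon_only", "pollination_only", "stages_ethephon",
)


@dataclass
class ExpressionFixture:
    counts: dict[str, pd.DataFrame]
    designs: dict[str, pd.DataFrame]
    lengths: pd.Series
    units: dict[str, str]
    family_genes: list[str]
    subfamilies: dict[str, str]
    truth: dict

    def abundances(self) -> dict[str, tuple[ExpressionMatrix, pd.DataFrame]]:
        """Normalized matrices per dataset, in each dataset's declared unit."""
        out = {}
        for name, cts in self.counts.items():
            fn = compute_fpkm if self.units[name] == "FPKM" else compute_tpm
            out[name] = (fn(cts, self.lengths), self.designs[name])
        return out

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, cts in self.counts.items():
            cts.to_csv(outdir / f"counts_{name}.tsv", sep="\t",
                       index_label="gene", lineterminator="\n")
            self.designs[name].to_csv(
                outdir / f"design_{name}.tsv", sep="\t", index=False,
                lineterminator="\n",
            )
        self.lengths.rename("length").to_csv(
            outdir / "lengths.tsv", sep="\t", index_label="gene",
            lineterminator="\n",
        )
        _dump_json(self.truth, outdir / "expression_truth.json")


def _stage_designs(config: SimConfig) -> dict[str, pd.DataFrame]:
    reps = range(1, config.replicates + 1)
    rows: dict[str, list[dict]] = {"stages": [], "ethephon": [], "pollination": []}
    for tissue, code in (("flesh", "F"), ("peel", "P")):
        for stage in range(1, 7):
            for rep in reps:
                rows["stages"].append({
                    "sample_id": f"{code}{stage}_r{rep}", "dataset": "stages",
                    "tissue": tissue, "stage": stage, "treatment": "none",
                    "day": None, "replicate": rep,
                })
    for treatment, code in (("ethephon", "E"), ("control", "W")):
        for day in (2, 4, 6):
            for tissue, tcode in (("flesh", "F"), ("receptacle", "R")):
                for rep in reps:
                    rows["ethephon"].append({
                        "sample_id": f"{code}{day}{tcode}_r{rep}",
                        "dataset": "ethephon", "tissue": tissue,
                        "stage": None, "treatment": treatment, "day": day,
                        "replicate": rep,
                    })
    for treatment, code in (("parthenocarpic", "Par"), ("pollinated", "Pol")):
        for ripeness in (60, 100):
            for tissue, tcode in (("flesh", "F"), ("receptacle", "R")):
                for rep in reps:
                    rows["pollination"].append({
                        "sample_id": f"{code}_{ripeness}_{tcode}_r{rep}",
                        "dataset": "pollination", "tissue": tissue,
                        "stage": ripeness, "treatment": treatment,
                        "day": None, "replicate": rep,
                    })
    return {k: pd.DataFrame(v) for k, v in rows.items()}


def _sample_multiplier(config: SimConfig, roles: dict[str, np.ndarray],
                       dataset: str, row: pd.Series) -> np.ndarray:
    """Per-gene multiplicative effect for one sample (vector over genes)."""
    m = np.ones(len(roles["key_up"]))
    ke, de = config.key_effect, config.deg_effect
    if dataset == "stages":
        if row.tissue == "flesh":
            m = np.where(roles["flesh_dominant"], m * config.dominance_effect, m)
        if row.tissue == "peel":
            m = np.where(roles["peel_dominant"], m * config.dominance_effect, m)
        if row.stage >= 4:
            m = np.where(roles["positive_correlated"],
                         m * config.correlation_effect, m)
            m = np.where(roles["negative_correlated"],
                         m / config.correlation_effect, m)
        if row.stage == 6:
            m = np.where(roles["key_up"], m * ke, m)
            m = np.where(roles["key_down"], m / ke, m)
            m = np.where(roles["stages_ethephon"], m * ke, m)
    elif dataset == "ethephon":
        if row.treatment == "ethephon":
            if row.day in (4, 6):
                m = np.where(roles["key_up"], m * ke, m)
                m = np.where(roles["key_down"], m / ke, m)
            if row.day in (2, 4):
                m = np.where(roles["ethephon_only"], m * de, m)
            if row.day == 4:
                m = np.where(roles["stages_ethephon"], m * ke, m)
    elif dataset == "pollination":
        if row.stage == 100:
            m = np.where(roles["key_up"], m * ke, m)
            m = np.where(roles["key_down"], m / ke, m)
            if row.treatment == "parthenocarpic":
                m = np.where(roles["pollination_only"], m * de, m)
    return m


def make_expression_fixture(config: SimConfig) -> ExpressionFixture:
    """Three replicate count datasets with planted expression patterns."""
    rng = np.random.default_rng(config.seed + 3)
    n_fam = config.n_erf + config.n_ap2 + config.n_rav + config.n_soloist
    fam_genes = [f"FCG_{i + 1:05d}" for i in range(n_fam)]
    subfam = {}
    for i, g in enumerate(fam_genes):
        if i < config.n_erf:
            subfam[g] = "ERF"
        elif i < config.n_erf + config.n_ap2:
            subfam[g] = "AP2"
        elif i < config.n_erf + config.n_ap2 + config.n_rav:
            subfam[g] = "RAV"
        else:
            subfam[g] = "soloist"
    bg_genes = [f"BG_{i + 1:04d}" for i in range(config.n_background)]
    genes = fam_genes + bg_genes
    gene_index = {g: i for i, g in enumerate(genes)}

    # role assignment: key genes mirror the study's six ERFs + one RAV
    erf_pool = [g for g in fam_genes if subfam[g] == "ERF"]
    rav_pool = [g for g in fam_genes if subfam[g] == "RAV"]
    erf_shuffled = list(rng.permutation(erf_pool))
    n_keys = config.n_key_up + config.n_key_down
    key_erfs = erf_shuffled[:max(0, n_keys - 1)]
    key_genes = sorted(key_erfs + rav_pool[:1])[:n_keys]
    key_up = set(key_genes[:config.n_key_up])
    key_down = set(key_genes[config.n_key_up:])

    others = [g for g in fam_genes if g not in set(key_genes)]
    others = list(rng.permutation(others))
    roles_named: dict[str, set[str]] = {
        "key_up": key_up, "key_down": key_down,
    }
    cursor = 0
    for role, n in (
        ("flesh_dominant", config.n_flesh_dominant),
        ("peel_dominant", config.n_peel_dominant),
        ("positive_correlated", config.n_positive_correlated),
        ("negative_correlated", config.n_negative_correlated),
        ("ethephon_only", config.n_ethephon_only),
        ("pollination_only", config.n_pollination_only),
        ("stages_ethephon", config.n_stages_ethephon),
    ):
        roles_named[role] = set(others[cursor:cursor + n])
        cursor += n
    remaining = others[cursor:]
    low_genes = set(remaining[:len(remaining) // 2])

    roles = {
        r: np.array([g in roles_named[r] for g in genes])
        for r in _ROLE_FIELDS
    }

    # baseline abundance scale (FPKM-like) and gene lengths
    theta = np.empty(len(genes))
    for g, i in gene_index.items():
        if g in low_genes:
            theta[i] = rng.uniform(2.0, 12.0)
        elif g.startswith("BG_"):
            theta[i] = rng.uniform(50.0, 450.0)
        else:
            theta[i] = rng.uniform(80.0, 300.0)
    lengths = pd.Series(
        rng.integers(600, 3001, size=len(genes)).astype(int),
        index=genes, name="length",
    )

    designs = _stage_designs(config)
    units = {"stages": "FPKM", "ethephon": "TPM", "pollination": "TPM"}
    counts: dict[str, pd.DataFrame] = {}
    expected: dict[str, pd.DataFrame] = {}
    r_nb = 1.0 / config.dispersion
    len_kb = lengths.to_numpy() / 1000.0
    for name, design in designs.items():
        cols = {}
        exp_cols = {}
        for _, row in design.iterrows():
            mult = _sample_multiplier(config, roles, name, row)
            mu = theta * mult * len_kb * config.depth_factor
            p = r_nb / (r_nb + mu)
            cols[row.sample_id] = rng.negative_binomial(r_nb, p)
            exp_cols[row.sample_id] = mu
        counts[name] = pd.DataFrame(cols, index=genes)
        expected[name] = pd.DataFrame(exp_cols, index=genes)

    # ---- analytic ground truth from the noise-free expected matrices
    truth: dict = {
        "key_genes": sorted(str(g) for g in key_genes),
        "roles": {r: sorted(str(g) for g in roles_named[r]) for r in roles_named},
        "subfamilies": subfam,
    }
    norm = {
        name: (compute_fpkm if units[name] == "FPKM" else compute_tpm)(
            expected[name], lengths
        )
        for name in expected
    }
    expressed = {name: set(filter_expressed(m)) for name, m in norm.items()}
    truth["expressed"] = {
        name: sorted(e & set(fam_genes)) for name, e in expressed.items()
    }
    stages_mat = norm["stages"]
    level = group_by_level(stages_mat)
    dom = classify_dominance(stages_mat, designs["stages"])
    corr = classify_ripening_correlation(stages_mat, designs["stages"])
    truth["group"] = {g: level[g] for g in fam_genes}
    truth["dominance"] = {
        g: dom[g] if g in expressed["stages"] else "none" for g in fam_genes
    }
    truth["correlation"] = {
        g: (corr[g] if g in expressed["stages"]
            else {t: "none" for t in corr[g]})
        for g in fam_genes
    }
    comparisons = standard_comparisons()
    groups = standard_groups(comparisons)
    deg_truth: dict[str, pd.DataFrame] = {}
    de_by_gene: dict[str, dict[str, str]] = {g: {} for g in fam_genes}
    for comp in comparisons:
        mat = norm[comp.dataset]
        design = designs[comp.dataset]
        keep = sorted(expressed[comp.dataset])
        sub = ExpressionMatrix(mat.values.loc[keep], mat.unit)
        table = call_degs(
            sub, _select_samples(design, comp.case),
            _select_samples(design, comp.control), comparison_id=comp.id,
        )
        deg_truth[comp.id] = table
        sig = table.loc[table.significant]
        for g in fam_genes:
            de_by_gene[g][comp.id] = (
                str(sig.loc[g, "direction"]) if g in sig.index else ""
            )
    truth["de"] = de_by_gene
    expected_keys, _ = intersect_screen(deg_truth, groups)
    truth["expected_key_genes"] = sorted(expected_keys)

    return ExpressionFixture(
        counts=counts, designs=designs, lengths=lengths, units=units,
        family_genes=fam_genes, subfamilies=subfam, truth=truth,
    )
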