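"""AP2/ERF subfamily and subgroup classification from domain architecture.

The AP2/ERF superfamily of plant transcription factors is defined by the
~60-70 aa AP2 DNA-binding domain.  Domain architecture splits the family into
subfamilies: a single AP2 domain (ERF, plus a handful of AP2-subfamily members
and one divergent "soloist"), two tandem AP2 domains (AP2), and AP2 + B3 (RAV).
Where the architecture is ambiguous (a single AP2 domain), the nearest entry of
a labelled reference panel — best global alignment score — decides the
subfamily and, for ERFs, the subgroup (Ia ... Xb).

The module also detects short C-terminal regulatory motifs (the EAR and
R/K-LFGV repression motifs and the EDLL activation motif) and computes basic
protein properties (length, average molecular weight, isoelectric point).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "SubfamilyCall",
    "MotifHit",
    "ReferencePanel",
    "NotFamilyMemberError",
    "ConfigurationError",
    "ERF_SUBGROUPS",
    "ALL_SUBGROUPS",
    "DEFAULT_MOTIF_PATTERNS",
    "merge_candidates",
    "assign_subgroup",
    "classify_subfamily",
    "detect_cterm_motifs",
    "protein_properties",
    "scan_domains",
]

#: ERF-subfamily subgroups in the Arabidopsis-based classification.
ERF_SUBGROUPS: tuple[str, ...] = (
    "Ia", "Ib", "II", "III", "IV", "Va", "Vb", "VIa", "VIb",
    "VIIa", "VIIb", "VIII", "IX", "Xa", "Xb",
)
ALL_SUBGROUPS: tuple[str, ...] = ERF_SUBGROUPS + ("AP2", "RAV", "soloist")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = set(AMINO_ACIDS + "X")


class NotFamilyMemberError(ValueError):
    """The protein carries no AP2 domain hit and is not a family member."""


class ConfigurationError(ValueError):
    """User-supplied pattern/panel/parameter is malformed."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - _VALID_AA
        if bad:
            raise ValueError(
                f"protein {self.id!r} has invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain: str  # "AP2" or "B3"
    start: int  # 1-based inclusive
    end: int
    score: float = 0.0

    def __post_init__(self):
        if self.domain not in ("AP2", "B3"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid domain interval [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class SubfamilyCall:
    protein_id: str
    subfamily: str  # ERF | AP2 | RAV | soloist
    subgroup: str
    nearest_reference: str
    alignment_score: float


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: str
    start: int  # 1-based inclusive
    end: int
    matched_text: str
    region: str = ""  # N-terminal | middle | C-terminal


@dataclass
class ReferencePanel:
    """Labelled reference proteins, one or more exemplars per subgroup."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        for ref_id, _seq, label in self.entries:
            if label not in ALL_SUBGROUPS:
                raise ConfigurationError(
                    f"panel entry {ref_id!r} has unknown subgroup label {label!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, labels: Iterable[str]) -> "ReferencePanel":
        keep = set(labels)
        return ReferencePanel(
            [e for e in self.entries if e[2] in keep]
        )


# --------------------------------------------------------------------------
# candidate merging

def merge_candidates(
    homology_ids: Iterable[str],
    domain_ids: Iterable[str],
    confirmed: Iterable[str],
) -> set[str]:
    """Merge homology-search and domain-search candidates, keep confirmed ones.

    Mirrors the two-pronged screen (BLAST homology + profile-domain search)
    whose union is then restricted to proteins whose AP2 domain was confirmed.
    """
    return (set(homology_ids) | set(domain_ids)) & set(confirmed)


# --------------------------------------------------------------------------
# alignment-based subgroup assignment

def _make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def assign_subgroup(
    protein: ProteinRecord,
    panel: ReferencePanel,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[str, str, float]:
    """Return ``(label, nearest_reference_id, alignment_score)``.

    The label is that of the panel entry with the maximal global alignment
    score (affine gaps); exact ties go to the lexicographically smallest
    reference id.  Invariant to panel order except through that tie rule.
    """
    if not panel.entries:
        raise ConfigurationError("reference panel is empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    best: tuple[float, str, str] | None = None
    for ref_id, ref_seq, label in sorted(panel.entries, key=lambda e: e[0]):
        score = aligner.score(protein.sequence, ref_seq)
        if best is None or score > best[0]:
            best = (score, ref_id, label)
    assert best is not None
    score, ref_id, label = best
    return label, ref_id, float(score)


def classify_subfamily(
    hits: Sequence[DomainHit],
    panel: ReferencePanel,
    protein: ProteinRecord,
    **aligner_kwargs,
) -> SubfamilyCall:
    """Call the subfamily of one protein from its domain hits.

    Rules: AP2 + B3 -> RAV; two or more AP2 domains (no B3) -> AP2; exactly
    one AP2 domain -> ERF, AP2 or soloist, decided by the nearest reference
    (some AP2-subfamily members carry a single AP2 domain).  No AP2 hit at
    all means the protein is not a family member.
    """
    mine = [h for h in hits if h.protein_id == protein.id]
    n_ap2 = sum(1 for h in mine if h.domain == "AP2")
    n_b3 = sum(1 for h in mine if h.domain == "B3")
    if n_ap2 == 0:
        raise NotFamilyMemberError(
            f"protein {protein.id!r} has no AP2 domain hit"
        )
    label, ref_id, score = assign_subgroup(protein, panel, **aligner_kwargs)
    if n_b3 >= 1:
        subfamily, subgroup = "RAV", "RAV"
    elif n_ap2 >= 2:
        subfamily, subgroup = "AP2", "AP2"
    else:
        if label == "soloist":
            subfamily, subgroup = "soloist", "soloist"
        elif label == "AP2":
            subfamily, subgroup = "AP2", "AP2"
        elif label in ERF_SUBGROUPS:
            subfamily, subgroup = "ERF", label
        else:
            # single AP2 domain but nearest reference is RAV-labelled: no B3
            # evidence, so call ERF and re-assign the subgroup among ERF
            # references only.
            subfamily = "ERF"
            erf_panel = panel.subset(ERF_SUBGROUPS)
            if erf_panel.entries:
                subgroup, ref_id, score = assign_subgroup(
                    protein, erf_panel, **aligner_kwargs
                )
            else:
                subgroup = ERF_SUBGROUPS[0]
    return SubfamilyCall(protein.id, subfamily, subgroup, ref_id, score)


# --------------------------------------------------------------------------
# C-terminal motif detection

#: Default motif patterns.  EAR is (L/F)DLN(L/F)(x)P; the wildcard position
#: matches any residue (including X), the residue classes never match X.
#: The broader LxLxL EAR variant is available but off by default.
DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    "EAR": r"[LF]DLN[LF].P",
    "RKLFGV": r"[RK]LFGV",
    "EDLL": r"EDLL",
}

EAR_LXLXL_PATTERN = r"L.L.L"


def _region_of(start: int, length: int) -> str:
    """Thirds of the sequence, by 1-based match start position."""
    if start > 2 * length / 3:
        return "C-terminal"
    if start > length / 3:
        return "middle"
    return "N-terminal"


def detect_cterm_motifs(
    protein: ProteinRecord,
    region_fraction: float = 1.0,
    patterns: Mapping[str, str] | None = None,
) -> list[MotifHit]:
    """Find all non-overlapping matches of each regulatory-motif pattern.

    Scans the C-terminal ``region_fraction`` of the sequence (1.0 = whole
    sequence, the default); each hit is annotated with the third of the
    protein (N-terminal / middle / C-terminal) in which it starts.
    """
    if patterns is None:
        patterns = DEFAULT_MOTIF_PATTERNS
    if not 0 < region_fraction <= 1:
        raise ConfigurationError("region_fraction must be in (0, 1]")
    seq = protein.sequence
    length = len(seq)
    offset = length - int(round(length * region_fraction))
    window = seq[offset:]
    hits: list[MotifHit] = []
    for name, pattern in patterns.items():
        try:
            rx = re.compile(pattern)
        except re.error as exc:
            raise ConfigurationError(
                f"malformed pattern for motif {name!r}: {exc}"
            ) from exc
        for m in rx.finditer(window):
            start = offset + m.start() + 1
            end = offset + m.end()
            hits.append(
                MotifHit(
                    protein.id, name, start, end, m.group(0),
                    region=_region_of(start, length),
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


# --------------------------------------------------------------------------
# protein properties

#: Average residue (amino acid minus water) masses, Da.  X contributes zero.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 0.0,
}
WATER_MASS = 18.0153

#: pKa values (EMBOSS set) used for the net-charge equation behind pI.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of a peptide at a given pH (Henderson–Hasselbalch)."""
    counts = {aa: sequence.count(aa) for aa in "KRHDECY"}
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def protein_properties(
    protein: ProteinRecord,
) -> tuple[int, float, float]:
    """Return ``(length_aa, molecular_weight_Da, isoelectric_point)``.

    The molecular weight is the sum of average residue masses plus one water
    (18.0153 Da); X residues contribute to the length only.  The pI is found
    by bisection on the net-charge equation to 0.01 pH units.
    """
    seq = protein.sequence
    mw = sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    lo, hi = 0.0, 14.0
    while hi - lo > 0.01:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return len(seq), mw, (lo + hi) / 2.0


# --------------------------------------------------------------------------
# minimal consensus scanner (so synthetic tests run without a profile-HMM
# search; real domain hits are consumed from a domtblout-compatible TSV)

def scan_domains(
    protein: ProteinRecord,
    consensus: str,
    domain: str,
    min_identity: float = 0.7,
) -> list[DomainHit]:
    """Slide a fixed consensus string along the protein and report windows
    with identity >= ``min_identity`` as domain hits, greedily non-overlapping
    from the best-scoring window down."""
    w = len(consensus)
    seq = protein.sequence
    candidates: list[tuple[float, int]] = []
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        ident = sum(a == b for a, b in zip(window, consensus)) / w
        if ident >= min_identity:
            candidates.append((ident, i))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[int, int]] = []
    hits: list[DomainHit] = []
    for ident, i in candidates:
        if any(i < e and i + w > s for s, e in taken):
            continue
        taken.append((i, i + w))
        hits.append(
            DomainHit(protein.id, domain, i + 1, i + w, score=100.0 * ident)
        )
    hits.sort(key=lambda h: h.start)
    return hits
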