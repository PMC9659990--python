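"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with :mod:`erfminer` — only the standard
genetic code table and the BLOSUM62 matrix, which are fixed public data.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA_OF = dict(_TABLE.forward_table)
STOPS = set(_TABLE.stop_codons)
SENSE_CODONS = sorted(AA_OF)


def oracle_site_counts(codon: str) -> tuple[float, float]:
    """Fraction of the nine single-nucleotide changes that are synonymous,
    counted exhaustively (stop-codon changes are nonsynonymous)."""
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOPS and AA_OF[alt] == AA_OF[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def oracle_pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous steps over all orderings of the
    differing positions, skipping orderings that pass through a stop."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, steps, ok = ca, [], True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            steps.append(AA_OF[cur] == AA_OF[nxt])
            cur = nxt
        if ok:
            results.append(steps)
    if not results:
        k = len(diffs)
        s_frac = (oracle_site_counts(ca)[0] + oracle_site_counts(cb)[0]) / 6.0
        return k * s_frac, k * (1.0 - s_frac)
    sd = sum(sum(steps) for steps in results) / len(results)
    total = len(diffs)
    return sd, total - sd


def oracle_ng86_raw(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for two aligned coding sequences, by enumeration."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        sa, na = oracle_site_counts(ca)
        sb, nb = oracle_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = oracle_pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def oracle_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up by its textbook definition:
    adj_(i) = min_{j >= i} min(1, p_(j) * m / j) on the sorted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj_sorted[rank - 1] = running_min
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def oracle_global_alignment_score(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Gotoh affine-gap global alignment score (first gap residue costs
    ``gap_open``, each further residue ``gap_extend``), quadratic DP."""
    blosum = substitution_matrices.load("BLOSUM62")
    na, nb = len(a), len(b)
    NEG = -1e18
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in b (a consumed)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, nb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[na, nb], X[na, nb], Y[na, nb]))


def oracle_spearman(x, y) -> float:
    """Rank correlation via average ranks and the Pearson formula on ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)
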