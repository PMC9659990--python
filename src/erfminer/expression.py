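"""Expression normalization, ratio-based pattern classification and the
three-dataset intersection screen for ripening regulator genes.

Abundances are FPKM or TPM computed from raw counts and gene lengths.  The
classification rules are simple printed thresholds, applied exactly:

* expressed: maximum abundance >= 20 (inclusive) in at least one sample;
* expression-level groups: C if max < 20, B if 20 <= max < 300, A if >= 300;
* tissue dominance: flesh if sum(flesh)/sum(peel) > 5, peel if < 0.2;
* ripening correlation per tissue: positive if (late-stage sum)/(early-stage
  sum) > 2, negative if < 0.5;
* differential expression: |log2 fold change| >= 1, optionally with a Welch
  test on log2(x + pseudocount) and Benjamini-Hochberg adjustment < 0.05.

A gene is a "key" ripening candidate when it is differentially regulated in
at least one comparison of every comparison group (one group per transcriptome
dataset).  The module also provides 2^-ddCT relative quantification for qPCR
and Spearman rank co-expression.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ScreenReport",
    "compute_fpkm",
    "compute_tpm",
    "filter_expressed",
    "group_by_level",
    "classify_dominance",
    "classify_ripening_correlation",
    "call_degs",
    "bh_adjust",
    "intersect_screen",
    "delta_delta_ct",
    "spearman_coexpression",
    "standard_comparisons",
    "standard_groups",
    "run_screen",
]

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = (
    "sample_id", "dataset", "tissue", "stage", "treatment", "day", "replicate",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with its unit and gene lengths (bp)."""

    values: pd.DataFrame
    unit: str  # counts | FPKM | TPM
    lengths: pd.Series | None = None

    def __post_init__(self):
        if self.unit not in ("counts", "FPKM", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix has negative entries")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("gene lengths must be positive and complete")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def _check_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.Series:
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for every gene")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        logger.warning("all-zero count columns: %s", zero)
    return lengths


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """FPKM_g = count_g * 1e9 / (length_g * column total)."""
    lengths = _check_counts(counts, lengths)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = counts * 1e9
        fpkm = fpkm.div(lengths, axis=0).div(totals, axis=1)
    fpkm = fpkm.fillna(0.0)
    return ExpressionMatrix(fpkm, "FPKM", lengths)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """TPM_g = rate_g * 1e6 / sum(rates), with rate_g = count_g / length_g."""
    lengths = _check_counts(counts, lengths)
    rates = counts.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = rates.mul(1e6).div(denom, axis=1)
    tpm = tpm.fillna(0.0)
    return ExpressionMatrix(tpm, "TPM", lengths)


def filter_expressed(
    matrix: ExpressionMatrix, threshold: float = 20.0
) -> list[str]:
    """Genes whose maximum abundance over samples is >= threshold (inclusive)."""
    if matrix.unit == "counts":
        raise ValueError("expression filter needs FPKM or TPM, not raw counts")
    keep = matrix.values.max(axis=1) >= threshold
    return sorted(matrix.values.index[keep])


def group_by_level(
    matrix: ExpressionMatrix, genes: Iterable[str] | None = None
) -> dict[str, str]:
    """Expression-level groups: C if max < 20, B if < 300, A otherwise."""
    if matrix.unit != "FPKM":
        raise ValueError("expression-level groups are defined on FPKM")
    sub = matrix.values if genes is None else matrix.values.loc[list(genes)]
    maxima = sub.max(axis=1)
    out: dict[str, str] = {}
    for gene, m in maxima.items():
        out[gene] = "C" if m < 20 else ("B" if m < 300 else "A")
    return out


def _tissue_samples(design: pd.DataFrame, tissue: str) -> list[str]:
    return design.loc[design.tissue == tissue, "sample_id"].tolist()


def classify_dominance(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    tissues: tuple[str, str] = ("flesh", "peel"),
) -> dict[str, str]:
    """Tissue dominance from summed abundances: ratio > 5 -> first tissue,
    < 0.2 -> second tissue, otherwise none (strict inequalities)."""
    first, second = tissues
    cols_1 = [s for s in _tissue_samples(design, first) if s in matrix.samples]
    cols_2 = [s for s in _tissue_samples(design, second) if s in matrix.samples]
    if not cols_1 or not cols_2:
        raise ValueError(f"both tissues {tissues} must be present in the design")
    sum_1 = matrix.values[cols_1].sum(axis=1)
    sum_2 = matrix.values[cols_2].sum(axis=1)
    out: dict[str, str] = {}
    for gene in matrix.genes:
        a, b = sum_1[gene], sum_2[gene]
        if b == 0:
            out[gene] = first if a > 0 else "none"
        else:
            r = a / b
            out[gene] = first if r > 5 else (second if r < 0.2 else "none")
    return out


def classify_ripening_correlation(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    early_stages: Sequence[int] = (1, 2, 3),
    late_stages: Sequence[int] = (4, 5, 6),
) -> dict[str, dict[str, str]]:
    """Per-tissue ripening correlation from late/early stage-sum ratios.

    Ratio > 2 -> positive, < 0.5 -> negative, otherwise none; a zero early
    sum with a positive late sum is positive.  Returns
    ``{gene: {tissue: label}}``.
    """
    tissues = sorted(design.tissue.unique())
    out: dict[str, dict[str, str]] = {g: {} for g in matrix.genes}
    for tissue in tissues:
        sub = design[design.tissue == tissue]
        early_cols: list[str] = []
        late_cols: list[str] = []
        for stage_set, cols in ((early_stages, early_cols), (late_stages, late_cols)):
            for stage in stage_set:
                picked = sub.loc[sub.stage == stage, "sample_id"]
                picked = [s for s in picked if s in matrix.samples]
                if not picked:
                    raise ValueError(
                        f"no samples for tissue {tissue!r} stage {stage}"
                    )
                cols.extend(picked)
        early_sum = matrix.values[early_cols].sum(axis=1)
        late_sum = matrix.values[late_cols].sum(axis=1)
        for gene in matrix.genes:
            e, l = early_sum[gene], late_sum[gene]
            if e == 0:
                label = "positive" if l > 0 else "none"
            else:
                r = l / e
                label = "positive" if r > 2 else ("negative" if r < 0.5 else "none")
            out[gene][tissue] = label
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix | pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    comparison_id: str = "case/control",
    pseudocount: float = 1.0,
    test: str = "none",
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential-expression calls for one comparison.

    log2fc = log2((mean_case + pseudocount) / (mean_control + pseudocount)).
    With ``test="welch"`` (needs >= 2 replicates per side) a Welch t-test on
    log2(x + pseudocount) is BH-adjusted across genes, and significance
    requires |log2fc| >= threshold AND adjusted p < alpha; with
    ``test="none"`` the fold-change rule alone decides.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    if not case_samples or not control_samples:
        raise ValueError("both sides of a comparison need at least one sample")
    if test not in ("none", "welch"):
        raise ValueError(f"unknown test {test!r}")
    case = values[case_samples]
    control = values[control_samples]
    log2fc = np.log2(
        (case.mean(axis=1) + pseudocount) / (control.mean(axis=1) + pseudocount)
    )
    if test == "welch":
        if len(case_samples) < 2 or len(control_samples) < 2:
            raise ValueError("Welch test needs >= 2 replicates per side")
        logc = np.log2(case + pseudocount)
        logk = np.log2(control + pseudocount)
        p = stats.ttest_ind(logc, logk, axis=1, equal_var=False).pvalue
        p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties
        p_adj = bh_adjust(p)
        significant = (np.abs(log2fc) >= lfc_threshold) & (p_adj < alpha)
    else:
        p = np.full(len(values), np.nan)
        p_adj = np.full(len(values), np.nan)
        significant = np.abs(log2fc) >= lfc_threshold
    return pd.DataFrame(
        {
            "comparison_id": comparison_id,
            "gene": values.index,
            "log2fc": log2fc.to_numpy(),
            "p": p,
            "p_adjust": p_adj,
            "significant": np.asarray(significant, dtype=bool),
            "direction": np.where(log2fc.to_numpy() > 0, "up", "down"),
        }
    ).set_index("gene", drop=False)


def intersect_screen(
    deg_tables: Mapping[str, pd.DataFrame],
    groups: Mapping[str, Sequence[str]],
) -> tuple[list[str], pd.DataFrame]:
    """Genes differentially regulated in every comparison group.

    A gene is "key" iff it is significant (either direction) in at least one
    comparison of every group.  Returns the sorted key-gene list and a table
    of per-comparison directions ("" where not significant) for those genes.
    """
    if not groups:
        raise ValueError("no comparison groups supplied")
    for name, comps in groups.items():
        if not comps:
            raise ValueError(f"comparison group {name!r} is empty")
        for c in comps:
            if c not in deg_tables:
                raise ValueError(f"comparison {c!r} has no DEG table")
    all_comparisons = [c for comps in groups.values() for c in comps]
    sig_sets = {
        c: set(t.loc[t.significant, "gene"]) for c, t in deg_tables.items()
    }
    key_genes = None
    for comps in groups.values():
        group_hits: set[str] = set()
        for c in comps:
            group_hits |= sig_sets[c]
        key_genes = group_hits if key_genes is None else key_genes & group_hits
    key_genes = sorted(key_genes or ())
    rows = {}
    for gene in key_genes:
        rows[gene] = {
            c: (
                deg_tables[c].loc[gene, "direction"]
                if gene in sig_sets[c] else ""
            )
            for c in all_comparisons
        }
    directions = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    directions = directions.reindex(columns=all_comparisons)
    directions.index.name = "gene"
    return key_genes, directions


def delta_delta_ct(
    ct_target: float,
    ct_reference: float,
    calibrator_ct_target: float,
    calibrator_ct_reference: float,
) -> float:
    """Relative expression by the 2^-ddCT method (reference-gene normalized,
    calibrator-sample relative)."""
    ddct = (ct_target - ct_reference) - (
        calibrator_ct_target - calibrator_ct_reference
    )
    return 2.0 ** (-ddct)


def spearman_coexpression(
    matrix: ExpressionMatrix | pd.DataFrame,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Gene x gene Spearman rank correlation (average ranks for ties).

    Constant genes yield an NA row/column; the diagonal is exactly 1 for
    non-constant genes.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    sub = values if genes is None else values.loc[list(genes)]
    if sub.shape[1] < 3:
        raise ValueError("Spearman co-expression needs at least 3 samples")
    corr = sub.T.corr(method="spearman")
    nonconst = sub.std(axis=1) > 0
    for gene in sub.index[nonconst]:
        corr.loc[gene, gene] = 1.0
    return corr


# --------------------------------------------------------------------------
# the three-dataset screen

@dataclass(frozen=True)
class Comparison:
    """One riper-vs-less-ripe comparison within a dataset, selected by
    matching design columns (``None`` matches anything)."""

    id: str
    dataset: str
    case: Mapping[str, object]
    control: Mapping[str, object]


def _select_samples(design: pd.DataFrame, criteria: Mapping[str, object]) -> list[str]:
    mask = pd.Series(True, index=design.index)
    for col, value in criteria.items():
        mask &= design[col] == value
    return design.loc[mask, "sample_id"].tolist()


def standard_comparisons() -> list[Comparison]:
    """The ripening comparisons of the intersection screen: stage 6 vs 5 in
    flesh and peel; ethephon vs control at days 4 and 6 in flesh and
    receptacle; 100% vs 60% ripeness in pollinated and parthenocarpic fruit,
    flesh and receptacle."""
    comps: list[Comparison] = [
        Comparison("F6/F5", "stages",
                   {"tissue": "flesh", "stage": 6}, {"tissue": "flesh", "stage": 5}),
        Comparison("P6/P5", "stages",
                   {"tissue": "peel", "stage": 6}, {"tissue": "peel", "stage": 5}),
    ]
    for day in (4, 6):
        for tissue, code in (("flesh", "F"), ("receptacle", "R")):
            comps.append(Comparison(
                f"E{day}{code}/W{day}{code}", "ethephon",
                {"tissue": tissue, "day": day, "treatment": "ethephon"},
                {"tissue": tissue, "day": day, "treatment": "control"},
            ))
    for treatment, code in (("pollinated", "Pol"), ("parthenocarpic", "Par")):
        for tissue, tcode in (("flesh", "F"), ("receptacle", "R")):
            comps.append(Comparison(
                f"{code}_100/{code}_60_{tcode}", "pollination",
                {"tissue": tissue, "stage": 100, "treatment": treatment},
                {"tissue": tissue, "stage": 60, "treatment": treatment},
            ))
    return comps


def standard_groups(comparisons: Sequence[Comparison]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for c in comparisons:
        groups.setdefault(c.dataset, []).append(c.id)
    return groups


@dataclass
class ScreenReport:
    """Per-gene classification labels and the key-gene intersection."""

    table: pd.DataFrame
    key_genes: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        t = self.table
        out: dict[str, object] = {"n_genes": int(len(t)), "key_genes": self.key_genes}
        for col in ("subfamily", "group", "dominance"):
            if col in t.columns:
                out[f"{col}_counts"] = (
                    t[col].value_counts().sort_index().to_dict()
                )
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_screen(
    datasets: Mapping[str, tuple[ExpressionMatrix, pd.DataFrame]],
    comparisons: Sequence[Comparison] | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    family_genes: Iterable[str] | None = None,
    subfamilies: Mapping[str, str] | None = None,
    threshold: float = 20.0,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> ScreenReport:
    """Run the full three-dataset screen.

    Each dataset is (abundance matrix, sample design).  Per dataset the
    ``>= threshold`` expression filter is applied, fold-change-only DEG
    calls are made for its comparisons, and the key-gene set is the
    intersection across comparison groups.  Dominance, ripening correlation
    and expression-level groups are computed on the "stages" dataset.
    ``family_genes`` restricts the report (not the normalization) to the gene
    family of interest.
    """
    if comparisons is None:
        comparisons = standard_comparisons()
    if groups is None:
        groups = standard_groups(comparisons)
    deg_tables: dict[str, pd.DataFrame] = {}
    expressed: dict[str, list[str]] = {}
    for name, (matrix, design) in datasets.items():
        expressed[name] = filter_expressed(matrix, threshold)
    for comp in comparisons:
        if comp.dataset not in datasets:
            raise ValueError(f"comparison {comp.id!r} needs dataset {comp.dataset!r}")
        matrix, design = datasets[comp.dataset]
        case = _select_samples(design, comp.case)
        control = _select_samples(design, comp.control)
        sub = ExpressionMatrix(
            matrix.values.loc[expressed[comp.dataset]], matrix.unit
        )
        table = call_degs(
            sub, case, control, comparison_id=comp.id,
            pseudocount=pseudocount, test="none", lfc_threshold=lfc_threshold,
        )
        deg_tables[comp.id] = table
    key_genes, directions = intersect_screen(deg_tables, groups)

    if family_genes is None:
        report_genes = sorted(
            set().union(*(set(m.values.index) for m, _ in datasets.values()))
        )
    else:
        report_genes = sorted(family_genes)
    table = pd.DataFrame({"gene": report_genes}).set_index("gene", drop=False)
    if subfamilies:
        table["subfamily"] = [subfamilies.get(g, "") for g in report_genes]

    if "stages" in datasets:
        matrix, design = datasets["stages"]
        stage_expressed = set(expressed["stages"])
        if matrix.unit == "FPKM":
            level = group_by_level(matrix)
            table["group"] = [level.get(g, "") for g in report_genes]
        dom = classify_dominance(matrix, design)
        corr = classify_ripening_correlation(matrix, design)
        table["dominance"] = [
            dom.get(g, "none") if g in stage_expressed else "none"
            for g in report_genes
        ]
        tissues = sorted(design.tissue.unique())
        for tissue in tissues:
            table[f"correlation_{tissue}"] = [
                corr[g][tissue]
                if g in stage_expressed and g in corr else "none"
                for g in report_genes
            ]
    for comp in comparisons:
        t = deg_tables[comp.id]
        sig = t.loc[t.significant]
        col = []
        for g in report_genes:
            col.append(sig.loc[g, "direction"] if g in sig.index else "")
        table[f"de_{comp.id}"] = col
    key_in_report = [g for g in key_genes if g in set(report_genes)]
    table["is_key"] = table["gene"].isin(key_in_report)
    return ScreenReport(table.reset_index(drop=True), key_in_report)
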