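"""Normalization, threshold classifications, DEGs and the intersection screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from erfminer.expression import (
    ExpressionMatrix,
    bh_adjust,
    call_degs,
    classify_dominance,
    classify_ripening_correlation,
    compute_fpkm,
    compute_tpm,
    delta_delta_ct,
    filter_expressed,
    group_by_level,
    intersect_screen,
    run_screen,
    spearman_coexpression,
)

from _oracles import oracle_bh, oracle_spearman


def _matrix(values, unit="FPKM", samples=None, genes=None):
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=genes or [f"g{i}" for i in range(len(values))],
        columns=samples,
    )
    return ExpressionMatrix(df, unit)


def _design(samples, tissues, stages):
    return pd.DataFrame({
        "sample_id": samples, "dataset": "stages", "tissue": tissues,
        "stage": stages, "treatment": "none", "day": None,
        "replicate": 1,
    })


class TestNormalization:
    def test_single_gene_tpm_is_one_million(self):
        counts = pd.DataFrame({"s1": [17]}, index=["g1"])
        tpm = compute_tpm(counts, pd.Series({"g1": 500}))
        assert tpm.values.loc["g1", "s1"] == pytest.approx(1e6)

    def test_hand_computed_tpm(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, pd.Series({"g1": 1000, "g2": 2000}))
        assert tpm.values["s"].tolist() == pytest.approx(
            [666666.6667, 333333.3333], rel=1e-6
        )

    def test_equal_counts_and_lengths_split_evenly(self):
        n = 8
        counts = pd.DataFrame({"s": [5] * n})
        tpm = compute_tpm(counts, pd.Series([700] * n))
        assert tpm.values["s"].tolist() == pytest.approx([1e6 / n] * n)

    def test_fpkm_definition(self):
        counts = pd.DataFrame({"s": [100, 300]}, index=["g1", "g2"])
        fpkm = compute_fpkm(counts, pd.Series({"g1": 2000, "g2": 1000}))
        total = 400
        assert fpkm.values.loc["g1", "s"] == pytest.approx(
            100 * 1e9 / (2000 * total)
        )

    def test_tpm_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 2000, size=(50, 6)))
        tpm = compute_tpm(counts, pd.Series(rng.integers(300, 4000, size=50)))
        sums = tpm.values.sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_fpkm_and_tpm_rank_identically_within_sample(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 2000, size=(40, 4)))
        lengths = pd.Series(rng.integers(300, 4000, size=40))
        f = compute_fpkm(counts, lengths).values
        t = compute_tpm(counts, lengths).values
        for col in f.columns:
            assert (f[col].rank() == t[col].rank()).all()

    def test_all_zero_column_yields_zeros(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]})
        tpm = compute_tpm(counts, pd.Series([1000, 1000]))
        assert (tpm.values["s1"] == 0).all()


class TestThresholds:
    def test_filter_is_inclusive_at_twenty(self):
        m = _matrix([[20.0], [19.99], [0.0]])
        assert filter_expressed(m) == ["g0"]

    def test_single_high_sample_suffices(self):
        m = _matrix([[25.0, 0.0, 0.0]])
        assert filter_expressed(m) == ["g0"]

    def test_counts_unit_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(_matrix([[5.0]], unit="counts"))

    @pytest.mark.parametrize(
        "maximum, group",
        [(500.0, "A"), (300.0, "A"), (299.99, "B"), (100.0, "B"),
         (20.0, "B"), (19.99, "C"), (10.0, "C")],
    )
    def test_level_groups(self, maximum, group):
        m = _matrix([[maximum]])
        assert group_by_level(m)["g0"] == group

    def test_groups_need_fpkm(self):
        with pytest.raises(ValueError):
            group_by_level(_matrix([[10.0]], unit="TPM"))


class TestDominance:
    SAMPLES = ["F1", "F2", "P1", "P2"]
    TISSUES = ["flesh", "flesh", "peel", "peel"]

    def _classify(self, flesh, peel):
        m = _matrix(
            [[flesh / 2, flesh / 2, peel / 2, peel / 2]],
            samples=self.SAMPLES,
        )
        d = _design(self.SAMPLES, self.TISSUES, [1, 2, 1, 2])
        return classify_dominance(m, d)["g0"]

    @pytest.mark.parametrize(
        "flesh, peel, label",
        [
            (120.0, 20.0, "flesh"),   # ratio 6 > 5
            (10.0, 100.0, "peel"),    # ratio 0.1 < 0.2
            (100.0, 20.0, "none"),    # ratio exactly 5: strict
            (20.0, 100.0, "none"),    # ratio exactly 0.2: strict
            (50.0, 0.0, "flesh"),     # infinite ratio
            (0.0, 0.0, "none"),
        ],
    )
    def test_ratio_rules(self, flesh, peel, label):
        assert self._classify(flesh, peel) == label

    def test_antisymmetry_under_tissue_swap(self):
        m = _matrix([[60.0, 60.0, 10.0, 10.0], [5.0, 5.0, 60.0, 60.0],
                     [30.0, 30.0, 30.0, 30.0]], samples=self.SAMPLES)
        d = _design(self.SAMPLES, self.TISSUES, [1, 2, 1, 2])
        swapped = d.assign(
            tissue=d.tissue.map({"flesh": "peel", "peel": "flesh"})
        )
        fwd = classify_dominance(m, d)
        rev = classify_dominance(m, swapped)
        flip = {"flesh": "peel", "peel": "flesh", "none": "none"}
        assert rev == {g: flip[v] for g, v in fwd.items()}

    def test_missing_tissue_is_error(self):
        m = _matrix([[1.0, 2.0]], samples=["F1", "F2"])
        d = _design(["F1", "F2"], ["flesh", "flesh"], [1, 2])
        with pytest.raises(ValueError):
            classify_dominance(m, d)


class TestRipeningCorrelation:
    def _one_tissue(self, stage_values):
        samples = [f"F{s}" for s in range(1, 7)]
        m = _matrix([stage_values], samples=samples)
        d = _design(samples, ["flesh"] * 6, list(range(1, 7)))
        return classify_ripening_correlation(m, d)["g0"]["flesh"]

    @pytest.mark.parametrize(
        "values, label",
        [
            ([100 / 3] * 3 + [100.0] * 3, "positive"),   # ratio 3 > 2
            ([100 / 3] * 3 + [40 / 3] * 3, "negative"),  # ratio 0.4 < 0.5
            ([10.0] * 6, "none"),                        # ratio 1
            ([25.0] * 3 + [50.0] * 3, "none"),           # exactly 2: strict
            ([50.0] * 3 + [25.0] * 3, "none"),           # exactly 0.5: strict
            ([0.0] * 3 + [30.0] * 3, "positive"),        # zero denominator
        ],
    )
    def test_ratio_rules(self, values, label):
        assert self._one_tissue(values) == label

    def test_scale_invariance(self):
        base = [10.0, 12.0, 8.0, 40.0, 45.0, 50.0]
        assert self._one_tissue(base) == \
            self._one_tissue([7.5 * v for v in base])

    def test_missing_stage_is_error(self):
        samples = ["F1", "F2"]
        m = _matrix([[1.0, 2.0]], samples=samples)
        d = _design(samples, ["flesh"] * 2, [1, 2])
        with pytest.raises(ValueError):
            classify_ripening_correlation(m, d)


class TestCallDegs:
    def test_identical_sides_not_significant(self):
        m = _matrix([[5.0, 5.0, 5.0, 5.0]], samples=list("abcd"))
        t = call_degs(m, ["a", "b"], ["c", "d"])
        assert t.log2fc.iloc[0] == 0.0
        assert not t.significant.iloc[0]

    def test_pseudocount_arithmetic(self):
        m = _matrix([[63.0, 0.0]], samples=["case", "ctrl"])
        t = call_degs(m, ["case"], ["ctrl"])
        assert t.log2fc.iloc[0] == pytest.approx(6.0)
        assert t.significant.iloc[0] and t.direction.iloc[0] == "up"

    def test_lfc_boundary_is_inclusive(self):
        # means chosen so (mean+1)/(mean+1) gives exactly log2fc = 1 and
        # just below
        m = _matrix(
            [[19.0, 9.0], [18.9, 9.0]], samples=["case", "ctrl"]
        )
        t = call_degs(m, ["case"], ["ctrl"])
        assert t.significant.tolist() == [True, False]

    def test_planted_fourfold_with_welch(self):
        rng = np.random.default_rng(5)
        base = rng.normal(100, 1, size=(30, 3))
        case = np.vstack([base[:5] * 4 + 3, base[5:] + 3])[:, :3]
        values = np.hstack([case, base[:, :3] + 3])
        m = _matrix(values, samples=["c1", "c2", "c3", "k1", "k2", "k3"])
        t = call_degs(m, ["c1", "c2", "c3"], ["k1", "k2", "k3"], test="welch",
                      pseudocount=1.0)
        assert t.significant.iloc[:5].all()
        assert not t.significant.iloc[5:].any()
        assert t.log2fc.iloc[0] == pytest.approx(2.0, abs=0.1)

    def test_welch_needs_two_replicates(self):
        m = _matrix([[1.0, 2.0]], samples=["a", "b"])
        with pytest.raises(ValueError):
            call_degs(m, ["a"], ["b"], test="welch")

    def test_empty_side_is_error(self):
        m = _matrix([[1.0, 2.0]], samples=["a", "b"])
        with pytest.raises(ValueError):
            call_degs(m, [], ["a"])


class TestBHAdjust:
    def test_small_example_matches_definition(self):
        got = bh_adjust([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.1] * 5) == pytest.approx([0.1] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        ps=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=60,
        )
    )
    def test_matches_oracle_and_dominates_raw(self, ps):
        got = bh_adjust(ps)
        assert np.allclose(got, oracle_bh(ps), atol=1e-12)
        assert (got >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(got[order]) >= -1e-12).all()


class TestIntersectScreen:
    @staticmethod
    def _table(comp, sig_genes, all_genes=("g1", "g2", "g3")):
        return pd.DataFrame({
            "comparison_id": comp, "gene": all_genes,
            "log2fc": [2.0 if g in sig_genes else 0.0 for g in all_genes],
            "significant": [g in sig_genes for g in all_genes],
            "direction": ["up"] * len(all_genes),
        }).set_index("gene", drop=False)

    def test_gene_needs_every_group(self):
        tables = {
            "c1": self._table("c1", {"g1", "g2"}),
            "c2": self._table("c2", {"g1"}),
            "c3": self._table("c3", {"g1", "g3"}),
        }
        groups = {"A": ["c1"], "B": ["c2"], "C": ["c3"]}
        keys, directions = intersect_screen(tables, groups)
        assert keys == ["g1"]
        assert directions.loc["g1"].tolist() == ["up", "up", "up"]

    def test_one_comparison_per_group_suffices(self):
        tables = {
            "c1": self._table("c1", set()),
            "c2": self._table("c2", {"g2"}),
            "c3": self._table("c3", {"g2"}),
        }
        groups = {"A": ["c1", "c2"], "B": ["c3"]}
        keys, _ = intersect_screen(tables, groups)
        assert keys == ["g2"]

    def test_missing_group_excludes_gene(self):
        tables = {
            "c1": self._table("c1", {"g1"}),
            "c2": self._table("c2", set()),
        }
        keys, _ = intersect_screen(tables, {"A": ["c1"], "B": ["c2"]})
        assert keys == []

    def test_empty_groups_are_errors(self):
        with pytest.raises(ValueError):
            intersect_screen({}, {})
        with pytest.raises(ValueError):
            intersect_screen({"c1": self._table("c1", set())}, {"A": []})


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20.0, 18.0, 22.0, 20.0), 1.0),   # ddCT = 0
            ((19.0, 18.0, 20.0, 18.0), 2.0),   # one cycle lower
            ((24.0, 20.0, 26.0, 20.0), 4.0),   # ddCT = -2
        ],
    )
    def test_hand_examples(self, cts, expected):
        assert delta_delta_ct(*cts) == pytest.approx(expected)


class TestSpearman:
    def test_self_correlation_is_one(self):
        m = _matrix([[1.0, 5.0, 2.0, 8.0]], samples=list("abcd"))
        assert spearman_coexpression(m).loc["g0", "g0"] == 1.0

    def test_reversed_profiles(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
                    samples=list("abcd"))
        assert spearman_coexpression(m).loc["g0", "g1"] == pytest.approx(-1.0)

    def test_constant_gene_gives_na(self):
        m = _matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], samples=list("abc"))
        corr = spearman_coexpression(m)
        assert math.isnan(corr.loc["g1", "g0"])

    def test_needs_three_samples(self):
        m = _matrix([[1.0, 2.0]], samples=["a", "b"])
        with pytest.raises(ValueError):
            spearman_coexpression(m)

    @given(
        x=st.lists(st.integers(0, 9), min_size=5, max_size=5),
        y=st.lists(st.integers(0, 9), min_size=5, max_size=5),
    )
    def test_matches_rank_oracle(self, x, y):
        if len(set(x)) == 1 or len(set(y)) == 1:
            return
        m = _matrix([x, y], samples=list("abcde"))
        got = spearman_coexpression(m).loc["g0", "g1"]
        assert got == pytest.approx(oracle_spearman(x, y), abs=1e-12)


class TestScreenEndToEnd:
    def test_key_genes_recovered_exactly(self, expression_fixture):
        ex = expression_fixture
        report = run_screen(
            ex.abundances(), family_genes=ex.family_genes,
            subfamilies=ex.subfamilies,
        )
        assert report.key_genes == ex.truth["key_genes"]

    def test_dominance_and_correlation_recovered(self, expression_fixture):
        ex = expression_fixture
        report = run_screen(
            ex.abundances(), family_genes=ex.family_genes,
            subfamilies=ex.subfamilies,
        )
        t = report.table.set_index("gene")
        for g in ex.family_genes:
            assert t.loc[g, "dominance"] == ex.truth["dominance"][g]
            for tissue in ("flesh", "peel"):
                assert t.loc[g, f"correlation_{tissue}"] == \
                    ex.truth["correlation"][g][tissue]

    def test_summary_counts(self, expression_fixture):
        ex = expression_fixture
        report = run_screen(
            ex.abundances(), family_genes=ex.family_genes,
            subfamilies=ex.subfamilies,
        )
        summary = report.summary()
        assert summary["key_genes"] == ex.truth["key_genes"]
        assert summary["dominance_counts"].get("flesh", 0) == 3
        assert summary["dominance_counts"].get("peel", 0) == 9
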