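"""Bulk fold-change, DE-filter, Venn and synergy-statistic tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costim.bulk import (
    AnalysisError,
    FoldChangeTable,
    benjamini_hochberg,
    call_synergy,
    compute_fold_changes,
    filter_de,
    normalize_cpm,
    paired_t_against_zero,
    run_bulk_pipeline,
    venn_partition,
)

from conftest import make_bulk


def fct_from_rows(rows) -> FoldChangeTable:
    """rows: (gene, condition, median_fc, total_reads, fdr)."""
    table = pd.DataFrame(rows, columns=["gene", "condition", "median_fc", "total_reads", "fdr"])
    table["log2_median_fc"] = np.log2(table["median_fc"])
    table["mean_norm_control"] = 100.0
    table["p_value"] = table["fdr"]
    return FoldChangeTable(per_patient_log2fc={}, table=table)


class TestNormalizeCPM:
    def test_single_sample_values(self):
        exp = make_bulk({"P1_control": [1, 1, 2], "P1_combo": [1, 1, 2]})
        cpm = normalize_cpm(exp)
        assert list(cpm["P1_control"]) == [250000.0, 250000.0, 500000.0]

    def test_column_already_at_one_million_unchanged(self):
        exp = make_bulk({"P1_control": [250000, 250000, 500000], "P1_combo": [1, 1, 2]})
        cpm = normalize_cpm(exp)
        assert np.array_equal(cpm["P1_control"], exp.counts["P1_control"])

    def test_all_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = {f"P{p}_{c}": rng.integers(0, 500, 50)
                  for p in (1, 2) for c in ("control", "IL17A", "TNF", "combo")}
        cpm = normalize_cpm(make_bulk(counts))
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_sample_error_names_sample(self):
        exp = make_bulk({"P1_control": [1, 1, 2], "P1_combo": [0, 0, 0]})
        with pytest.raises(AnalysisError, match="P1_combo"):
            normalize_cpm(exp)

    def test_depth_invariance_of_fold_changes(self):
        """Multiplying one library by a constant leaves all FCs unchanged."""
        exp = make_bulk({
            "P1_control": [10, 20, 70], "P1_IL17A": [20, 20, 60],
            "P1_TNF": [10, 30, 60], "P1_combo": [40, 30, 30],
        })
        scaled = exp.counts.copy()
        scaled["P1_combo"] *= 7
        exp2 = make_bulk({s: list(scaled[s]) for s in scaled.columns})
        fc_cols = ["gene", "condition", "median_fc", "log2_median_fc", "mean_norm_control"]
        a = compute_fold_changes(exp, pseudocount=0.0).table[fc_cols]
        b = compute_fold_changes(exp2, pseudocount=0.0).table[fc_cols]
        pd.testing.assert_frame_equal(a, b)


class TestFoldChanges:
    def test_forced_arithmetic_single_patient(self):
        """CPM 100 -> 400 with pseudocount 0 gives log2FC 2, median FC 4."""
        # totals 10000 per library so CPM = 100 x count
        exp = make_bulk({
            "P1_control": [1, 9999], "P1_IL17A": [1, 9999],
            "P1_TNF": [1, 9999], "P1_combo": [4, 9996],
        })
        fct = compute_fold_changes(exp, pseudocount=0.0)
        row = fct.condition("combo").loc["g1"]
        assert fct.per_patient_log2fc["combo"].loc["g1", "P1"] == pytest.approx(2.0)
        assert row["median_fc"] == pytest.approx(4.0)
        assert row["total_reads"] == 7

    def test_treated_equals_control_gives_unit_fc(self, two_patient_bulk):
        counts = {s: [10, 20, 70] for s in two_patient_bulk.samples}
        fct = compute_fold_changes(make_bulk(counts))
        assert np.allclose(fct.table["median_fc"], 1.0)

    def test_median_over_three_patients(self):
        """Per-patient FCs (2, 4, 8) summarize to median 4."""
        counts = {}
        for p, fc in zip((1, 2, 3), (2, 4, 8)):
            counts[f"P{p}_control"] = [100, 9900]
            counts[f"P{p}_IL17A"] = [100, 9900]
            counts[f"P{p}_TNF"] = [100, 9900]
            counts[f"P{p}_combo"] = [100 * fc, 10000 - 100 * fc]
        fct = compute_fold_changes(make_bulk(counts), pseudocount=0.0)
        g1 = fct.condition("combo").loc["g1"]
        per_patient = np.exp2(fct.per_patient_log2fc["combo"].loc["g1"])
        assert list(per_patient.round(6)) == pytest.approx([2.0, 4.0, 8.0], rel=1e-3)
        assert g1["median_fc"] == pytest.approx(4.0, rel=1e-3)

    def test_incomplete_patient_skipped_and_missing_pair_errors(self):
        exp = make_bulk({
            "P1_control": [10, 90], "P1_combo": [20, 80],
            "P2_control": [10, 90],  # P2 lacks all treated arms
        })
        with pytest.raises(AnalysisError, match="IL17A"):
            compute_fold_changes(exp)


class TestDifferentialTest:
    def test_consistent_per_patient_fcs_are_significant(self):
        log2fc = pd.DataFrame([[1.0, 1.1, 0.9, 1.05, 0.95]], index=["g1"])
        result = paired_t_against_zero(log2fc)
        assert result.loc["g1", "p_value"] < 0.001

    def test_zero_fold_changes_give_p_one(self):
        log2fc = pd.DataFrame([[0.0] * 5, [1.0, 1.2, 0.8, 1.1, 0.9]], index=["g0", "g1"])
        result = paired_t_against_zero(log2fc)
        assert result.loc["g0", "p_value"] == 1.0

    def test_fewer_than_three_pairs_error(self):
        with pytest.raises(AnalysisError, match=">= 3"):
            paired_t_against_zero(pd.DataFrame([[1.0, 1.1]], index=["g1"]))

    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.001, 0.01, 0.04, 0.2), (0.004, 0.02, 0.04 * 4 / 3, 0.2)),
        ],
    )
    def test_benjamini_hochberg_hand_values(self, pvals, expected):
        assert benjamini_hochberg(np.array(pvals)) == pytest.approx(expected)


class TestFilterDE:
    # (median_fc, total_reads, fdr, in_de_set) straddling every threshold
    CASES = [
        ("reads_below", 8.0, 14, 0.01, False),
        ("all_boundary", 2.0, 15, 0.05, True),  # log2FC exactly 1.0, inclusive
        ("fdr_above", 8.0, 1000, 0.051, False),
        ("fc_below", 1.9, 1000, 0.01, False),
        ("repressed_passes", 0.25, 1000, 0.01, True),  # |log2 0.25| = 2
        ("clear_pass", 16.0, 1000, 0.001, True),
    ]

    def test_membership_matches_hand_evaluation(self):
        rows = [
            (name, cond, fc, reads, fdr)
            for cond in ("IL17A", "TNF", "combo")
            for name, fc, reads, fdr, _ in self.CASES
        ]
        de = filter_de(fct_from_rows(rows))
        expected = {name for name, _, _, _, keep in self.CASES if keep}
        for cond in ("IL17A", "TNF", "combo"):
            assert de[cond] == expected

    def test_brute_force_agreement_on_random_tables(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(200)]
        rows = [
            (g, "combo", float(np.exp2(rng.normal(0, 1.5))),
             int(rng.integers(0, 40)), float(rng.uniform(0, 0.1)))
            for g in genes
        ]
        for g in genes:  # other conditions present but out of focus
            rows.append((g, "IL17A", 1.0, 100, 1.0))
            rows.append((g, "TNF", 1.0, 100, 1.0))
        de = filter_de(fct_from_rows(rows))
        brute = {
            g for g, cond, fc, reads, fdr in rows
            if cond == "combo" and reads >= 15 and fdr <= 0.05 and abs(np.log2(fc)) >= 1.0
        }
        assert de["combo"] == brute


def brute_force_venn(a, b, ab):
    """Independent region assignment: classify each gene of the union by
    its membership triple."""
    regions = {r: set() for r in (
        "IL17A_only", "TNF_only", "combo_only", "IL17A_TNF",
        "IL17A_combo", "TNF_combo", "IL17A_TNF_combo")}
    names = {
        (True, False, False): "IL17A_only",
        (False, True, False): "TNF_only",
        (False, False, True): "combo_only",
        (True, True, False): "IL17A_TNF",
        (True, False, True): "IL17A_combo",
        (False, True, True): "TNF_combo",
        (True, True, True): "IL17A_TNF_combo",
    }
    for gene in a | b | ab:
        regions[names[(gene in a, gene in b, gene in ab)]].add(gene)
    return regions


class TestVennPartition:
    def test_hand_example(self):
        part = venn_partition({"IL17A": {"g1"}, "TNF": {"g2"}, "combo": {"g1", "g2", "g3"}})
        assert part.regions["combo_only"] == {"g3"}
        assert part.total == 3
        assert part.combo_only_percent == pytest.approx(100 / 3)

    def test_identical_sets_all_in_center(self):
        s = {"g1", "g2", "g3"}
        part = venn_partition({"IL17A": s, "TNF": s, "combo": s})
        assert part.regions["IL17A_TNF_combo"] == s
        assert part.total == 3
        assert part.combo_only_percent == 0.0

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        ab=st.sets(st.integers(0, 30)),
    )
    def test_regions_partition_union_exactly(self, a, b, ab):
        part = venn_partition({"IL17A": a, "TNF": b, "combo": ab})
        brute = brute_force_venn(a, b, ab)
        assert {k: set(v) for k, v in part.regions.items()} == brute
        union = set().union(*part.regions.values())
        assert union == a | b | ab
        assert part.total == len(union)


class TestCallSynergy:
    def _fct(self, triples):
        """triples: gene -> (fc_a, fc_b, fc_combo); all genes DE everywhere."""
        rows = []
        for gene, (fa, fb, fc) in triples.items():
            rows += [(gene, "IL17A", fa, 100, 0.01), (gene, "TNF", fb, 100, 0.01),
                     (gene, "combo", fc, 100, 0.01)]
        fct = fct_from_rows(rows)
        de = {c: set(triples) for c in ("IL17A", "TNF", "combo")}
        return fct, de

    def test_worked_examples(self):
        fct, de = self._fct({
            "strong": (1.2, 3.0, 10.0),
            "exactly_additive": (2.0, 2.0, 4.0),
            "boundary": (1.0, 1.0, 4.0),
        })
        out = call_synergy(fct, de).set_index("gene")
        assert out.loc["strong", "fc_expected"] == pytest.approx(4.2)
        assert out.loc["strong", "ratio"] == pytest.approx(10 / 4.2)
        assert bool(out.loc["strong", "synergistic"])
        assert out.loc["exactly_additive", "ratio"] == pytest.approx(1.0)
        assert not out.loc["exactly_additive", "synergistic"]
        # ratio exactly 2 is synergistic: the threshold is inclusive
        assert out.loc["boundary", "ratio"] == pytest.approx(2.0)
        assert bool(out.loc["boundary", "synergistic"])

    def test_requires_de_in_combo_and_induction(self):
        fct, de = self._fct({"g1": (1.0, 1.0, 8.0), "g2": (0.1, 0.1, 0.9)})
        de["combo"] = {"g2"}  # g1 has the ratio but fails the DE gate
        out = call_synergy(fct, de).set_index("gene")
        assert not out.loc["g1", "synergistic"]
        assert not out.loc["g2", "synergistic"]  # ratio 4.5 but not induced

    def test_sorted_by_descending_ratio(self):
        fct, de = self._fct({"a": (1, 1, 4), "b": (1, 1, 10), "c": (1, 1, 6)})
        out = call_synergy(fct, de)
        assert list(out["gene"]) == ["b", "c", "a"]

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = {f"P{p}_{c}": list(rng.integers(10, 500, 30))
                  for p in (1, 2, 3) for c in ("control", "IL17A", "TNF", "combo")}
        exp = make_bulk(counts)
        _, _, _, syn = run_bulk_pipeline(exp)

        perm = rng.permutation(30)
        shuffled_counts = exp.counts.iloc[perm]
        sample_order = list(rng.permutation(exp.samples))
        exp2 = make_bulk(
            {s: list(shuffled_counts[s]) for s in sample_order},
            genes=list(shuffled_counts.index),
        )
        _, _, _, syn2 = run_bulk_pipeline(exp2)
        merged = syn.set_index("gene").sort_index()
        merged2 = syn2.set_index("gene").sort_index()
        pd.testing.assert_frame_equal(merged, merged2)

    def test_repressed_mirror_behind_flag(self):
        fct, de = self._fct({"rep": (0.5, 0.5, 0.1)})
        off = call_synergy(fct, de).set_index("gene")
        assert not off.loc["rep", "synergistic"]
        on = call_synergy(fct, de, include_repressed=True).set_index("gene")
        # reciprocal ratio: (1/0.1) / (1/0.5 + 1/0.5) = 2.5 >= 2
        assert bool(on.loc["rep", "synergistic"])
        assert on.loc["rep", "direction"] == "repressed"
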