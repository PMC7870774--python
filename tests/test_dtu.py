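"""DTU cascade: filters, synchronization, ANOVA, gene calling, non-DEG^DTU-."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txcompare.data_model import IsoformTable, compute_isoform_percentages
from txcompare.dtu import (
    DTUCallSet,
    anova_isoform_usage,
    call_dtu_genes,
    derive_nondeg_dtu_minus,
    filter_detection,
    filter_low_expression,
    filter_similar_usage,
    run_dtu,
    run_filter_cascade,
    synchronize_and_prune,
)
from conftest import make_sample_table


def _iso_from_usage(usage_rows: dict, parents: dict, samples) -> IsoformTable:
    """Build a table whose usage percentages equal ``usage_rows`` by scaling
    counts; gene totals are constant at 1000 per sample."""
    counts = pd.DataFrame(usage_rows, index=samples.sample_ids).T * 10.0
    parent = pd.Series(parents)
    return compute_isoform_percentages(IsoformTable(counts, parent))


class TestLowExpressionFilter:
    def test_below_floor_in_one_group_removed_and_boundary_retained(self):
        samples = make_sample_table(3, 3)
        # library ~1e6 per sample via a big ballast isoform
        rows = {
            "ballast": [1e6] * 6,
            "low_test": [3000.0] * 3 + [0.5] * 3,   # test CPM ~0.5 -> removed
            "at_floor": [0.0] * 6,                   # filled below: CPM exactly 1
            "high": [30000.0] * 6,
        }
        counts = pd.DataFrame(rows, index=samples.sample_ids).T
        others = counts.drop(index="at_floor").sum(axis=0)
        # c / (others + c) * 1e6 == 1  <=>  c = others / (1e6 - 1)
        counts.loc["at_floor"] = others / (1e6 - 1)
        parent = pd.Series({k: "G" + k for k in counts.index})
        iso = compute_isoform_percentages(IsoformTable(counts, parent))
        removed, _ = filter_low_expression(iso, samples, cpm_floor=1.0)
        assert "low_test" in removed
        assert "at_floor" not in removed  # strict <
        assert "high" not in removed

    def test_hand_enumerated_cpm_fixture(self):
        samples = make_sample_table(2, 2)
        # one sample column sums to exactly 1e6 -> CPM == count
        ids = [f"I{i}" for i in range(10)]
        base = np.array([0.2, 0.5, 0.9, 1.0, 1.1, 2.0, 10.0, 100.0, 5000.0, 1e6 - 5115.7])
        counts = pd.DataFrame({s: base for s in samples.sample_ids}, index=ids)
        iso = compute_isoform_percentages(
            IsoformTable(counts, pd.Series({i: f"G{i}" for i in ids}))
        )
        removed, _ = filter_low_expression(iso, samples, cpm_floor=1.0)
        assert removed == {"I0", "I1", "I2"}  # CPM 0.2, 0.5, 0.9 < 1


class TestSimilarUsageFilter:
    def test_worked_dominant_drop_is_retained(self):
        # dominant isoform at 52% in the reference collapsing to 2% in the
        # test model must survive the similar-usage filter (delta = 50)
        samples = make_sample_table(3, 3)
        iso = _iso_from_usage(
            {"T1": [52, 52, 52, 2, 2, 2], "T2": [48, 48, 48, 98, 98, 98]},
            {"T1": "G1", "T2": "G1"},
            samples,
        )
        removed, _ = filter_similar_usage(iso, samples)
        assert "T1" not in removed and "T2" not in removed

    @pytest.mark.parametrize(
        "test_usage,expected_removed",
        [(40.0, True), (39.5, False)],  # delta exactly 10 removed; 10.5 retained
    )
    def test_inclusive_boundary(self, test_usage, expected_removed):
        samples = make_sample_table(3, 3)
        iso = _iso_from_usage(
            {
                "T1": [50, 50, 50, test_usage, test_usage, test_usage],
                "T2": [50, 50, 50, 100 - test_usage, 100 - test_usage, 100 - test_usage],
            },
            {"T1": "G1", "T2": "G1"},
            samples,
        )
        removed, _ = filter_similar_usage(iso, samples, delta_pct=10.0)
        assert ("T1" in removed) is expected_removed


class TestDetectionFilter:
    def _iso(self, control_zero: int, test_zero: int, n_control=24, n_test=3):
        samples = make_sample_table(n_control, n_test)
        vals = []
        for i in range(n_control):
            vals.append(0.0 if i < control_zero else 500.0)
        for i in range(n_test):
            vals.append(0.0 if i < test_zero else 500.0)
        counts = pd.DataFrame(
            {"A": vals, "B": [500.0] * (n_control + n_test)},
            index=samples.sample_ids,
        ).T
        iso = compute_isoform_percentages(
            IsoformTable(counts, pd.Series({"A": "G1", "B": "G1"}))
        )
        return iso, samples

    def test_over_twenty_percent_missing_discarded(self):
        iso, samples = self._iso(control_zero=5, test_zero=0)  # 5/24 = 20.8%
        removed, _ = filter_detection(iso, samples)
        assert "A" in removed

    def test_under_threshold_retained(self):
        iso, samples = self._iso(control_zero=4, test_zero=0)  # 4/24 = 16.7%
        removed, _ = filter_detection(iso, samples)
        assert "A" not in removed

    def test_small_group_requires_full_detection(self):
        iso, samples = self._iso(control_zero=0, test_zero=1)  # 1/3 with n<5
        removed, reasons = filter_detection(iso, samples)
        assert "A" in removed
        assert "all-samples" in reasons["A"]


class TestSynchronizeAndPrune:
    def test_single_survivor_gene_is_pruned(self):
        samples = make_sample_table(2, 2)
        counts = pd.DataFrame(
            {s: [60.0, 40.0, 30.0, 30.0, 40.0] for s in samples.sample_ids},
            index=["A", "B", "C", "D", "E"],
        )
        parent = pd.Series({"A": "G1", "B": "G1", "C": "G2", "D": "G2", "E": "G2"})
        iso = compute_isoform_percentages(IsoformTable(counts, parent))
        # B removed by the count view -> A pruned; E removed -> C, D kept
        final, pruned = synchronize_and_prune(iso, {"B"}, {"E"})
        assert pruned == {"A"}
        assert set(final.isoform_ids) == {"C", "D"}

    def test_cascade_fixture_matches_hand_enumeration(self, cascade_fixture):
        iso, samples, expected = cascade_fixture
        final, trace = run_filter_cascade(iso, samples)
        by_step = {name: set(removed) for name, removed, _ in trace.steps}
        for step in ("low_expression", "similar_usage", "detection", "single_isoform_prune"):
            assert by_step[step] == expected[step], step
        assert set(final.isoform_ids) == expected["survivors"]

    def test_trace_partition_and_monotonicity(self, cascade_fixture):
        iso, samples, _ = cascade_fixture
        _, trace = run_filter_cascade(iso, samples)
        removed_sets = [set(r) for _, r, _ in trace.steps]
        for i, a in enumerate(removed_sets):
            for b in removed_sets[i + 1 :]:
                assert not (a & b)
        assert trace.removed_total() | trace.survivors() == trace.initial
        survivors = [trace.survivors_after(name) for name, _, _ in trace.steps]
        for earlier, later in zip(survivors, survivors[1:]):
            assert later <= earlier

    def test_threshold_monotonicity(self, default_sim):
        iso, samples = default_sim.isoforms, default_sim.samples
        base, _ = run_filter_cascade(iso, samples, delta_pct=10.0, cpm_floor=1.0)
        stricter, _ = run_filter_cascade(iso, samples, delta_pct=20.0, cpm_floor=1.0)
        assert set(stricter.isoform_ids) <= set(base.isoform_ids)
        looser, _ = run_filter_cascade(iso, samples, delta_pct=10.0, cpm_floor=0.1)
        assert set(base.isoform_ids) <= set(looser.isoform_ids)


class TestAnova:
    def test_identical_groups_give_p_one(self):
        samples = make_sample_table(3, 3)
        iso = _iso_from_usage(
            {"T1": [50.0] * 6, "T2": [50.0] * 6}, {"T1": "G1", "T2": "G1"}, samples
        )
        p = anova_isoform_usage(iso, samples)
        assert p["T1"] == 1.0

    def test_degenerate_unequal_means_give_p_zero(self):
        samples = make_sample_table(3, 3)
        iso = _iso_from_usage(
            {"T1": [60, 60, 60, 20, 20, 20], "T2": [40, 40, 40, 80, 80, 80]},
            {"T1": "G1", "T2": "G1"},
            samples,
        )
        p = anova_isoform_usage(iso, samples)
        assert p["T1"] == 0.0

    def test_equals_pooled_t_test(self):
        samples = make_sample_table(4, 3)
        control = [50.0, 52.0, 48.0, 50.0]
        test = [20.0, 22.0, 21.0]
        iso = _iso_from_usage(
            {"T1": control + test, "T2": [100 - u for u in control + test]},
            {"T1": "G1", "T2": "G1"},
            samples,
        )
        p = anova_isoform_usage(iso, samples)
        expected = stats.ttest_ind(control, test, equal_var=True).pvalue
        assert p["T1"] == pytest.approx(expected, abs=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(22)
        samples = make_sample_table(12, 12)
        values = rng.normal(50, 5, (2000, 24)).clip(0, 100)
        counts = pd.DataFrame(values, columns=samples.sample_ids)
        counts.index = [f"I{i}" for i in range(2000)]
        other = 100.0 - counts
        other.index = [f"J{i}" for i in range(2000)]
        all_counts = pd.concat([counts, other])
        parent = pd.Series(
            {**{f"I{i}": f"G{i}" for i in range(2000)}, **{f"J{i}": f"G{i}" for i in range(2000)}}
        )
        iso = compute_isoform_percentages(IsoformTable(all_counts * 10, parent))
        p = anova_isoform_usage(iso, samples).loc[[f"I{i}" for i in range(2000)]]
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestCallDtu:
    def _callset(self, p_dominant, p_minor):
        samples = make_sample_table(3, 3)
        iso = _iso_from_usage(
            {"T1": [70, 70, 70, 65, 65, 65], "T2": [30, 30, 30, 35, 35, 35]},
            {"T1": "G1", "T2": "G1"},
            samples,
        )
        pvals = pd.Series({"T1": p_dominant, "T2": p_minor})
        return call_dtu_genes(iso, pvals, samples)

    def test_dominant_isoform_rule(self):
        assert self._callset(0.001, 0.5).dtu_genes == {"G1"}
        # significant minor isoform does not make the gene DTU
        assert self._callset(0.02, 0.001).dtu_genes == set()

    def test_dominant_switch_flagged_without_calling(self):
        samples = make_sample_table(3, 3)
        iso = _iso_from_usage(
            {"T1": [60, 60, 60, 45, 45, 45], "T2": [40, 40, 40, 55, 55, 55]},
            {"T1": "G1", "T2": "G1"},
            samples,
        )
        calls = call_dtu_genes(iso, pd.Series({"T1": 0.5, "T2": 0.5}), samples)
        assert calls.table.loc["G1", "dominant_isoform"] == "T1"
        assert bool(calls.table.loc["G1", "dominant_switched"])
        assert calls.dtu_genes == set()

    @pytest.mark.parametrize(
        "non_degs,dtu,expected",
        [
            ({"a", "b", "c"}, {"b"}, {"a", "c"}),
            ({"a", "b"}, set(), {"a", "b"}),
            ({"a", "b"}, {"a", "b", "z"}, set()),
        ],
    )
    def test_derive_nondeg_dtu_minus(self, non_degs, dtu, expected):
        table = pd.DataFrame(
            {"is_dtu": [True] * len(dtu)}, index=sorted(dtu)
        )
        table.index.name = "gene_id"
        for col in ("dominant_isoform", "control_mean_pct", "test_mean_pct", "anova_p", "dominant_switched"):
            table[col] = 0
        calls = DTUCallSet(table)
        assert derive_nondeg_dtu_minus(non_degs, calls) == expected


class TestRecovery:
    def test_truth_labelled_recall_and_fdr_single_seed(self, default_sim):
        calls, _ = run_dtu(default_sim.isoforms, default_sim.samples)
        truth = default_sim.truth
        true_dtu = set(truth.index[truth["is_dtu"]])
        called = calls.dtu_genes
        recall = len(called & true_dtu) / len(true_dtu)
        fdr = len(called - true_dtu) / max(len(called), 1)
        assert recall >= 0.8
        assert fdr <= 0.1

    def test_dtu_free_simulation_false_calls_rare(self, null_sim):
        calls, _ = run_dtu(null_sim.isoforms, null_sim.samples)
        frac = len(calls.dtu_genes) / null_sim.genes.shape[0]
        assert frac <= 0.02
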