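"""Null splits, ROC/AUC, spike-in benchmark mechanics, reference evaluation."""

import numpy as np
import pandas as pd
import pytest

import editbench as eb
from editbench._errors import DegenerateDataError, DesignError, ParameterError
from editbench.de.result import make_de_result
from tests.conftest import null_params


class TestNullSplits:
    @pytest.mark.parametrize("n,g,expected", [(6, 3, 10), (4, 2, 3), (2, 1, 1)])
    def test_unordered_partition_counts(self, n, g, expected):
        splits = eb.enumerate_null_splits([f"s{i}" for i in range(n)], g)
        assert len(splits) == expected
        seen = {frozenset((frozenset(a), frozenset(b))) for a, b in splits}
        assert len(seen) == expected  # all partitions distinct

    def test_ordered_mode_doubles_balanced_splits(self):
        ids = [f"s{i}" for i in range(6)]
        assert len(eb.enumerate_null_splits(ids, 3, ordered=True)) == 20

    def test_groups_partition_the_samples(self):
        ids = list("abcdef")
        for g1, g2 in eb.enumerate_null_splits(ids, 2):
            assert sorted(g1 + g2) == sorted(ids)

    def test_bad_group_size_raises(self):
        with pytest.raises(ParameterError):
            eb.enumerate_null_splits(list("abc"), 3)


class TestROC:
    def test_perfect_and_inverted_separation(self):
        scores = pd.Series([5.0, 4.0, 1.0, 0.5], index=list("abcd"))
        assert eb.roc_auc(scores, {"a", "b"}) == 1.0
        assert eb.roc_auc(scores, {"c", "d"}) == 0.0

    def test_matches_brute_force_pairwise_probability(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.integers(0, 8, size=40).astype(float),
                           index=[f"g{i}" for i in range(40)])
        truth = {f"g{i}" for i in range(0, 40, 3)}
        pos = [scores[g] for g in scores.index if g in truth]
        neg = [scores[g] for g in scores.index if g not in truth]
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert eb.roc_auc(scores, truth) == pytest.approx(brute, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(6)
        n_pos, n_neg = 200, 2000
        scores = pd.Series(rng.normal(size=n_pos + n_neg),
                           index=[f"g{i}" for i in range(n_pos + n_neg)])
        truth = {f"g{i}" for i in range(n_pos)}
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))  # Mann-Whitney null SE
        assert abs(eb.roc_auc(scores, truth) - 0.5) < 3 * se

    def test_all_tied_warns_and_returns_half(self):
        scores = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.warns(UserWarning):
            assert eb.roc_auc(scores, {"a"}) == 0.5


def _result_with_sets(universe, significant):
    p = np.array([1e-8 if g in significant else 0.9 for g in universe])
    return make_de_result(universe, np.ones(len(universe)), p, np.zeros(len(universe)), "glm_lrt")


class TestReferenceEvaluation:
    def test_worked_percentages_from_printed_style_counts(self):
        universe = [f"G{i}" for i in range(6000)]
        reference = set(universe[:1296])
        sig = set(universe[:105]) | set(universe[1296 : 1296 + 316])  # 421 calls, 105 inside
        ev = eb.evaluate_against_reference(_result_with_sets(universe, sig), reference)
        assert (ev.total_significant, ev.tp, ev.fp) == (421, 105, 316)
        assert ev.tp_pct == 8.1
        assert ev.fp_pct == 75.1  # 316/421

    def test_subset_of_reference_has_no_false_positives(self):
        universe = [f"G{i}" for i in range(100)]
        reference = set(universe[:50])
        ev = eb.evaluate_against_reference(_result_with_sets(universe, set(universe[:20])), reference)
        assert ev.fp == 0 and ev.fp_pct == 0.0

    def test_tp_plus_fp_equals_total(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(500)]
        for _ in range(5):
            sig = set(rng.choice(universe, size=rng.integers(1, 200), replace=False))
            ref = set(rng.choice(universe, size=120, replace=False))
            ev = eb.evaluate_against_reference(_result_with_sets(universe, sig), ref)
            assert ev.tp + ev.fp == ev.total_significant

    def test_no_calls_flagged(self):
        universe = [f"G{i}" for i in range(50)]
        ev = eb.evaluate_against_reference(_result_with_sets(universe, set()), set(universe[:10]))
        assert ev.no_calls and ev.tp_pct == 0.0 and ev.fp_pct == 0.0

    def test_errors(self):
        universe = [f"G{i}" for i in range(50)]
        res = _result_with_sets(universe, set(universe[:5]))
        with pytest.raises(DegenerateDataError):
            eb.evaluate_against_reference(res, set())
        with pytest.raises(DesignError):
            eb.evaluate_against_reference(res, {"not_a_gene"})


class TestAggregateReference:
    def test_recovers_planted_effects(self):
        """With strong planted effects the reference is close to the truth."""
        design = eb.make_design(4, 3, 3)
        effects = {f"G{i + 1:06d}": 2.0 * (1 if i % 2 else -1) for i in range(2, 102)}
        effects["HPRT1"] = -3.0
        params = eb.SimulationParams(
            n_genes=1200, libsize_logmean=np.log(3e5), edit_effects=effects, seed=61
        )
        counts, truth = eb.simulate_counts(design, params)
        ref = eb.build_aggregate_reference(counts, design, engine="glm")
        planted = set(truth.loc[truth.affected, "gene_id"])
        jac = len(ref & planted) / len(ref | planted)
        assert jac > 0.7

    def test_exact_engine_rejected(self, four_line_counts):
        design, counts, _ = four_line_counts
        with pytest.raises(DesignError):
            eb.build_aggregate_reference(counts, design, engine="exact")

    def test_single_line_rejected(self, null_counts_3v3):
        design, counts = null_counts_3v3
        with pytest.raises(DesignError):
            eb.build_aggregate_reference(counts, design, engine="glm")

    def test_zero_threshold_gives_empty_reference(self, four_line_counts):
        design, counts, _ = four_line_counts
        ref = eb.build_aggregate_reference(counts, design, engine="wmt", q_threshold=0.0)
        assert ref == set()
        line1 = design[design.line == "L1"]
        res = eb.edit_contrast_de(counts[line1.sample_id], line1, engine="wmt", adjust_line=False)
        with pytest.raises(DegenerateDataError):
            eb.evaluate_against_reference(res, ref)


class TestSpikeInBenchmark:
    def test_combined_mode_truth_covers_400_perturbations(self, null_counts_3v3):
        _, counts = null_counts_3v3
        splits = eb.enumerate_null_splits(list(counts.columns), 3)[:1]
        perf = eb.run_spikein_benchmark(
            counts, splits, n_spike_genes=50, engine="wmt", seed=5, mode="combined"
        )
        assert int((perf.table.tp + perf.table.fn).sum()) == 400
        assert len(perf.table) == len(eb.DEFAULT_SPIKE_LEVELS)

    def test_spiked_level_one_has_no_power(self, null_counts_3v3):
        _, counts = null_counts_3v3
        splits = eb.enumerate_null_splits(list(counts.columns), 3)[:5]
        perf = eb.run_spikein_benchmark(
            counts, splits, n_spike_genes=40, levels=[1.0], engine="wmt", seed=6
        )
        row = perf.table.iloc[0]
        assert row.sensitivity < 0.1  # null spikes behave like unspiked genes
        assert row.specificity > 0.9

    def test_stronger_fold_change_is_easier(self, null_counts_3v3):
        _, counts = null_counts_3v3
        splits = eb.enumerate_null_splits(list(counts.columns), 3)[:5]
        perf = eb.run_spikein_benchmark(
            counts, splits, n_spike_genes=40, levels=[1.5, 5.0], engine="wmt", seed=7
        )
        t = perf.table.set_index("level")
        assert t.loc[5.0, "sensitivity"] >= t.loc[1.5, "sensitivity"]
        assert t.loc[5.0, "auc"] > t.loc[1.5, "auc"]
        assert ((perf.table.tp + perf.table.fn) == 200).all()
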