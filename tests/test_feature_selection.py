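"""Outcome binarization, importance ranking, step schedule and backward search."""

import numpy as np
import pandas as pd
import pytest

import mutpanel as mp
from mutpanel.cohort_io import ClinicalRecord
from mutpanel.feature_selection import (
    OutcomeLabels,
    RfConfig,
    SelectionIteration,
    SelectionTrace,
    StepSchedule,
    binarize_outcome,
    choose_best_subset,
    rank_features,
    sbs_select,
)


class TestBinarizeOutcome:
    def test_event_indicator(self):
        rec = ClinicalRecord("S1", 9.0, 1)
        labels = binarize_outcome([rec, ClinicalRecord("S2", 30.0, 0)], "event_indicator")
        assert dict(zip(labels.sample_ids, labels.labels)) == {"S1": 1, "S2": 0}

    def test_alive_at_horizon_event_after_horizon_is_alive(self):
        recs = [ClinicalRecord("S1", 14.0, 1), ClinicalRecord("S2", 3.0, 1)]
        labels = binarize_outcome(recs, "alive_at_horizon", horizon_months=12)
        assert dict(zip(labels.sample_ids, labels.labels)) == {"S1": 0, "S2": 1}

    def test_censored_before_horizon_excluded(self):
        recs = [
            ClinicalRecord("S1", 6.0, 0),   # censored early: excluded
            ClinicalRecord("S2", 20.0, 0),  # alive at 12
            ClinicalRecord("S3", 5.0, 1),   # died before 12
        ]
        labels = binarize_outcome(recs, "alive_at_horizon", horizon_months=12)
        assert list(labels.sample_ids) == ["S2", "S3"]

    def test_single_class_is_error(self):
        recs = [ClinicalRecord("S1", 5.0, 1), ClinicalRecord("S2", 3.0, 1)]
        with pytest.raises(ValueError, match="single class"):
            binarize_outcome(recs, "event_indicator")


class TestStepSchedule:
    def test_default_tiers_match_anchors(self):
        s = StepSchedule()
        assert s.step_for(430) == 100  # hundreds of features: big steps
        assert s.step_for(400) == 100
        assert s.step_for(399) == 50
        assert s.step_for(150) == 50
        assert s.step_for(51) == 20
        assert s.step_for(50) == 1   # from 50 genes on: one at a time
        assert s.step_for(2) == 1

    def test_planned_sizes_from_ten_single_steps(self):
        assert StepSchedule(((1, 1),)).planned_sizes(10) == list(range(10, 0, -1))

    def test_first_iteration_from_430_removes_100(self):
        sizes = StepSchedule().planned_sizes(430)
        assert sizes[:2] == [430, 330]
        assert sizes[-1] == 1

    def test_step_never_overshoots_below_one(self):
        # 55 -> step 20 would land at 35; 21 -> tier step 1
        assert StepSchedule().planned_sizes(55)[:2] == [55, 35]
        assert StepSchedule(((1, 10),)).planned_sizes(5)[:2] == [5, 1]

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            StepSchedule(((100, 10), (200, 5), (1, 1)))  # not decreasing
        with pytest.raises(ValueError):
            StepSchedule(((100, 0), (1, 1)))  # nonpositive step
        with pytest.raises(ValueError):
            StepSchedule(((100, 10),))  # never reaches 1


class TestChooseBestSubset:
    def _trace(self, pairs):
        its = [
            SelectionIteration(n, acc, [f"G{i}" for i in range(n)], 1)
            for n, acc in pairs
        ]
        return SelectionTrace(its)

    def test_max_accuracy_then_min_size(self):
        trace = self._trace([(5, 0.70), (4, 0.74), (3, 0.74), (2, 0.69)])
        assert len(choose_best_subset(trace)) == 3

    def test_single_iteration(self):
        trace = self._trace([(7, 0.6)])
        assert len(choose_best_subset(trace)) == 7

    def test_exact_tie_prefers_fewer_variables(self):
        trace = self._trace([(20, 0.7368), (18, 0.7368)])
        assert len(choose_best_subset(trace, tie_tolerance=0.0)) == 18

    def test_tie_tolerance_admits_near_best(self):
        trace = self._trace([(10, 0.75), (4, 0.74)])
        assert len(choose_best_subset(trace, tie_tolerance=0.02)) == 4

    def test_empty_trace_is_error(self):
        with pytest.raises(ValueError):
            choose_best_subset(SelectionTrace([]))


def _planted_matrix_labels(n, g, seed, flip=0.15, prevalence=0.35):
    """One strongly label-associated gene among g-1 noise genes."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, g)) < prevalence).astype(np.int8)
    noise = rng.random(n) < flip
    y = np.where(noise, 1 - X[:, 0], X[:, 0])
    samples = [f"S{i}" for i in range(n)]
    matrix = mp.BinaryMutationMatrix(
        pd.DataFrame(X, index=pd.Index(samples, name="sample_id"),
                     columns=[f"G{j}" for j in range(g)])
    )
    return matrix, OutcomeLabels(tuple(samples), tuple(int(v) for v in y))


class TestRankFeatures:
    def test_strong_gene_ranks_top5_across_seeds(self):
        hits = 0
        for seed in range(10):
            matrix, labels = _planted_matrix_labels(300, 50, seed)
            imp = rank_features(matrix, labels, RfConfig(seed=seed))
            hits += list(imp.index).index("G0") < 5
        assert hits >= 9

    def test_constant_zero_column_has_floor_importance(self):
        matrix, labels = _planted_matrix_labels(200, 20, seed=1)
        df = matrix.df.copy()
        df["GZERO"] = 0
        imp = rank_features(mp.BinaryMutationMatrix(df), labels, RfConfig(seed=1))
        assert imp["GZERO"] == pytest.approx(imp.min())

    def test_importance_calibrated_against_permutation_null(self):
        """With labels independent of the matrix, at most 10% of genes show
        importance above the 95th percentile of a 50-permutation null."""
        rng = np.random.default_rng(0)
        n, g = 150, 30
        X = (rng.random((n, g)) < 0.2).astype(np.int8)
        y = (rng.random(n) < 0.5).astype(int)
        samples = [f"S{i}" for i in range(n)]
        matrix = mp.BinaryMutationMatrix(
            pd.DataFrame(X, index=pd.Index(samples, name="sample_id"),
                         columns=[f"G{j:02d}" for j in range(g)])
        )
        labels = OutcomeLabels(tuple(samples), tuple(int(v) for v in y))
        obs = rank_features(matrix, labels, RfConfig(n_trees=30, seed=0))
        null = np.empty((50, g))
        for b in range(50):
            yp = rng.permutation(y)
            perm = OutcomeLabels(tuple(samples), tuple(int(v) for v in yp))
            imp = rank_features(matrix, perm, RfConfig(n_trees=30, seed=1000 + b))
            null[b] = imp.reindex(sorted(imp.index)).to_numpy()
        obs_sorted = obs.reindex(sorted(obs.index)).to_numpy()
        exceed = (obs_sorted > np.quantile(null, 0.95, axis=0)).mean()
        assert exceed <= 0.10

    def test_sample_mismatch_is_error(self):
        matrix, labels = _planted_matrix_labels(50, 5, seed=2)
        bad = OutcomeLabels(("NOPE", *labels.sample_ids[1:]), labels.labels)
        with pytest.raises(ValueError, match="NOPE"):
            rank_features(matrix, bad, RfConfig(seed=2))


class TestSbsSelect:
    def test_trace_visits_exactly_the_scheduled_sizes(self):
        matrix, labels = _planted_matrix_labels(60, 10, seed=3)
        cfg = RfConfig(n_trees=10, seed=3)
        trace = sbs_select(matrix, labels, cfg, StepSchedule(((1, 1),)))
        assert trace.sizes() == list(range(10, 0, -1))
        assert [it.step_size for it in trace.iterations][:-1] == [1] * 9

    def test_deterministic_under_fixed_seed(self):
        matrix, labels = _planted_matrix_labels(60, 6, seed=4)
        cfg = RfConfig(n_trees=10, seed=11)
        t1 = sbs_select(matrix, labels, cfg)
        t2 = sbs_select(matrix, labels, cfg)
        assert t1.to_json() == t2.to_json()

    def test_strong_gene_survives_to_the_chosen_subset(self):
        matrix, labels = _planted_matrix_labels(200, 15, seed=5, flip=0.1)
        trace = sbs_select(matrix, labels, RfConfig(n_trees=50, seed=5))
        chosen = choose_best_subset(trace)
        assert "G0" in chosen

    def test_null_labels_accuracy_near_majority_rate(self):
        """With permuted labels the best CV accuracy stays within 3 standard
        errors of the majority-class rate (max-over-trace selection bias
        included in the allowance)."""
        rng = np.random.default_rng(6)
        matrix, labels = _planted_matrix_labels(150, 12, seed=6)
        y = np.array(labels.labels)
        rng.shuffle(y)
        null_labels = OutcomeLabels(labels.sample_ids, tuple(int(v) for v in y))
        trace = sbs_select(matrix, null_labels, RfConfig(n_trees=50, seed=6))
        majority = max(y.mean(), 1 - y.mean())
        se = np.sqrt(majority * (1 - majority) / len(y))
        assert max(trace.accuracies()) <= majority + 3 * se


def test_chosen_subset_beats_random_gene_draws():
    """On a planted-signature cohort the chosen subset's Jaccard overlap with
    the planted genes strictly exceeds the 95th percentile of 200 random
    same-size gene draws."""
    cfg = mp.SimulationConfig(
        n_samples=250, n_genes=40, planted_genes=8, seed=1,
        planted_prevalence_range=(0.08, 0.2),
    )
    cohort, truth = mp.simulate_cohort(cfg)
    matrix = mp.prevalence_filter(mp.build_binary_matrix(cohort), 3)
    labels = mp.binarize_outcome(cohort.clinical)
    trace = sbs_select(matrix, labels, RfConfig(n_trees=50, seed=1))
    chosen = set(choose_best_subset(trace))
    planted = set(truth.planted_genes)
    jaccard = len(chosen & planted) / len(chosen | planted)

    rng = np.random.default_rng(1)
    genes = np.array(matrix.genes)
    null = []
    for _ in range(200):
        draw = set(rng.choice(genes, size=len(chosen), replace=False))
        null.append(len(draw & planted) / len(draw | planted))
    assert jaccard > np.quantile(null, 0.95)


def test_selection_trace_round_trips_json():
    its = [SelectionIteration(3, 0.7, ["A", "B", "C"], 1),
           SelectionIteration(2, 0.6, ["A", "B"], 1)]
    trace = SelectionTrace(its)
    assert SelectionTrace.from_json(trace.to_json()).to_json() == trace.to_json()
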