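"""Evaluation protocol: split stratification, metrics, PR curves, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beakid import classify, evaluate
from beakid.errors import InvalidParameterError


def brute_force_ap(y, scores):
    """Average precision by an explicit threshold sweep over distinct scores,
    descending: AP = sum over positives-adding thresholds of (dR * P)."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    y = np.asarray(y)[order]
    n_pos = y.sum()
    ap, tp = 0.0, 0
    i = 0
    scores_sorted = np.asarray(scores, dtype=float)[order]
    while i < len(y):
        j = i
        while j < len(y) and scores_sorted[j] == scores_sorted[i]:
            j += 1
        new_tp = tp + y[i:j].sum()
        precision = new_tp / j
        ap += (new_tp - tp) / n_pos * precision
        tp = new_tp
        i = j
    return ap


class TestStratifiedShuffleSplits:
    def test_exact_twenty_percent_small_example(self):
        labels = ["A"] * 10 + ["B"] * 5
        plan = evaluate.stratified_shuffle_splits(labels, runs=1, folds=1, base_seed=0)
        _, _, train, test = plan.splits[0]
        y = np.asarray(labels)
        assert (y[test] == "A").sum() == 2
        assert (y[test] == "B").sum() == 1
        assert len(train) + len(test) == 15
        assert not set(train) & set(test)

    def test_study_cohort_test_size_35(self):
        """Largest-remainder allocation of 20% per class over the 174-sample
        cohort yields a 35-sample test set."""
        from beakid.synthetic import DEFAULT_COUNTS

        labels = np.repeat(list(DEFAULT_COUNTS), list(DEFAULT_COUNTS.values()))
        plan = evaluate.stratified_shuffle_splits(labels, runs=1, folds=1)
        assert len(plan.splits[0][3]) == 35

    def test_same_seed_identical_plan(self):
        labels = ["A"] * 8 + ["B"] * 8 + ["C"] * 4
        p1 = evaluate.stratified_shuffle_splits(labels, runs=2, folds=3, base_seed=7)
        p2 = evaluate.stratified_shuffle_splits(labels, runs=2, folds=3, base_seed=7)
        for s1, s2 in zip(p1.splits, p2.splits):
            assert np.array_equal(s1[2], s2[2]) and np.array_equal(s1[3], s2[3])

    def test_folds_within_a_run_differ(self):
        labels = ["A"] * 40 + ["B"] * 40
        plan = evaluate.stratified_shuffle_splits(labels, runs=1, folds=5, base_seed=1)
        tests = [tuple(s[3]) for s in plan.splits]
        assert len(set(tests)) == 5

    def test_singleton_class_rejected_by_name(self):
        with pytest.raises(InvalidParameterError, match="rare"):
            evaluate.stratified_shuffle_splits(["a"] * 5 + ["rare"], runs=1, folds=1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        counts=st.lists(st.integers(2, 40), min_size=2, max_size=6),
        seed=st.integers(0, 1000),
    )
    def test_stratification_within_one_sample_of_quota(self, counts, seed):
        """Per class and per fold, the test share differs from exactly 20%
        of the class size by less than one sample; partitions are clean."""
        labels = np.repeat([f"c{i}" for i in range(len(counts))], counts)
        plan = evaluate.stratified_shuffle_splits(labels, runs=2, folds=2, base_seed=seed)
        for _, _, train, test in plan.splits:
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == len(labels)
            for i, c in enumerate(counts):
                n_test = (labels[test] == f"c{i}").sum()
                assert abs(n_test - 0.2 * c) < 1


class TestConfusionAndMetrics:
    def test_counting_and_conservation(self):
        cm = evaluate.confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.tolist() == [[1, 1], [0, 1]]
        assert cm.sum() == 3

    def test_perfect_predictions_diagonal(self):
        cm = evaluate.confusion_matrix(["A", "B", "C"], ["A", "B", "C"], ["A", "B", "C"])
        assert np.array_equal(cm, np.eye(3, dtype=int))
        assert evaluate.accuracy(cm) == 1.0

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidParameterError):
            evaluate.confusion_matrix(["A"], ["Z"], ["A", "B"])

    def test_binary_accuracy_formula(self):
        # TP=3, FN=1 / FP=2, TN=4 -> (3+4)/10
        cm = np.array([[3, 1], [2, 4]])
        assert evaluate.accuracy(cm) == pytest.approx(0.7)

    def test_all_wrong_is_zero(self):
        assert evaluate.accuracy(np.array([[0, 2], [3, 0]])) == 0.0

    def test_precision_recall_formulas(self):
        cm = np.array([[3, 1], [1, 5]])  # class 0: TP=3, FP=1, FN=1
        p, r, degenerate = evaluate.precision_recall(cm, 0)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.75)
        assert not degenerate

    def test_absent_class_flagged_degenerate(self):
        cm = np.array([[0, 0, 0], [0, 4, 0], [0, 0, 4]])
        p, r, degenerate = evaluate.precision_recall(cm, 0)
        assert (p, r) == (0.0, 0.0)
        assert degenerate


class TestPrCurveAuc:
    def test_perfect_separation_auc_one(self):
        y = [0, 0, 0, 1, 1]
        scores = [0.1, 0.2, 0.3, 0.8, 0.9]
        _, _, auc = evaluate.pr_curve_auc(y, scores)
        assert auc == pytest.approx(1.0)

    def test_random_scores_approach_prevalence(self):
        """Label-independent scores give AP near the positive prevalence."""
        rng = np.random.default_rng(0)
        n, p = 10_000, 0.3
        y = (rng.uniform(size=n) < p).astype(int)
        scores = rng.uniform(size=n)
        _, _, auc = evaluate.pr_curve_auc(y, scores)
        assert auc == pytest.approx(y.mean(), abs=0.05)

    def test_reversed_perfect_scores_sink_below_half(self):
        """Anti-informative ranking at prevalence 0.2 lands near the tail
        precision, well below 0.5 (and below prevalence)."""
        y = np.array([0] * 80 + [1] * 20)
        scores = np.linspace(1, 0, 100)  # every negative outranks every positive
        _, _, auc_rev = evaluate.pr_curve_auc(y, scores)
        expected = np.mean([k / (80 + k) for k in range(1, 21)])
        assert auc_rev == pytest.approx(expected, abs=1e-9)
        assert auc_rev < 0.5

    def test_agrees_with_brute_force_sweep(self, rng):
        y = (rng.uniform(size=200) < 0.4).astype(int)
        scores = rng.normal(size=200) + 0.5 * y
        _, _, auc = evaluate.pr_curve_auc(y, scores)
        assert auc == pytest.approx(brute_force_ap(y, scores), abs=1e-10)

    def test_no_positives_rejected(self):
        with pytest.raises(InvalidParameterError):
            evaluate.pr_curve_auc([0, 0], [0.1, 0.2])

    def test_curve_recalls_monotone(self, rng):
        y = (rng.uniform(size=50) < 0.5).astype(int)
        precisions, recalls, _ = evaluate.pr_curve_auc(y, rng.uniform(size=50))
        assert np.all(np.diff(recalls) >= 0)


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(5)
    rows, labels = [], []
    for k in range(3):
        rows.append(rng.normal(k * 10, 0.5, size=(20, 3)))
        labels += [f"sp{k}"] * 20
    t = pd.DataFrame(np.vstack(rows), columns=["f0", "f1", "f2"])
    t["label"] = labels
    return t


class TestRunExperiment:

    def test_report_carries_one_accuracy_per_fold(self, table):
        plan = evaluate.stratified_shuffle_splits(table["label"], runs=2, folds=5, base_seed=1)
        report = evaluate.run_experiment(table, classify.ClassifierSpec("GNB"), plan)
        assert len(report.fold_accuracies) == 10
        assert all(cm.sum() == 12 for cm in report.confusions)

    def test_separable_data_perfect_scores(self, table):
        plan = evaluate.stratified_shuffle_splits(table["label"], runs=1, folds=5, base_seed=2)
        report = evaluate.run_experiment(table, classify.ClassifierSpec("ANN", seed=0), plan)
        assert report.mean_accuracy == pytest.approx(1.0)
        assert report.macro_auc == pytest.approx(1.0)

    def test_report_json_deterministic(self, table):
        plan = evaluate.stratified_shuffle_splits(table["label"], runs=1, folds=3, base_seed=3)
        spec = classify.ClassifierSpec("ANN", seed=4)
        r1 = evaluate.run_experiment(table, spec, plan)
        r2 = evaluate.run_experiment(table, spec, plan)
        assert r1.to_json() == r2.to_json()

    def test_per_class_tp_plus_fn_equals_class_test_count(self, table):
        plan = evaluate.stratified_shuffle_splits(table["label"], runs=1, folds=2, base_seed=4)
        report = evaluate.run_experiment(table, classify.ClassifierSpec("DT", seed=0), plan)
        for cm in report.confusions:
            assert np.all(cm.sum(axis=1) == 4)  # 20% of 20 per class
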