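"""Repeated stratified shuffle-split evaluation with PR reporting.

The protocol: five independent stratified 80/20 shuffle splits per run,
repeated for ten runs — 50 train/test fits per classifier.  Stratification
allocates each class's test quota by largest-remainder rounding of
class_count x test_fraction, so every class's test share is within one
sample of exactly 20% on every fold.  Fold f of run r draws from a
dedicated seed ``base_seed + r * 1000 + f``, making the whole plan
reproducible from one number.

Per fold the report collects the confusion matrix, accuracy (trace /
total), one-vs-rest precision and recall per class, and the per-class
precision-recall curve summarised by average precision (step-wise
summation, no linear interpolation).  Accuracies aggregate to a mean and
standard deviation over all folds x runs; per-class AUCs macro-average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from . import classify
from .errors import InvalidParameterError


@dataclass(frozen=True)
class SplitPlan:
    """Materialised train/test index pairs for runs x folds shuffle splits."""

    runs: int
    folds: int
    test_fraction: float
    base_seed: int
    splits: tuple  # ((run, fold, train_idx, test_idx), ...)


def _test_quotas(counts: pd.Series, test_fraction: float) -> dict:
    """Largest-remainder allocation of the total test size over classes.

    The total is round-half-up of n x test_fraction; floors are assigned
    first and the remainder goes to the classes with the largest fractional
    parts (ties: larger class first, then label order).
    """
    quotas = counts * test_fraction
    total = int(np.floor(counts.sum() * test_fraction + 0.5))
    floors = np.floor(quotas).astype(int)
    leftover = total - int(floors.sum())
    remainders = quotas - floors
    order = sorted(
        counts.index,
        key=lambda lab: (-remainders[lab], -counts[lab], str(lab)),
    )
    alloc = floors.to_dict()
    for lab in order[:leftover]:
        alloc[lab] += 1
    return alloc


def stratified_shuffle_splits(
    labels,
    runs: int = 10,
    folds: int = 5,
    test_fraction: float = 0.2,
    base_seed: int = 0,
) -> SplitPlan:
    """Build the full runs x folds split plan for a label vector."""
    labels = pd.Series(np.asarray(labels))
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise InvalidParameterError(
            f"classes with a single sample cannot be split: {sorted(map(str, singletons.index))}"
        )
    if not 0 < test_fraction < 1:
        raise InvalidParameterError("test_fraction must lie in (0, 1)")
    quotas = _test_quotas(counts, test_fraction)
    by_class = {lab: np.flatnonzero(labels.to_numpy() == lab) for lab in counts.index}

    splits = []
    for r in range(runs):
        for f in range(folds):
            rng = np.random.default_rng(base_seed + r * 1000 + f)
            test_parts = []
            for lab in sorted(by_class, key=str):
                idx = by_class[lab]
                perm = rng.permutation(len(idx))
                test_parts.append(idx[perm[: quotas[lab]]])
            test_idx = np.sort(np.concatenate(test_parts))
            train_idx = np.setdiff1d(np.arange(len(labels)), test_idx)
            splits.append((r, f, train_idx, test_idx))
    return SplitPlan(
        runs=runs,
        folds=folds,
        test_fraction=test_fraction,
        base_seed=base_seed,
        splits=tuple(splits),
    )


def confusion_matrix(y_true, y_pred, class_order) -> np.ndarray:
    """K x K count matrix: entry (i, j) = true class i predicted as j."""
    class_order = list(class_order)
    index = {lab: k for k, lab in enumerate(class_order)}
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise InvalidParameterError("y_true and y_pred differ in length")
    cm = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise InvalidParameterError(f"label outside class_order: {t!r} / {p!r}")
        cm[index[t], index[p]] += 1
    return cm


def accuracy(confusion: np.ndarray) -> float:
    """Multiclass accuracy trace/total; reduces to
    (TP + TN) / (TP + TN + FP + FN) for two classes."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise InvalidParameterError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def precision_recall(confusion: np.ndarray, class_k: int) -> tuple[float, float, bool]:
    """One-vs-rest precision and recall of class ``class_k``.

    Returns ``(precision, recall, degenerate)``: zero-denominator cases
    yield 0.0 with the degenerate flag set.
    """
    confusion = np.asarray(confusion)
    tp = confusion[class_k, class_k]
    fp = confusion[:, class_k].sum() - tp
    fn = confusion[class_k, :].sum() - tp
    degenerate = False
    if tp + fp == 0 or tp + fn == 0:
        degenerate = True
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return float(precision), float(recall), degenerate


def pr_curve_auc(y_true_onevsrest, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and its area for one binary problem.

    Returns ``(precisions, recalls, auc)`` with one point per distinct
    score threshold, thresholds descending.  The area is the average
    precision, the step-wise summation sum_n (R_n - R_{n-1}) P_n — no
    linear interpolation between points.
    """
    y = np.asarray(y_true_onevsrest).astype(int)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise InvalidParameterError("scores must be finite")
    if y.sum() == 0:
        raise InvalidParameterError("need at least one positive sample")
    precisions, recalls, _ = precision_recall_curve(y, scores)
    auc = float(average_precision_score(y, scores))
    # precision_recall_curve returns points in ascending-threshold order;
    # flip so the curve reads threshold-descending (recall increasing).
    return precisions[::-1], recalls[::-1], auc


@dataclass
class EvalReport:
    classifier: str
    descriptor: str | None
    view: str | None
    class_order: list
    fold_accuracies: list[float]
    confusions: list[np.ndarray]
    mean_accuracy: float
    sd_accuracy: float
    per_class: dict  # label -> {precision, recall, auc}
    macro_auc: float

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "descriptor": self.descriptor,
            "view": self.view,
            "class_order": [str(c) for c in self.class_order],
            "folds": [round(a, 10) for a in self.fold_accuracies],
            "mean_accuracy": round(self.mean_accuracy, 10),
            "sd_accuracy": round(self.sd_accuracy, 10),
            "per_class": {
                str(lab): {k: round(v, 10) for k, v in stats.items()}
                for lab, stats in self.per_class.items()
            },
            "macro_auc": round(self.macro_auc, 10),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def run_experiment(
    features: pd.DataFrame,
    spec: classify.ClassifierSpec,
    plan: SplitPlan,
    descriptor: str | None = None,
    view: str | None = None,
) -> EvalReport:
    """Fit the classifier on every fold of the plan and aggregate.

    The feature table carries one row per sample and a final ``label``
    column aligned with the labels the plan was built from.
    """
    y = features["label"].to_numpy()
    class_order = sorted(np.unique(y), key=str)
    fold_accuracies: list[float] = []
    confusions: list[np.ndarray] = []
    per_class_acc: dict = {lab: {"precision": [], "recall": [], "auc": []} for lab in class_order}

    for fold_counter, (r, f, train_idx, test_idx) in enumerate(plan.splits):
        # each fold trains a fresh model: stochastic learners re-initialise
        # per fold, deterministically derived from the spec seed
        fold_spec = replace(spec, seed=spec.seed + fold_counter)
        try:
            model = classify.fit(fold_spec, features, train_idx)
            scores, y_pred = classify.predict_scores(model, features.iloc[test_idx])
        except Exception as exc:
            raise RuntimeError(f"run {r} fold {f}: {exc}") from exc
        y_test = y[test_idx]
        cm = confusion_matrix(y_test, y_pred, class_order)
        confusions.append(cm)
        fold_accuracies.append(accuracy(cm))
        for k, lab in enumerate(class_order):
            p, rec, degenerate = precision_recall(cm, k)
            if not degenerate:
                per_class_acc[lab]["precision"].append(p)
                per_class_acc[lab]["recall"].append(rec)
            positives = (y_test == lab).astype(int)
            if positives.sum() and lab in model.classes:
                col = list(model.classes).index(lab)
                _, _, auc = pr_curve_auc(positives, scores[:, col])
                per_class_acc[lab]["auc"].append(auc)

    acc = np.asarray(fold_accuracies)
    per_class = {
        lab: {
            "precision": float(np.mean(v["precision"])) if v["precision"] else 0.0,
            "recall": float(np.mean(v["recall"])) if v["recall"] else 0.0,
            "auc": float(np.mean(v["auc"])) if v["auc"] else 0.0,
        }
        for lab, v in per_class_acc.items()
    }
    macro_auc = float(np.mean([s["auc"] for s in per_class.values()]))
    return EvalReport(
        classifier=spec.name,
        descriptor=descriptor,
        view=view,
        class_order=list(class_order),
        fold_accuracies=[float(a) for a in fold_accuracies],
        confusions=confusions,
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        per_class=per_class,
        macro_auc=macro_auc,
    )
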