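"""The eight benchmark classifiers behind one train/score contract.

Each classifier is configured with the study's published hyperparameters
(everything else stays at the scikit-learn defaults, documented in the
methods note):

ANN   one hidden layer of 30 neurons, learning rate 0.001, max 200
      iterations, stochastic gradient-based (adam) weight optimisation
SVM   C = 30, sigmoid kernel, one-vs-one decision function
RF    100 trees, Gini impurity, sqrt(n_features) per split
DT    information-gain (entropy) splits, max depth 2
kNN   k = 8, Minkowski/Euclidean metric, uniform weights
LR    C = 0.15, multinomial loss, newton-cg optimiser
LDA   singular-value-decomposition solver, tol = 1e-4
GNB   variance floor (var_smoothing) = 1e-9

Features are z-score standardised by default, with the scaler fitted on
training rows only (``scale=False`` switches it off).  Scores are class
probabilities where the model defines them; for the SVM they are one-vs-one
vote shares min-max normalised per row.  Hard labels are the score argmax
with ties broken toward the lowest class index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import HyperparameterSchemaError, InvalidParameterError

CLASSIFIER_NAMES = ("ANN", "SVM", "RF", "DT", "kNN", "LR", "LDA", "GNB")

#: Published hyperparameter values, keyed by the scikit-learn argument names.
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "ANN": {
        "hidden_layer_sizes": (30,),
        "learning_rate_init": 0.001,
        "max_iter": 200,
        "solver": "adam",
    },
    "SVM": {"C": 30.0, "kernel": "sigmoid", "decision_function_shape": "ovo"},
    "RF": {"n_estimators": 100, "criterion": "gini", "max_features": "sqrt"},
    "DT": {"criterion": "entropy", "max_depth": 2},
    "kNN": {"n_neighbors": 8, "metric": "minkowski", "weights": "uniform"},
    "LR": {"C": 0.15, "solver": "newton-cg"},
    "LDA": {"solver": "svd", "tol": 1e-4},
    "GNB": {"var_smoothing": 1e-9},
}

_SEEDED = {"ANN", "RF", "DT"}  # learners whose fit consumes randomness


@dataclass(frozen=True)
class ClassifierSpec:
    """One named classifier plus hyperparameter overrides and a seed."""

    name: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    scale: bool = True

    def __post_init__(self):
        if self.name not in CLASSIFIER_NAMES:
            raise InvalidParameterError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )
        schema = DEFAULT_HYPERPARAMETERS[self.name]
        for key in self.hyperparameters:
            if self.name == "LDA" and key == "C":
                # The study lists C for LDA, a parameter the model does not
                # have; it is dropped with a warning rather than guessed at.
                warnings.warn("LDA has no C parameter; ignoring it", stacklevel=3)
                continue
            if key not in schema:
                raise HyperparameterSchemaError(
                    f"{self.name} does not accept hyperparameter {key!r}"
                )

    def resolved(self) -> dict[str, Any]:
        params = dict(DEFAULT_HYPERPARAMETERS[self.name])
        params.update({k: v for k, v in self.hyperparameters.items() if k in params})
        return params


_ESTIMATORS = {
    "ANN": MLPClassifier,
    "SVM": SVC,
    "RF": RandomForestClassifier,
    "DT": DecisionTreeClassifier,
    "kNN": KNeighborsClassifier,
    "LR": LogisticRegression,
    "LDA": LinearDiscriminantAnalysis,
    "GNB": GaussianNB,
}


def build_classifier(spec: ClassifierSpec) -> Pipeline:
    """Unfitted scikit-learn pipeline (optional scaler + estimator)."""
    params = spec.resolved()
    if spec.name in _SEEDED or spec.name == "SVM":
        params["random_state"] = spec.seed
    est = _ESTIMATORS[spec.name](**params)
    steps = [("scale", StandardScaler())] if spec.scale else []
    steps.append(("model", est))
    return Pipeline(steps)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    pipeline: Pipeline
    classes: np.ndarray
    n_features: int


def _split_features(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "label" not in features.columns:
        raise InvalidParameterError("feature table must carry a 'label' column")
    X = features.drop(columns="label").to_numpy(dtype=float)
    y = features["label"].to_numpy()
    return X, y


def fit(spec_or_model, features: pd.DataFrame, train_index=None) -> TrainedModel:
    """Fit a classifier on the selected rows of a feature table.

    ``spec_or_model`` is a :class:`ClassifierSpec` or a pre-built pipeline
    paired with its spec.  Training rows must contain at least two classes
    and only finite values; scaling statistics (when enabled) are learned
    from the training rows alone.
    """
    if isinstance(spec_or_model, ClassifierSpec):
        spec = spec_or_model
        pipeline = build_classifier(spec)
    else:
        spec, pipeline = spec_or_model
        pipeline = clone(pipeline)
    X, y = _split_features(features)
    if train_index is not None:
        X, y = X[np.asarray(train_index)], y[np.asarray(train_index)]
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("training features contain non-finite values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InvalidParameterError(
            f"training set holds a single class ({classes[0]!r}); need at least two"
        )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        pipeline.fit(X, y)
    return TrainedModel(spec=spec, pipeline=pipeline, classes=classes, n_features=X.shape[1])


def _ovo_vote_scores(decision: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class vote counts from one-vs-one decision values, min-max
    normalised per row to [0, 1] (constant rows map to 0.5)."""
    votes = np.zeros((decision.shape[0], n_classes))
    for col, (i, j) in enumerate(combinations(range(n_classes), 2)):
        winner = np.where(decision[:, col] > 0, i, j)
        votes[np.arange(len(winner)), winner] += 1
    lo = votes.min(axis=1, keepdims=True)
    hi = votes.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (votes - lo) / np.where(span > 0, span, 1.0), 0.5)
    return out


def predict_scores(model: TrainedModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Per-class score matrix plus hard labels for new samples.

    ``features`` is a feature table (the label column, if present, is
    ignored) or a plain 2-D array.  The feature width must match training.
    """
    if isinstance(features, pd.DataFrame):
        X = features.drop(columns="label", errors="ignore").to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    if X.shape[1] != model.n_features:
        raise InvalidParameterError(
            f"feature width {X.shape[1]} does not match training width {model.n_features}"
        )
    if model.spec.name == "SVM":
        decision = model.pipeline.decision_function(X)
        if decision.ndim == 1:  # binary: one column of signed margins
            decision = decision[:, None]
        scores = _ovo_vote_scores(decision, len(model.classes))
    else:
        scores = model.pipeline.predict_proba(X)
    labels = model.classes[np.argmax(scores, axis=1)]
    return scores, labels
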