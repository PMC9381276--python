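"""Wrapper stage: greedy sequential forward selection over the ORT order.

Starting from the single best-ranked feature, candidate features are appended
one at a time in ascending overall-rank order.  After each append the subset is
re-scored by stratified k-fold cross-validated classification accuracy (with
per-fold hyperparameter tuning by grid search); the candidate is kept only when
the accuracy *strictly* improves — a tie or a drop removes it again.  The loop
visits every ranked feature once, so the result is an ordered subset, the best
cross-validated accuracy reached, and the full per-candidate decision
trajectory.

Cross-validation protocol: the outer split is a seeded stratified k-fold
(k = 10 by default, matching common practice for these sample sizes).  Inside
each outer training set, hyperparameters are chosen by an inner seeded
stratified 3-fold grid search — nested, so the held-out fold never influences
tuning.  Accuracy is the plain fraction of correctly labeled cases,
(TP + TN) / (TP + TN + FP + FN) for two classes and its multi-class
generalization (summed per-class true positives over n).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import KFold, ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .io_preprocess import Dataset
from .overall_ranker import OverallRankTable

__all__ = [
    "EvaluatorSpec",
    "EvalResult",
    "SFSResult",
    "accuracy_from_counts",
    "make_classifier",
    "cv_evaluate",
    "sequential_forward_select",
    "DEFAULT_GRIDS",
]

# Overridable defaults; hyperparameter names follow scikit-learn.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.1, 1.0, 10.0, 100.0], "kernel": ["linear", "rbf"]},
    "dt": {"max_depth": [3, 5, 10, None]},
    "rf": {"n_estimators": [100, 200], "max_depth": [5, None]},
    "knn": {"n_neighbors": [1, 3, 5, 7]},
}

CLASSIFIER_NAMES = ("svm", "dt", "rf", "knn", "custom")


@dataclass
class EvaluatorSpec:
    """How feature subsets are scored: classifier, grid, CV protocol, seed."""

    classifier_name: str = "knn"
    hyper_grid: dict[str, list] | None = None
    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0
    tune_every_step: bool = True
    inner_cv_folds: int = 3
    custom_model: BaseEstimator | None = None

    def __post_init__(self) -> None:
        if self.classifier_name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"classifier_name must be one of {CLASSIFIER_NAMES}, "
                f"got {self.classifier_name!r}"
            )
        if self.classifier_name == "custom" and self.custom_model is None:
            raise ValueError("classifier_name='custom' requires custom_model")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.hyper_grid is not None and any(
            len(v) == 0 for v in self.hyper_grid.values()
        ):
            raise ValueError("hyperparameter grids must be non-empty")

    @property
    def grid(self) -> dict[str, list]:
        if self.hyper_grid is not None:
            return self.hyper_grid
        return DEFAULT_GRIDS.get(self.classifier_name, {})


@dataclass
class EvalResult:
    """Cross-validated accuracy of one feature subset."""

    accuracy: float
    per_fold_accuracy: list[float]
    best_hyperparams: dict
    per_fold_hyperparams: list[dict] = field(default_factory=list)


@dataclass
class TrajectoryStep:
    feature: str
    accuracy: float
    kept: bool


@dataclass
class SFSResult:
    """Outcome of the forward-selection loop."""

    selected_features: list[str]
    best_accuracy: float
    trajectory: list[TrajectoryStep]
    seed: int | None = None
    classifier_name: str | None = None
    best_hyperparams: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "best_accuracy": self.best_accuracy,
            "seed": self.seed,
            "classifier": self.classifier_name,
            "hyperparams": self.best_hyperparams,
            "trajectory": [
                {"feature": s.feature, "accuracy": s.accuracy, "kept": s.kept}
                for s in self.trajectory
            ],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN); errors on an empty confusion."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("confusion counts sum to zero")
    return (tp + tn) / total


def make_classifier(spec: EvaluatorSpec) -> BaseEstimator:
    """Fresh unfitted estimator for the spec; 'custom' clones the user object."""
    name = spec.classifier_name
    if name == "svm":
        return SVC(random_state=spec.seed)
    if name == "dt":
        return DecisionTreeClassifier(random_state=spec.seed)
    if name == "rf":
        return RandomForestClassifier(random_state=spec.seed)
    if name == "knn":
        return KNeighborsClassifier()
    return clone(spec.custom_model)


def _splitter(spec: EvaluatorSpec, n_splits: int):
    if spec.stratified:
        return StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    return KFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)


def _grid_search(
    X: np.ndarray, y: np.ndarray, spec: EvaluatorSpec, n_splits: int
) -> dict:
    """Pick the grid point with the best mean CV accuracy (ties: grid order)."""
    grid = list(ParameterGrid(spec.grid)) if spec.grid else [{}]
    if len(grid) == 1:
        return grid[0]
    n_splits = min(n_splits, int(np.min(np.bincount(np.unique(y, return_inverse=True)[1]))))
    n_splits = max(n_splits, 2)
    splits = list(_splitter(spec, n_splits).split(X, y))
    best_params, best_score = grid[0], -1.0
    for params in grid:
        scores = []
        for train, test in splits:
            model = make_classifier(spec).set_params(**params)
            model.fit(X[train], y[train])
            scores.append(float(np.mean(model.predict(X[test]) == y[test])))
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def cv_evaluate(
    data: Dataset,
    feature_subset: list[str],
    spec: EvaluatorSpec,
    fixed_params: dict | None = None,
) -> EvalResult:
    """Cross-validated accuracy of a feature subset.

    With ``fixed_params`` the inner grid search is skipped and those
    hyperparameters are used in every fold; otherwise each outer training set
    runs its own nested grid search.
    """
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    X = data.subset(feature_subset)
    y = data.labels

    per_fold_acc: list[float] = []
    per_fold_params: list[dict] = []
    for train, test in _splitter(spec, spec.cv_folds).split(X, y):
        if fixed_params is not None:
            params = fixed_params
        else:
            params = _grid_search(X[train], y[train], spec, spec.inner_cv_folds)
        model = make_classifier(spec).set_params(**params)
        model.fit(X[train], y[train])
        per_fold_acc.append(float(np.mean(model.predict(X[test]) == y[test])))
        per_fold_params.append(params)

    # majority vote across folds, ties resolved by first occurrence
    counts = Counter(tuple(sorted(p.items())) for p in per_fold_params)
    best = dict(counts.most_common(1)[0][0]) if counts else {}
    return EvalResult(
        accuracy=float(np.mean(per_fold_acc)),
        per_fold_accuracy=per_fold_acc,
        best_hyperparams=best,
        per_fold_hyperparams=per_fold_params,
    )


def sequential_forward_select(
    ort: OverallRankTable,
    data: Dataset | None,
    spec: EvaluatorSpec,
    evaluate: Callable[[list[str]], float] | None = None,
    max_features: int | None = None,
) -> SFSResult:
    """Greedy forward selection over the ORT order with strict improvement.

    The top-ranked feature is always retained.  Each subsequent feature is
    appended, the subset re-evaluated, and the feature kept only when accuracy
    strictly exceeds the best so far.  ``evaluate`` overrides the default
    cross-validated scorer with any callable from a feature-name list to an
    accuracy in [0, 1] (used e.g. for deterministic mock evaluators);
    ``max_features`` optionally caps the subset size, after which remaining
    candidates are recorded as not kept without evaluation.
    """
    order = list(ort.feature_names)
    if not order:
        raise ValueError("ORT is empty")
    if data is not None:
        missing = [f for f in order if f not in data.feature_names]
        if missing:
            raise KeyError(f"ORT features absent from dataset: {missing[:5]}")

    last_eval: dict = {}

    if evaluate is None:
        if data is None:
            raise ValueError("data is required unless an evaluate callable is given")
        fixed = (
            None
            if spec.tune_every_step
            else _grid_search(data.subset([order[0]]), data.labels, spec, spec.cv_folds)
        )

        def evaluate(subset: list[str]) -> float:
            result = cv_evaluate(data, subset, spec, fixed_params=fixed)
            last_eval["params"] = result.best_hyperparams
            return result.accuracy

    selected = [order[0]]
    best = float(evaluate(selected))
    best_params = dict(last_eval.get("params", {}))
    trajectory = [TrajectoryStep(order[0], best, True)]

    for feature in order[1:]:
        if max_features is not None and len(selected) >= max_features:
            trajectory.append(TrajectoryStep(feature, best, False))
            continue
        current = float(evaluate(selected + [feature]))
        kept = current > best
        if kept:
            selected.append(feature)
            best = current
            best_params = dict(last_eval.get("params", {}))
        trajectory.append(TrajectoryStep(feature, current, kept))

    return SFSResult(
        selected_features=selected,
        best_accuracy=best,
        trajectory=trajectory,
        seed=spec.seed,
        classifier_name=spec.classifier_name,
        best_hyperparams=best_params,
    )
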