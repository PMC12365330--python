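"""Wrapper objective: cross-validated classifier accuracy of a feature mask.

The fitness of a candidate mask is

    w * (mean stratified k-fold CV accuracy on the masked columns)
      + (1 - w) * (1 - |mask| / d)

with ``w = 1`` by default (pure accuracy).  The optional parsimony term
rewards small subsets.  The CV split is seeded inside the spec, so the
objective is a deterministic function of the mask and the optimizer sees
a coherent landscape.

Because the same masks recur constantly during a metaheuristic run, a
run-scoped :class:`FitnessCache` memoises evaluations by bit-string key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

__all__ = ["FitnessSpec", "evaluate_fitness", "FitnessCache", "make_classifier"]

CLASSIFIERS = ("knn", "svm", "random_forest", "xgboost", "decision_tree")


@dataclass(frozen=True)
class FitnessSpec:
    """Configuration of the wrapper objective.

    Parameters
    ----------
    classifier
        One of ``knn`` (default, k=5), ``svm``, ``random_forest``,
        ``xgboost``, ``decision_tree``.  k-NN is the default search-time
        classifier for speed; any of them may be used for final scoring.
    classifier_params
        Extra keyword arguments forwarded to the estimator constructor.
    cv_folds
        Stratified k-fold count (>= 2); reduced with a warning when the
        smallest class has fewer members.
    cv_seed
        Seed of the shuffled CV split (fixed => deterministic objective).
    penalty_weight
        ``w`` above; 1 means pure accuracy, smaller values add parsimony
        pressure.
    """

    classifier: str = "knn"
    classifier_params: tuple = ()  # stored as sorted (key, value) pairs
    cv_folds: int = 5
    cv_seed: int = 0
    penalty_weight: float = 1.0
    score: str = "accuracy"

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 <= self.penalty_weight <= 1.0:
            raise ValueError("penalty_weight must lie in [0, 1]")
        if self.score != "accuracy":
            raise ValueError("only accuracy scoring is supported")
        if isinstance(self.classifier_params, dict):
            object.__setattr__(
                self, "classifier_params", tuple(sorted(self.classifier_params.items()))
            )

    @property
    def params_dict(self) -> dict:
        return dict(self.classifier_params)


def make_classifier(spec: FitnessSpec):
    """Instantiate the estimator named by ``spec`` (seeded where stochastic)."""
    params = spec.params_dict
    if spec.classifier == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        params.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**params)
    if spec.classifier == "svm":
        from sklearn.svm import SVC

        params.setdefault("random_state", spec.cv_seed)
        return SVC(**params)
    if spec.classifier == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        params.setdefault("n_estimators", 100)
        params.setdefault("random_state", spec.cv_seed)
        return RandomForestClassifier(**params)
    if spec.classifier == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        params.setdefault("random_state", spec.cv_seed)
        return DecisionTreeClassifier(**params)
    if spec.classifier == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("random_state", spec.cv_seed)
        params.setdefault("n_estimators", 50)
        return XGBClassifier(**params)
    raise ValueError(spec.classifier)  # unreachable


def _effective_folds(y_encoded: np.ndarray, requested: int) -> int:
    _, counts = np.unique(y_encoded, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError(
            "every class needs at least 2 members for stratified CV "
            f"(smallest class has {min_count})"
        )
    if min_count < requested:
        warnings.warn(
            f"reducing cv_folds from {requested} to {min_count}: "
            "smallest class is too small",
            stacklevel=3,
        )
        return min_count
    return requested


def evaluate_fitness(mask: np.ndarray, dataset, spec: FitnessSpec) -> float:
    """Score a feature mask: penalised mean stratified-CV accuracy in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1 or mask.size != dataset.n_features:
        raise ValueError(
            f"mask length {mask.size} does not match dataset d={dataset.n_features}"
        )
    if not mask.any():
        raise ValueError("mask must select at least one feature")

    X = dataset.features[:, mask]
    y = dataset.target_encoded
    folds = _effective_folds(y, spec.cv_folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.cv_seed)
    clf = make_classifier(spec)
    accs = np.empty(folds)
    for k, (train, test) in enumerate(skf.split(X, y)):
        model = clone(clf)
        try:
            model.fit(X[train], y[train])
        except Exception as exc:
            raise RuntimeError(
                f"classifier training failed for mask {''.join(map(str, mask.astype(int)))}"
            ) from exc
        accs[k] = float(np.mean(model.predict(X[test]) == y[test]))
    cv_accuracy = float(accs.mean())

    w = spec.penalty_weight
    parsimony = 1.0 - mask.sum() / mask.size
    return w * cv_accuracy + (1.0 - w) * parsimony


class FitnessCache:
    """Run-scoped memoiser: one CV run per distinct mask.

    Bound to a single (dataset, spec) pair; call it with a mask (or use
    :meth:`get_or_compute`) and it returns the cached value when the
    same bit pattern was seen before.  ``hits``/``misses`` expose cache
    statistics so evaluation budgets can be compared fairly.
    """

    def __init__(self, dataset, spec: FitnessSpec):
        self.dataset = dataset
        self.spec = spec
        self._store: Dict[str, float] = {}
        self.hits = 0
        self.misses = 0

    def get_or_compute(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = "".join("1" if b else "0" for b in mask)
        if key in self._store:
            self.hits += 1
            return self._store[key]
        self.misses += 1
        value = evaluate_fitness(mask, self.dataset, self.spec)
        self._store[key] = value
        return value

    __call__ = get_or_compute

    @property
    def n_evaluations(self) -> int:
        """Number of distinct CV runs performed."""
        return self.misses
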