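"""The pool of 18 base classification algorithms.

The selective-ensemble layer needs a pool of diverse learners whose
out-of-fold correctness profiles can be compared; it does not depend on any
particular implementation of each named algorithm.  The registry therefore
maps each of the 18 classical names to its nearest available analog
(documented per entry), with fixed seeds so every fit is reproducible.
ZeroR, OneR and Decision Stump are implemented natively — they are tiny
and serve as exactly-verifiable learners in tests.

Every classifier consumes the *same* stratified fold assignment when
producing out-of-fold predictions, so the resulting correctness profiles
are directly comparable across classifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Native minimal learners
# ---------------------------------------------------------------------------

class ZeroR(ClassifierMixin, BaseEstimator):
    """Majority-class predictor (ties broken by label sort order)."""

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = unique_labels(y)
        labels, counts = np.unique(y, return_counts=True)
        self.majority_ = labels[np.argmax(counts)]  # argmax: first = sorted order
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.full(X.shape[0], self.majority_, dtype=self.classes_.dtype)


class OneR(ClassifierMixin, BaseEstimator):
    """Single-attribute rule learner for continuous features.

    Each feature is discretized into up to ``n_bins`` equal-frequency bins;
    a rule maps each bin to its training-majority class.  The feature whose
    rule has the fewest training errors wins (ties: lowest feature index).
    """

    def __init__(self, n_bins: int = 5):
        self.n_bins = n_bins

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = unique_labels(y)
        y_enc = np.searchsorted(self.classes_, y)
        best = (-1,)
        for j in range(X.shape[1]):
            edges, rule, correct = self._build_rule(X[:, j], y_enc)
            if correct > best[0]:  # strict: ties keep the lowest feature index
                best = (correct, j, edges, rule)
        _, self.feature_, self.edges_, self.rule_ = best
        return self

    def _build_rule(self, col, y_enc):
        qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(col, qs))
        bins = np.searchsorted(edges, col, side="right")
        rule = np.zeros(len(edges) + 1, dtype=np.intp)
        correct = 0
        for b in range(len(edges) + 1):
            mask = bins == b
            if mask.any():
                cnt = np.bincount(y_enc[mask], minlength=len(self.classes_))
                rule[b] = int(np.argmax(cnt))
                correct += int(cnt.max())
        return edges, rule, correct

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        bins = np.searchsorted(self.edges_, X[:, self.feature_], side="right")
        return self.classes_[self.rule_[bins]]


class DecisionStump(ClassifierMixin, BaseEstimator):
    """Depth-1 decision tree: one feature, one threshold, two leaf classes.

    Exhaustive search over all (feature, midpoint) splits for the fewest
    training misclassifications; ties go to the lowest feature index, then
    the lowest threshold.
    """

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = unique_labels(y)
        y_enc = np.searchsorted(self.classes_, y)
        n, p = X.shape
        C = len(self.classes_)
        total = np.bincount(y_enc, minlength=C)
        best_correct = int(total.max())  # no-split baseline
        self.feature_, self.threshold_ = None, None
        self.left_, self.right_ = int(np.argmax(total)), int(np.argmax(total))
        for j in range(p):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys = X[order, j], y_enc[order]
            left = np.zeros(C, dtype=int)
            for i in range(n - 1):
                left[ys[i]] += 1
                if xs[i] == xs[i + 1]:
                    continue
                right = total - left
                correct = int(left.max()) + int(right.max())
                if correct > best_correct:
                    best_correct = correct
                    self.feature_ = j
                    self.threshold_ = (xs[i] + xs[i + 1]) / 2.0
                    self.left_ = int(np.argmax(left))
                    self.right_ = int(np.argmax(right))
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if self.feature_ is None:
            return self.classes_[np.full(X.shape[0], self.left_)]
        side = X[:, self.feature_] <= self.threshold_
        return self.classes_[np.where(side, self.left_, self.right_)]


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseClassifierSpec:
    """One named base learner: analog description, hyperparameters, seed."""

    name: str
    analog: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def make(self) -> BaseEstimator:
        factory = _FACTORIES[self.name]
        return factory(self.seed, dict(self.hyperparameters))

    def with_seed(self, seed: int) -> "BaseClassifierSpec":
        return BaseClassifierSpec(self.name, self.analog, dict(self.hyperparameters), seed)


def _seeded(cls, seed, hp, **defaults):
    kw = {**defaults, **hp}
    if "random_state" in cls().get_params():
        kw.setdefault("random_state", seed)
    return cls(**kw)


_FACTORIES: dict[str, Callable[[int, dict], BaseEstimator]] = {
    "Logistic Regression": lambda s, hp: _seeded(LogisticRegression, s, hp, max_iter=2000),
    "SMO": lambda s, hp: _seeded(SVC, s, hp, kernel="linear", C=1.0),
    "SVM": lambda s, hp: _seeded(SVC, s, hp, kernel="rbf", C=1.0, gamma="scale"),
    "IB1": lambda s, hp: KNeighborsClassifier(**{"n_neighbors": 1, **hp}),
    "IB5": lambda s, hp: KNeighborsClassifier(**{"n_neighbors": 5, **hp}),
    "IB10": lambda s, hp: KNeighborsClassifier(**{"n_neighbors": 10, **hp}),
    "OneR": lambda s, hp: OneR(**hp),
    "Conjunctive Rule": lambda s, hp: _seeded(DecisionTreeClassifier, s, hp, max_depth=2),
    "Decision Table": lambda s, hp: _seeded(DecisionTreeClassifier, s, hp,
                                            max_depth=4, min_samples_leaf=2),
    "JRip": lambda s, hp: _seeded(DecisionTreeClassifier, s, hp,
                                  min_samples_leaf=5, ccp_alpha=0.005),
    "ZeroR": lambda s, hp: ZeroR(),
    "Simple Cart": lambda s, hp: _seeded(DecisionTreeClassifier, s, hp,
                                         criterion="gini", min_samples_leaf=2),
    "Naive Bayes": lambda s, hp: GaussianNB(**hp),
    "Random Tree": lambda s, hp: _seeded(DecisionTreeClassifier, s, hp,
                                         splitter="random", max_features="sqrt"),
    "FT Tree": lambda s, hp: LinearDiscriminantAnalysis(**hp),
    "Random Forest": lambda s, hp: _seeded(RandomForestClassifier, s, hp, n_estimators=50),
    "Decision Stump": lambda s, hp: DecisionStump(**hp),
    "J48": lambda s, hp: _seeded(DecisionTreeClassifier, s, hp,
                                 criterion="entropy", min_samples_leaf=2),
}

_ANALOGS = {
    "Logistic Regression": "multinomial logistic regression (lbfgs)",
    "SMO": "linear-kernel support vector machine",
    "SVM": "RBF-kernel support vector machine",
    "IB1": "1-nearest-neighbour",
    "IB5": "5-nearest-neighbour",
    "IB10": "10-nearest-neighbour",
    "OneR": "native single-attribute rule learner (equal-frequency bins)",
    "Conjunctive Rule": "depth-2 decision tree (conjunction of two tests)",
    "Decision Table": "depth-4 decision tree (compact attribute table)",
    "JRip": "cost-complexity-pruned decision tree (pruned rule list analog)",
    "ZeroR": "native majority-class predictor",
    "Simple Cart": "CART decision tree (gini)",
    "Naive Bayes": "Gaussian naive Bayes",
    "Random Tree": "single randomized tree (random splitter, sqrt features)",
    "FT Tree": "linear discriminant analysis (oblique linear decision functions)",
    "Random Forest": "random forest (50 trees)",
    "Decision Stump": "native depth-1 decision stump",
    "J48": "entropy decision tree (C4.5 analog)",
}


def registry(seed: int = 0, names: Optional[Sequence[str]] = None) -> list[BaseClassifierSpec]:
    """The 18 default base-classifier specs, in fixed C1..C18 order.

    Each spec carries a seed derived from *seed* so refitting with the same
    global seed is fully deterministic.  *names* restricts the pool (order
    preserved) — useful for fast desk-scale runs.
    """
    specs = [
        BaseClassifierSpec(name=name, analog=_ANALOGS[name], seed=(seed * 131 + i) % (2**31))
        for i, name in enumerate(_FACTORIES)
    ]
    if names is not None:
        unknown = set(names) - set(_FACTORIES)
        if unknown:
            raise KeyError(f"unknown classifier names: {sorted(unknown)}")
        specs = [s for s in specs if s.name in set(names)]
    return specs


REGISTRY_NAMES: tuple[str, ...] = tuple(_FACTORIES)


# ---------------------------------------------------------------------------
# Fitting and out-of-fold prediction
# ---------------------------------------------------------------------------

@dataclass
class FittedClassifier:
    spec: BaseClassifierSpec
    model: BaseEstimator
    class_labels: np.ndarray

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)))


@dataclass
class OOFPredictions:
    """Out-of-fold predictions of one classifier under a shared fold map."""

    classifier_name: str
    fold_assignment: np.ndarray
    predicted: np.ndarray
    accuracy: float


def fit(spec: BaseClassifierSpec, X, y) -> FittedClassifier:
    """Fit one base learner; degrade to majority-class on single-class y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X and y must be non-empty and aligned")
    classes = np.unique(y)
    if len(classes) < 2:
        logger.warning("%s: single-class training set; fitting constant model", spec.name)
        model = ZeroR().fit(X, y)
    else:
        model = spec.make().fit(X, y)
    return FittedClassifier(spec=spec, model=model, class_labels=classes)


def fold_assignment(y, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold indices depending only on (y, folds, seed).

    Members of each class are shuffled and dealt cyclically across folds,
    with a per-class starting offset so classes smaller than *folds* do not
    all land in fold 0.  Classes with fewer members than folds are simply
    spread as evenly as possible — no error.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    fold = np.empty(len(y), dtype=np.intp)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % folds
        offset += len(idx)
    return fold


def oof_predict(spec: BaseClassifierSpec, X, y, folds: int = 10, seed: int = 0) -> OOFPredictions:
    """Out-of-fold predictions under the shared stratified fold map.

    Every instance is predicted exactly once, by a model trained on the
    folds not containing it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold = fold_assignment(y, folds, seed)
    predicted = np.empty(len(y), dtype=y.dtype)
    for f in range(folds):
        test = fold == f
        if not test.any():
            continue
        train = ~test
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = fit(spec, X[train], y[train])
            predicted[test] = fc.predict(X[test])
    accuracy = float(np.mean(predicted == y))
    return OOFPredictions(spec.name, fold, predicted, accuracy)
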