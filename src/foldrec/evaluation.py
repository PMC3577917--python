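"""Cross-validation harness and principal-component feature report.

``crossval`` supports two protocols for ensemble-style builders:

* **nested** (default, honest generalization estimate): the entire model
  build — including any selection done from internal out-of-fold
  predictions — is rerun inside each training split;
* **reuse** (the cheaper protocol): the builder runs once on the full data
  and its committee's internal out-of-fold vote predictions are scored
  directly.

Fold assignment depends only on (y, folds, seed), never on X, so competing
builders evaluated under the same seed share folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .base_classifiers import fold_assignment

logger = logging.getLogger(__name__)


@dataclass
class CVReport:
    folds: int
    seed: int
    per_class_accuracy: dict[str, float]
    total_accuracy: float
    mode: str
    per_class_count: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = [
            {"class": c, "n": self.per_class_count.get(c, 0), "accuracy": a}
            for c, a in sorted(self.per_class_accuracy.items())
        ]
        rows.append({"class": "TOTAL", "n": sum(self.per_class_count.values()),
                     "accuracy": self.total_accuracy})
        return rows


def _report(y, predicted, folds, seed, mode) -> CVReport:
    y = np.asarray(y, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    per_class, counts = {}, {}
    for cls in np.unique(y):
        mask = y == cls
        per_class[str(cls)] = float(np.mean(predicted[mask] == y[mask]))
        counts[str(cls)] = int(mask.sum())
    total = float(np.mean(predicted == y))
    return CVReport(folds=folds, seed=seed, per_class_accuracy=per_class,
                    total_accuracy=total, mode=mode, per_class_count=counts)


def crossval(
    model_builder: Callable,
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    mode: str = "nested",
) -> CVReport:
    """Stratified k-fold accuracy of ``model_builder(X_train, y_train)``.

    In nested mode the builder runs once per fold and its ``.predict`` is
    scored on the held-out fold.  In reuse mode the builder runs once on
    all data and must expose ``oof_vote_predicted`` (an ensemble's internal
    out-of-fold committee vote), which is scored as-is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if mode == "reuse":
        model = model_builder(X, y)
        predicted = getattr(model, "oof_vote_predicted", None)
        if predicted is None:
            raise ValueError("reuse mode needs a builder exposing oof_vote_predicted")
        return _report(y, predicted, folds, seed, mode)
    if mode != "nested":
        raise ValueError(f"unknown mode {mode!r}")
    fold = fold_assignment(y, folds, seed)
    predicted = np.empty(len(y), dtype=object)
    for f in range(folds):
        test = fold == f
        if not test.any():
            continue
        model = model_builder(X[~test], y[~test])
        predicted[test] = model.predict(X[test])
    return _report(y, predicted, folds, seed, mode)


@dataclass
class PCAReport:
    eigenvalues: np.ndarray
    percent_explained: np.ndarray
    cumulative_percent: np.ndarray
    retained: list[int]                       # component indices (0-based)
    top_loadings: list[list[tuple[int, float]]]  # per retained comp: (1-based feature, loading)
    dropped_constant_columns: list[int] = field(default_factory=list)


def pca_report(X, eigen_threshold: float = 3.0, top: int = 3) -> PCAReport:
    """Eigen-decomposition of the feature correlation matrix.

    Zero-variance columns are dropped with a notice (correlation is
    undefined for them); eigenvalues are reported in descending order with
    percent and cumulative contributions, components above
    *eigen_threshold* are retained, and each retained component lists its
    *top* features by absolute loading.  The eigenvalue sum equals the
    number of non-constant columns (trace of the correlation matrix).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("pca_report requires at least 2 rows")
    variances = X.var(axis=0)
    keep = np.flatnonzero(variances > 0)
    dropped = np.flatnonzero(variances == 0)
    if len(dropped):
        logger.info("dropping %d constant column(s) from PCA", len(dropped))
    corr = np.corrcoef(X[:, keep], rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0, None)
    percent = eigvals / eigvals.sum()
    cumulative = np.cumsum(percent)
    retained = [int(i) for i in np.flatnonzero(eigvals > eigen_threshold)]
    top_loadings = []
    for comp in retained:
        vec = eigvecs[:, comp]
        idx = np.argsort(-np.abs(vec))[:top]
        top_loadings.append([(int(keep[i]) + 1, float(vec[i])) for i in idx])
    return PCAReport(
        eigenvalues=eigvals, percent_explained=percent, cumulative_percent=cumulative,
        retained=retained, top_loadings=top_loadings,
        dropped_constant_columns=[int(i) + 1 for i in dropped],
    )
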