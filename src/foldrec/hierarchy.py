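"""Two-layer class -> fold classification.

Layer 1 is a selective ensemble over the seven structural classes; layer 2
holds one selective ensemble per class, trained only on that class's
records with their fold labels.  Prediction routes hard: the layer-1 class
decides which layer-2 model names the fold, so the predicted fold is always
prefixed by the predicted class.  There is no reject or fallback when
layer 1 errs — the exposed vote tallies let a downstream user add one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .ensemble_efss import EnsembleConfig, EnsembleModel, fit_ensemble
from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConstantModel:
    """Degenerate layer-2 model for a class with a single observed fold."""

    label: str

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.label, dtype=object)

    def predict_with_votes(self, x) -> tuple[str, dict[str, int]]:
        return self.label, {self.label: 1}


Layer2Model = Union[EnsembleModel, ConstantModel]


@dataclass
class HierPrediction:
    class_pred: str
    fold_pred: str
    layer1_votes: dict[str, int] = field(default_factory=dict)
    layer2_votes: dict[str, int] = field(default_factory=dict)


@dataclass
class HierarchicalModel:
    layer1: EnsembleModel
    layer2: dict[str, Layer2Model]
    fold_counts: dict[str, int]

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Batch routing: per-row predicted class and fold."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        class_pred = self.layer1.predict(X).astype(object)
        fold_pred = np.empty(X.shape[0], dtype=object)
        for cls in np.unique(class_pred):
            mask = class_pred == cls
            fold_pred[mask] = self.layer2[str(cls)].predict(X[mask.astype(bool)])
        return class_pred, fold_pred


def _split_labels(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    if matrix.labels is None:
        raise ValueError("feature matrix carries no labels")
    y_class, y_fold = [], []
    for rid, lab in zip(matrix.ids, matrix.labels):
        if lab is None or lab.fold_id is None:
            raise ValueError(f"record {rid} lacks a class.fold label")
        y_class.append(lab.class_id)
        y_fold.append(lab.fold_id)
    return np.array(y_class, dtype=object), np.array(y_fold, dtype=object)


def fit_hierarchy(matrix: FeatureMatrix, config: Optional[EnsembleConfig] = None) -> HierarchicalModel:
    """Fit layer 1 on class labels and one layer-2 model per class.

    Every training record contributes to exactly one layer-2 model (its
    true class's).  A class whose records all share one fold, or with fewer
    than two records, gets a constant layer-2 model.
    """
    cfg = config or EnsembleConfig()
    y_class, y_fold = _split_labels(matrix)
    if len(np.unique(y_class)) < 2:
        raise ValueError("fit_hierarchy requires at least 2 classes")
    X = matrix.values

    layer1 = fit_ensemble(X, y_class, cfg)

    layer2: dict[str, Layer2Model] = {}
    fold_counts: dict[str, int] = {}
    for cls in np.unique(y_class):
        mask = y_class == cls
        folds_here = np.unique(y_fold[mask])
        fold_counts[str(cls)] = len(folds_here)
        if len(folds_here) < 2 or int(mask.sum()) < 2:
            majority = Counter(y_fold[mask].tolist()).most_common(1)[0][0]
            if int(mask.sum()) < 2:
                logger.warning("class %s has %d record(s); constant layer-2 model",
                               cls, int(mask.sum()))
            layer2[str(cls)] = ConstantModel(label=str(majority))
        else:
            layer2[str(cls)] = fit_ensemble(X[mask], y_fold[mask], cfg)
    return HierarchicalModel(layer1=layer1, layer2=layer2, fold_counts=fold_counts)


def predict_hier(model: HierarchicalModel, x) -> HierPrediction:
    """Route one feature vector through both layers, exposing vote tallies."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    class_pred, l1_votes = model.layer1.predict_with_votes(x)
    fold_pred, l2_votes = model.layer2[str(class_pred)].predict_with_votes(x)
    return HierPrediction(class_pred=str(class_pred), fold_pred=str(fold_pred),
                          layer1_votes=l1_votes, layer2_votes=l2_votes)


def hier_accuracy(
    model: HierarchicalModel, X, y_class, y_fold
) -> tuple[float, dict[str, float], float]:
    """Layer-wise and end-to-end accuracy on a labeled evaluation set.

    Returns (layer-1 accuracy, per-class layer-2 accuracy conditional on
    the true class, end-to-end fold accuracy).  End-to-end requires both
    layers correct, so it is bounded by each.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_class = np.asarray(y_class, dtype=object)
    y_fold = np.asarray(y_fold, dtype=object)
    class_pred, fold_pred = model.predict(X)
    layer1_acc = float(np.mean(class_pred == y_class))

    per_class: dict[str, float] = {}
    for cls in np.unique(y_class):
        mask = y_class == cls
        sub = model.layer2.get(str(cls))
        if sub is None:
            per_class[str(cls)] = 0.0
            continue
        preds = sub.predict(X[mask.astype(bool)])
        per_class[str(cls)] = float(np.mean(preds == y_fold[mask]))

    end_to_end = float(np.mean((class_pred == y_class) & (fold_pred == y_fold)))
    return layer1_acc, per_class, end_to_end
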