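import numpy as np
import pytest

import foldrec as fr

#: A fast, diverse 6-learner subset of the registry used where the full
#: 18-learner pool would only add runtime, not coverage.
FAST_POOL = ("Logistic Regression", "IB1", "Naive Bayes",
             "Decision Stump", "OneR", "ZeroR")

FAST_CONFIG = fr.EnsembleConfig(k=4, folds=5, seed=7, classifier_names=FAST_POOL)


@pytest.fixture(scope="session")
def separable_xy():
    """A well-separated 3-class feature problem (from the generator)."""
    cfg = fr.GeneratorConfig(n_classes=3, folds_per_class=1, seqs_per_fold=15,
                             length_range=(60, 120), separation=2.5,
                             concentration=0.4, seed=11)
    ds, _ = fr.sample_dataset(cfg)
    M = fr.extract_matrix(ds)
    y = np.array([lab.class_id for lab in M.labels])
    return M.values, y


@pytest.fixture(scope="session")
def fold_labeled_matrix():
    """A 3-class x 2-fold labeled feature matrix for hierarchy tests."""
    cfg = fr.GeneratorConfig(n_classes=3, folds_per_class=2, seqs_per_fold=10,
                             length_range=(60, 120), separation=2.5,
                             concentration=0.4, seed=13)
    ds, _ = fr.sample_dataset(cfg)
    return fr.extract_matrix(ds)


def make_oofs_from_B(B, y):
    """Turn a binary correctness matrix into synthetic OOF predictions.

    Instance j's truth is y[j]; classifier i predicts y[j] when B[i][j]==1
    and the 'wrong' complementary label otherwise.
    """
    wrong = {lab: "wrong_" + lab for lab in set(y)}
    oofs = {}
    order = []
    for i, row in enumerate(B):
        name = f"C{i + 1}"
        predicted = np.array([y[j] if row[j] else wrong[y[j]] for j in range(len(y))])
        oofs[name] = fr.OOFPredictions(
            classifier_name=name,
            fold_assignment=np.zeros(len(y), dtype=int),
            predicted=predicted,
            accuracy=float(np.mean(row)),
        )
        order.append(name)
    return oofs, order
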