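"""Selective ensemble construction: correctness profiles, K-Means
preselection, and forward sequential selection with circulating target
relaxation (EFSS), fused by majority vote.

The pipeline:

1. every base learner produces out-of-fold predictions under a shared
   stratified fold map; the binary **correctness matrix** ``B`` (classifiers
   x instances) records which instances each learner got right;
2. K-Means (default k = 9) clusters the rows of ``B`` so that learners with
   similar error profiles co-cluster; the most accurate learner of each
   cluster survives, yielding a small, diverse candidate pool;
3. **EFSS** grows a committee: candidates are visited in descending accuracy
   order, and a candidate joins iff the committee's vote accuracy strictly
   increases and its diversity strictly improves (mean pairwise agreement of
   correctness profiles strictly decreases) — the diversity gate is waived
   while the committee has fewer than two members.  An outer loop relaxes a
   target accuracy from 1 downward in steps of 0.05 and re-circulates the
   candidate list until the best achieved accuracy meets the target.

Committee evaluation during selection reuses the out-of-fold predictions;
no model is refit inside the search.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .base_classifiers import (
    BaseClassifierSpec,
    FittedClassifier,
    OOFPredictions,
    fit,
    oof_predict,
    registry,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12
INF_DIVERSITY = math.inf


@dataclass
class EnsembleConfig:
    """Knobs of the selective ensemble.

    Defaults are the method's stated constants: 18-learner pool, k = 9
    clusters, target-accuracy step 0.05, tenfold out-of-fold evaluation.
    """

    k: int = 9
    step: float = 0.05
    folds: int = 10
    seed: int = 0
    classifier_names: Optional[tuple[str, ...]] = None  # None = full registry


@dataclass
class CorrectnessMatrix:
    """Binary matrix B: B[i, j] = 1 iff classifier i got instance j right."""

    B: np.ndarray
    classifier_names: list[str]
    accuracies: np.ndarray

    def row(self, name: str) -> np.ndarray:
        return self.B[self.classifier_names.index(name)]


@dataclass
class ClusterSelection:
    k: int
    cluster_assignment: dict[str, int]
    selected: list[str]


@dataclass
class EnsembleModel:
    """A fitted committee with majority-vote fusion."""

    members: list[FittedClassifier]
    priors: dict[str, int]            # training-label counts, for vote ties
    trace: list[dict] = field(default_factory=list)
    selection: Optional[ClusterSelection] = None
    oof_vote_predicted: Optional[np.ndarray] = None
    oof_vote_accuracy: Optional[float] = None

    @property
    def member_names(self) -> list[str]:
        return [m.spec.name for m in self.members]

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.stack([m.predict(X) for m in self.members])
        return np.array([_vote(votes[:, j], self.priors) for j in range(votes.shape[1])])

    def predict_with_votes(self, x) -> tuple[str, dict[str, int]]:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        votes = [str(m.predict(x)[0]) for m in self.members]
        tally = dict(Counter(votes))
        return _vote(votes, self.priors), tally


def correctness_matrix(oofs: Sequence[OOFPredictions], y) -> CorrectnessMatrix:
    """Stack out-of-fold correctness indicators, one row per classifier."""
    y = np.asarray(y)
    rows, names = [], []
    for oof in oofs:
        if len(oof.predicted) != len(y):
            raise ValueError(f"{oof.classifier_name}: covers {len(oof.predicted)} "
                             f"instances, expected {len(y)}")
        rows.append((np.asarray(oof.predicted) == y).astype(np.int8))
        names.append(oof.classifier_name)
    B = np.vstack(rows)
    return CorrectnessMatrix(B=B, classifier_names=names, accuracies=B.mean(axis=1))


def cluster_classifiers(B: CorrectnessMatrix, k: int = 9, seed: int = 0) -> ClusterSelection:
    """K-Means over correctness profiles; keep the best row per cluster.

    Euclidean K-Means with 10 restarts on the binary rows of B; within each
    cluster the classifier with the highest out-of-fold accuracy survives
    (ties go to registry order).  Empty clusters contribute nothing.
    """
    n = B.B.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of classifiers {n}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    with warnings.catch_warnings():
        # identical correctness profiles are expected (e.g. two strong
        # learners both all-correct); fewer distinct clusters is fine
        warnings.simplefilter("ignore")
        labels = km.fit_predict(B.B.astype(float))
    assignment = dict(zip(B.classifier_names, (int(c) for c in labels)))
    selected: list[str] = []
    for c in range(k):
        members = [i for i in range(n) if labels[i] == c]
        if not members:
            continue
        best = max(members, key=lambda i: (B.accuracies[i], -i))
        selected.append(B.classifier_names[best])
    selected = [name for name in B.classifier_names if name in set(selected)]
    return ClusterSelection(k=k, cluster_assignment=assignment, selected=selected)


def _vote(votes: Sequence[str], priors: dict[str, int]) -> str:
    """Majority label; ties to higher training frequency, then lexicographic."""
    counts = Counter(votes)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    return min(tied, key=lambda lab: (-priors.get(lab, 0), lab))


def majority_vote(members: Sequence[FittedClassifier], x, priors: dict[str, int]) -> str:
    """Fuse one instance's member predictions by the vote rule."""
    if not members:
        raise ValueError("majority_vote needs at least one member")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return _vote([str(m.predict(x)[0]) for m in members], priors)


def diversity_score(rows: np.ndarray) -> float:
    """Mean pairwise agreement of correctness profiles; lower = more diverse.

    agreement(i, i') = fraction of instances on which rows i and i' agree.
    Committees of fewer than two rows get the +inf sentinel (the "very
    large number" initialization), so the first member always passes the
    diversity gate.
    """
    rows = np.atleast_2d(rows)
    p = rows.shape[0]
    if p < 2:
        return INF_DIVERSITY
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            total += float(np.mean(rows[i] == rows[j]))
    return total / (p * (p - 1) / 2)


def ensemble_success_rate(
    candidate: Sequence[str],
    oofs: dict[str, OOFPredictions],
    y,
    priors: Optional[dict[str, int]] = None,
) -> float:
    """Vote accuracy of a committee over reused out-of-fold predictions."""
    if not candidate:
        raise ValueError("candidate committee is empty")
    y = np.asarray(y)
    if priors is None:
        labels, counts = np.unique(y, return_counts=True)
        priors = dict(zip((str(l) for l in labels), (int(c) for c in counts)))
    votes = np.stack([np.asarray(oofs[name].predicted) for name in candidate])
    fused = np.array([_vote([str(v) for v in votes[:, j]], priors) for j in range(votes.shape[1])])
    return float(np.mean(fused == y.astype(fused.dtype)))


def efss_select(
    selection: ClusterSelection,
    B: CorrectnessMatrix,
    oofs: dict[str, OOFPredictions],
    y,
    step: float = 0.05,
) -> tuple[list[str], list[dict]]:
    """Forward sequential selection with a circulating, relaxing target.

    State: target accuracy TA starts at 1, optimal accuracy OA at 0, the
    committee CC empty with success rate 0 and diversity +inf.  Each outer
    circle re-sorts the candidate pool by accuracy (descending) and walks
    it; the head candidate joins CC iff the committee vote success rate
    strictly increases AND (diversity strictly decreases OR the grown
    committee has fewer than two members).  OA tracks the best success
    rate; while OA < TA, TA drops by *step* and the pool circulates again.
    CC persists across circles.  Returns CC and a per-evaluation trace.
    """
    if not selection.selected:
        raise ValueError("empty classifier selection")
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    priors = dict(zip((str(l) for l in labels), (int(c) for c in counts)))

    order = {name: i for i, name in enumerate(B.classifier_names)}
    sorted_pool = sorted(
        selection.selected, key=lambda nm: (-B.accuracies[order[nm]], order[nm])
    )

    cc: list[str] = []
    cur_success = 0.0
    cur_diversity = INF_DIVERSITY
    oa = 0.0
    trace: list[dict] = []

    circle = 0
    while True:
        ta = 1.0 - circle * step
        if ta < -_EPS or oa >= ta - _EPS:
            break
        sc = list(sorted_pool)
        while sc and cur_success < ta - _EPS:
            c0 = sc.pop(0)
            cand = cc + [c0] if c0 not in cc else cc
            success = ensemble_success_rate(cand, oofs, y, priors)
            rows = B.B[[order[nm] for nm in cand]]
            div = diversity_score(rows)
            accepted = (
                c0 not in cc
                and success > cur_success + _EPS
                and (div < cur_diversity - _EPS or len(cand) < 2)
            )
            trace.append({
                "TA": round(ta, 10), "candidate": c0, "success": success,
                "diversity": div, "accepted": accepted, "committee_size": len(cc),
            })
            if accepted:
                cc.append(c0)
                cur_success = success
                cur_diversity = div
        oa = max(oa, cur_success)
        circle += 1

    if not cc:
        # degenerate pool (e.g. every candidate at accuracy 0): fall back to
        # the accuracy-sorted head so the committee is never empty
        cc = [sorted_pool[0]]
        logger.warning("EFSS accepted no classifier; falling back to %s", cc[0])
    return cc, trace


def fit_ensemble(X, y, config: Optional[EnsembleConfig] = None) -> EnsembleModel:
    """The full selective-ensemble build on a labeled feature matrix.

    Out-of-fold predictions for the whole pool -> correctness matrix ->
    K-Means preselection -> EFSS committee -> chosen members refit on all
    of (X, y).  Deterministic given the config seed.
    """
    cfg = config or EnsembleConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_ensemble requires at least 2 classes")
    specs = registry(cfg.seed, cfg.classifier_names)
    oof_list = [oof_predict(s, X, y, folds=cfg.folds, seed=cfg.seed) for s in specs]
    oofs = {o.classifier_name: o for o in oof_list}
    B = correctness_matrix(oof_list, y)
    k = min(cfg.k, len(specs))
    if k < cfg.k:
        logger.info("clamping k from %d to pool size %d", cfg.k, k)
    selection = cluster_classifiers(B, k=k, seed=cfg.seed)
    chosen, trace = efss_select(selection, B, oofs, y, step=cfg.step)

    spec_by_name = {s.name: s for s in specs}
    members = [fit(spec_by_name[nm], X, y) for nm in chosen]
    labels, counts = np.unique(y, return_counts=True)
    priors = dict(zip((str(l) for l in labels), (int(c) for c in counts)))

    votes = np.stack([np.asarray(oofs[nm].predicted) for nm in chosen])
    fused = np.array([_vote([str(v) for v in votes[:, j]], priors) for j in range(votes.shape[1])])
    model = EnsembleModel(
        members=members, priors=priors, trace=trace, selection=selection,
        oof_vote_predicted=fused, oof_vote_accuracy=float(np.mean(fused == y)),
    )
    return model
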