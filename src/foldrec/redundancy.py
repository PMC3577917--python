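"""Sequence redundancy reduction.

Three reductions are provided, matching the three ways a training set is
made non-homogeneous before model fitting:

* ``identity_filter`` — greedy Hobohm-style representative selection at a
  percent-identity threshold (typical thresholds 20/35/40/70/95%);
* ``edit_distance_filter`` — remove the shorter member of every pair within
  Levenshtein distance ``d`` (typical d in {0, 1, 3, 5, 10});
* ``family_longest`` — keep the single longest sequence of each family.

Pairwise identity is computed on an optimal global alignment
(match/mismatch/gap = 1/0/-1); capped edit distance uses a banded
dynamic program (edlib) that exits early once the distance provably
exceeds the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import edlib
from Bio import Align

from .sequence_io import LabeledDataset, SequenceRecord

__all__ = [
    "RedundancyReport",
    "pairwise_identity",
    "identity_filter",
    "edit_distance",
    "edit_distance_filter",
    "family_longest",
]


@dataclass
class RedundancyReport:
    input_count: int
    kept_count: int
    removed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    method: str = ""
    threshold: float = 0.0

    def to_rows(self) -> list[dict]:
        return [
            {"kept_id": k, "removed_id": r, "value": v, "method": self.method,
             "threshold": self.threshold}
            for k, r, v in self.removed_pairs
        ]


_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=0,
    open_gap_score=-1, extend_gap_score=-1,
)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Identical positions / alignment length in an optimal global alignment.

    The alignment maximizes match=+1, mismatch=0, linear gap=-1; the score
    itself is discarded — it only picks the alignment.
    """
    if not a.residues or not b.residues:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aln = _aligner.align(a.residues, b.residues)[0]
    return aln.counts().identities / aln.length


def _length_priority(records: list[SequenceRecord]) -> list[SequenceRecord]:
    return sorted(records, key=lambda r: (-len(r), r.id))


def identity_filter(
    dataset: LabeledDataset, threshold: float
) -> tuple[LabeledDataset, RedundancyReport]:
    """Greedy Hobohm selection at a percent-identity *threshold* in (0, 100].

    Sequences are visited longest first (ties by id); a sequence is accepted
    iff its identity to every already-accepted sequence is below
    ``threshold/100``.  The accepted set is returned in original order, and
    every kept pair is guaranteed below threshold.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    frac = threshold / 100.0
    accepted: list[SequenceRecord] = []
    removed: list[tuple[str, str, float]] = []
    for rec in _length_priority(list(dataset)):
        blocker = None
        for kept in accepted:
            ident = pairwise_identity(kept, rec)
            if ident >= frac:
                blocker = (kept.id, rec.id, ident)
                break
        if blocker is None:
            accepted.append(rec)
        else:
            removed.append(blocker)
    kept_ids = {r.id for r in accepted}
    out = LabeledDataset(
        records=[r for r in dataset if r.id in kept_ids],
        provenance=f"{dataset.provenance} | identity_filter<{threshold}%",
    )
    return out, RedundancyReport(len(dataset), len(out), removed, "identity", threshold)


def edit_distance(a: SequenceRecord, b: SequenceRecord, cap: int) -> Optional[int]:
    """Unit-cost Levenshtein distance, or None if it exceeds *cap*.

    The length difference is a free lower bound; otherwise a banded DP
    (edlib) computes the distance, abandoning the band once the distance is
    provably greater than the cap.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if abs(len(a) - len(b)) > cap:
        return None
    d = edlib.align(a.residues, b.residues, task="distance", k=cap)["editDistance"]
    return None if d == -1 else d


def edit_distance_filter(
    dataset: LabeledDataset, d: int
) -> tuple[LabeledDataset, RedundancyReport]:
    """Remove the shorter member of every pair within edit distance *d*.

    Sequences are processed longest first (ties by id, so of an equal-length
    close pair the lexicographically later id is removed); a sequence is
    dropped iff it lies within distance ``d`` of an already-kept sequence,
    which resolves transitive chains deterministically.
    """
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, str, float]] = []
    for rec in _length_priority(list(dataset)):
        blocker = None
        for k in kept:
            dist = edit_distance(k, rec, cap=d)
            if dist is not None:
                blocker = (k.id, rec.id, float(dist))
                break
        if blocker is None:
            kept.append(rec)
        else:
            removed.append(blocker)
    kept_ids = {r.id for r in kept}
    out = LabeledDataset(
        records=[r for r in dataset if r.id in kept_ids],
        provenance=f"{dataset.provenance} | edit_distance_filter<={d}",
    )
    return out, RedundancyReport(len(dataset), len(out), removed, "edit_distance", d)


def family_longest(dataset: LabeledDataset) -> tuple[LabeledDataset, RedundancyReport]:
    """Keep exactly one record per family: the longest, ties by id."""
    best: dict[str, SequenceRecord] = {}
    for rec in dataset:
        if rec.label is None or rec.label.family_id is None:
            raise ValueError(f"record {rec.id} has no family_id")
        fam = rec.label.family_id
        cur = best.get(fam)
        if cur is None or (len(rec), ) > (len(cur), ) or (len(rec) == len(cur) and rec.id < cur.id):
            best[fam] = rec
    kept_ids = {r.id for r in best.values()}
    removed = [
        (best[rec.label.family_id].id, rec.id, float(len(rec)))
        for rec in dataset if rec.id not in kept_ids
    ]
    out = LabeledDataset(
        records=[r for r in dataset if r.id in kept_ids],
        provenance=f"{dataset.provenance} | family_longest",
    )
    return out, RedundancyReport(len(dataset), len(out), removed, "family_longest", 0)
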