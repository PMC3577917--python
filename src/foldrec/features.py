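"""The 188-dimensional sequence descriptor.

The vector concatenates amino-acid composition (20 values) with, for each
of eight physicochemical properties, a CTD-style block of 21 values
computed over a fixed 3-way partition of the alphabet:

* **content** (3): fraction of residues in each group;
* **distribution** (15): for each group, the normalized sequence positions
  at which the first, 25%, 50%, 75% and 100% of that group's residues have
  appeared;
* **bivalent frequency** (3): among the ``L-1`` adjacent residue pairs
  ("bivalent seeds"), the fraction whose two residues fall in distinct
  groups, one value per unordered group pair (1,2), (1,3), (2,3).

20 + 8 x 21 = 188.  All values lie in [0, 1] and are length-normalized, so
sequences of different lengths are directly comparable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .sequence_io import AMINO_ACIDS, AA_INDEX, HierLabel, LabeledDataset, SequenceRecord

logger = logging.getLogger(__name__)

N_FEATURES = 188


@dataclass(frozen=True)
class PropertyGrouping:
    """A physicochemical property's 3-way partition of the 20 residues."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.groups)
        if sorted(joined) != sorted(AMINO_ACIDS):
            raise ValueError(f"{self.name}: groups must partition the 20 standard residues")

    def group_of(self) -> np.ndarray:
        """Array mapping alphabetical residue index -> group index 0/1/2."""
        out = np.empty(20, dtype=np.intp)
        for g, members in enumerate(self.groups):
            for aa in members:
                out[AA_INDEX[aa]] = g
        return out


#: The eight default property partitions, in fixed row order.  Each row
#: lists the property's three residue groups.
PROPERTY_GROUPINGS: tuple[PropertyGrouping, ...] = (
    PropertyGrouping("hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")),
    PropertyGrouping("normalized_vdw_volume", ("GASCTPD", "NVEQIL", "MHKFRYW")),
    PropertyGrouping("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    PropertyGrouping("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    PropertyGrouping("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    PropertyGrouping("surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")),
    PropertyGrouping("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    PropertyGrouping("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")),
)

_GROUP_MAPS = {g.name: g.group_of() for g in PROPERTY_GROUPINGS}
_QUANTILES = (0.0, 0.25, 0.50, 0.75, 1.0)  # 0.0 stands for "first occurrence"


@dataclass
class FeatureMatrix:
    """Stacked 188D vectors: one row per sequence id."""

    ids: list[str]
    values: np.ndarray
    labels: Optional[list[Optional[HierLabel]]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v.reshape(0, N_FEATURES) if not len(self.ids) else v.reshape(len(self.ids), -1)
        if len(self.ids) and self.values.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} columns, got {self.values.shape[1]}")

    def __len__(self) -> int:
        return len(self.ids)


def _codes(record: SequenceRecord) -> np.ndarray:
    try:
        return np.array([AA_INDEX[ch] for ch in record.residues], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"{record.id}: non-standard residue {e.args[0]!r}; sanitize first") from None


def composition(record: SequenceRecord) -> np.ndarray:
    """Per-residue frequency n_i / L, alphabetical order. Sums to 1."""
    if len(record) == 0:
        raise ValueError(f"{record.id}: empty sequence")
    counts = np.bincount(_codes(record), minlength=20)
    return counts / len(record)


def content(record: SequenceRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Fraction of residues in each of the property's 3 groups. Sums to 1."""
    if len(record) == 0:
        raise ValueError(f"{record.id}: empty sequence")
    gidx = grouping.group_of()[_codes(record)]
    return np.bincount(gidx, minlength=3) / len(record)


def distribution(record: SequenceRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Positional distribution of each group along the chain (15 values).

    For a group occurring at 1-based positions p_1 <= ... <= p_c the five
    values are p_1/L, p_ceil(.25c)/L, p_ceil(.5c)/L, p_ceil(.75c)/L, p_c/L.
    A group with no occurrences contributes five zeros.
    """
    if len(record) == 0:
        raise ValueError(f"{record.id}: empty sequence")
    L = len(record)
    gidx = grouping.group_of()[_codes(record)]
    out = np.zeros(15)
    for g in range(3):
        positions = np.flatnonzero(gidx == g) + 1  # 1-based
        c = len(positions)
        if c == 0:
            continue
        for j, q in enumerate(_QUANTILES):
            k = max(1, math.ceil(q * c))
            out[5 * g + j] = positions[k - 1] / L
    return out


def bivalent_frequency(record: SequenceRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Cross-group adjacent-pair frequencies (3 values).

    The L-1 adjacent residue pairs are scanned; pairs whose two residues lie
    in distinct groups are counted per unordered group pair (1,2), (1,3),
    (2,3) and divided by L-1.  Same-group pairs count nowhere.
    """
    L = len(record)
    if L < 2:
        raise ValueError(f"{record.id}: need length >= 2 for bivalent features, got {L}")
    gidx = grouping.group_of()[_codes(record)]
    left, right = gidx[:-1], gidx[1:]
    lo = np.minimum(left, right)
    hi = np.maximum(left, right)
    out = np.zeros(3)
    out[0] = np.count_nonzero((lo == 0) & (hi == 1))
    out[1] = np.count_nonzero((lo == 0) & (hi == 2))
    out[2] = np.count_nonzero((lo == 1) & (hi == 2))
    return out / (L - 1)


def extract_188(record: SequenceRecord) -> np.ndarray:
    """The full 188D vector for one sanitized sequence of length >= 2.

    Layout: FV1-FV20 composition, then per property (fixed row order)
    content (3) + distribution (15) + bivalent frequency (3); e.g.
    FV21-FV23 / FV24-FV38 / FV39-FV41 are the hydrophobicity block.
    """
    parts = [composition(record)]
    for grouping in PROPERTY_GROUPINGS:
        parts.append(content(record, grouping))
        parts.append(distribution(record, grouping))
        parts.append(bivalent_frequency(record, grouping))
    vec = np.concatenate(parts)
    assert vec.shape == (N_FEATURES,)
    return vec


def extract_matrix(dataset: LabeledDataset) -> FeatureMatrix:
    """Extract one row per eligible record, in dataset order.

    Records shorter than 2 residues are skipped with a warning.
    """
    ids, rows, labels = [], [], []
    for rec in dataset:
        if len(rec) < 2:
            logger.warning("skipping %s: length %d < 2", rec.id, len(rec))
            continue
        ids.append(rec.id)
        rows.append(extract_188(rec))
        labels.append(rec.label)
    values = np.vstack(rows) if rows else np.empty((0, N_FEATURES))
    return FeatureMatrix(ids=ids, values=values, labels=labels)


def feature_dictionary() -> list[dict]:
    """Machine-readable layout: index (1-based) -> descriptor coordinates."""
    entries: list[dict] = []
    for i, aa in enumerate(AMINO_ACIDS, start=1):
        entries.append({"index": i, "property": "composition", "descriptor": "composition",
                        "group": aa, "quantile": None})
    idx = 21
    pair_names = ("1-2", "1-3", "2-3")
    for grouping in PROPERTY_GROUPINGS:
        for g in range(3):
            entries.append({"index": idx, "property": grouping.name, "descriptor": "content",
                            "group": g + 1, "quantile": None})
            idx += 1
        for g in range(3):
            for q in ("first", "25%", "50%", "75%", "100%"):
                entries.append({"index": idx, "property": grouping.name,
                                "descriptor": "distribution", "group": g + 1, "quantile": q})
                idx += 1
        for pair in pair_names:
            entries.append({"index": idx, "property": grouping.name,
                            "descriptor": "bivalent_frequency", "group": pair, "quantile": None})
            idx += 1
    assert idx == N_FEATURES + 1
    return entries
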