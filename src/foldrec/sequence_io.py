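"""Sequence and label I/O.

Protein chains are plain FASTA; hierarchical structure labels (SCOP-style
``class.fold``, e.g. ``a.1``) live in a sidecar TSV ``id <tab> fold_id
[<tab> family_id]``.  A header-embedded dialect ``>id|a.1`` is accepted as a
fallback when no label table is given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical by one-letter code.  This ordering
#: is used everywhere a per-residue vector is laid out.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The seven structural class codes (all-alpha .. small proteins).
CLASS_CODES = "abcdefg"

#: Replacement map for common ambiguity codes under the ``map_ambiguous``
#: sanitization policy.  X has no single-residue reading and is dropped.
AMBIGUOUS_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K"}


class SanitizePolicy(str, Enum):
    """How to treat characters outside the 20 standard residue codes."""

    DROP_RESIDUE = "drop_residue"
    DROP_SEQUENCE = "drop_sequence"
    MAP_AMBIGUOUS = "map_ambiguous"


@dataclass(frozen=True)
class HierLabel:
    """A hierarchical structure label: class, optionally fold and family.

    ``fold_id`` is the dotted form ``<class>.<n>`` and is always prefixed by
    ``class_id``; ``family_id`` extends the fold id further.
    """

    class_id: str
    fold_id: Optional[str] = None
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fold_id is not None and not self.fold_id.startswith(self.class_id):
            raise ValueError(
                f"fold_id {self.fold_id!r} is not prefixed by class_id {self.class_id!r}"
            )

    @classmethod
    def parse(cls, text: str, family_id: Optional[str] = None) -> "HierLabel":
        """Parse ``"a"`` or ``"a.1"`` into a label."""
        text = text.strip()
        if not text:
            raise ValueError("empty label")
        class_id = text.split(".", 1)[0]
        fold_id = text if "." in text else None
        return cls(class_id=class_id, fold_id=fold_id, family_id=family_id)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein chain: identifier, residue string, optional label."""

    id: str
    residues: str
    label: Optional[HierLabel] = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """An ordered collection of records with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sequence id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if r.label is not None:
                out[r.label.class_id] = out.get(r.label.class_id, 0) + 1
        return out

    def fold_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if r.label is not None and r.label.fold_id is not None:
                out[r.label.fold_id] = out.get(r.label.fold_id, 0) + 1
        return out


def sanitize(
    record: SequenceRecord,
    policy: SanitizePolicy = SanitizePolicy.MAP_AMBIGUOUS,
) -> Optional[SequenceRecord]:
    """Return *record* restricted to the 20 standard residues, or None.

    Residues are uppercased first.  Under ``drop_residue`` non-standard
    characters are removed; under ``map_ambiguous`` the B/Z/U/O ambiguity
    codes are mapped to D/E/C/K and anything else non-standard (including X)
    is dropped; under ``drop_sequence`` any non-standard character discards
    the whole record.  A record left empty is discarded with a warning.
    """
    policy = SanitizePolicy(policy)
    out = []
    for ch in record.residues.upper():
        if ch in AA_INDEX:
            out.append(ch)
            continue
        if policy is SanitizePolicy.DROP_SEQUENCE:
            logger.warning("dropping sequence %s: non-standard residue %r", record.id, ch)
            return None
        if policy is SanitizePolicy.MAP_AMBIGUOUS and ch in AMBIGUOUS_MAP:
            out.append(AMBIGUOUS_MAP[ch])
        # else: drop the character
    cleaned = "".join(out)
    if not cleaned:
        logger.warning("dropping sequence %s: empty after sanitization", record.id)
        return None
    if cleaned == record.residues:
        return record
    return replace(record, residues=cleaned)


def read_label_table(path: str | Path) -> dict[str, HierLabel]:
    """Read the sidecar TSV ``id <tab> fold_id [<tab> family_id]``."""
    labels: dict[str, HierLabel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}")
            family = parts[2] if len(parts) > 2 and parts[2] else None
            labels[parts[0]] = HierLabel.parse(parts[1], family_id=family)
    return labels


def write_label_table(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in dataset:
            if r.label is None:
                continue
            fold = r.label.fold_id or r.label.class_id
            fam = r.label.family_id or ""
            fh.write(f"{r.id}\t{fold}\t{fam}\n" if fam else f"{r.id}\t{fold}\n")


def read_fasta(
    path: str | Path,
    label_table: Optional[str | Path] = None,
    policy: SanitizePolicy = SanitizePolicy.MAP_AMBIGUOUS,
) -> LabeledDataset:
    """Read a FASTA file (and optional label table) into a dataset.

    Labels are joined by id from *label_table* when given; otherwise a
    header of the form ``id|a.1`` is treated as carrying the label.
    Records are sanitized with *policy*; records that sanitize to nothing
    are skipped with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        # SimpleFastaParser silently skips any text before the first '>';
        # reject it explicitly so truncated files fail loudly.
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected FASTA header line, got {line.strip()!r}")
            break
        fh.seek(0)
        entries = list(SimpleFastaParser(fh))

    labels = read_label_table(label_table) if label_table else None

    records = []
    for title, seq in entries:
        header_id = title.split()[0]
        label: Optional[HierLabel] = None
        if labels is not None:
            label = labels.get(header_id)
        elif "|" in header_id:
            header_id, _, label_text = header_id.partition("|")
            try:
                label = HierLabel.parse(label_text)
            except ValueError:
                label = None
        rec = sanitize(SequenceRecord(id=header_id, residues=seq), policy)
        if rec is not None:
            records.append(replace(rec, label=label))
    return LabeledDataset(records=records, provenance=f"read_fasta({path.name})")


def write_fasta(dataset: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in dataset:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def write_feature_table(matrix, path: str | Path) -> None:
    """Write a FeatureMatrix as TSV: id column + FV1..FV188 header.

    Values are written with 12 significant digits so a read round-trips.
    """
    n_feat = matrix.values.shape[1] if len(matrix.values.shape) == 2 else 0
    if len(matrix.ids) and n_feat != 188:
        raise ValueError(f"feature table must have 188 columns, got {n_feat}")
    cols = [f"FV{i}" for i in range(1, 189)]
    df = pd.DataFrame(matrix.values.reshape(-1, 188) if len(matrix.ids) else [],
                      columns=cols, index=pd.Index(matrix.ids, name="id"))
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_feature_table(path: str | Path):
    """Read a TSV written by :func:`write_feature_table`."""
    from .features import FeatureMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col="id")
    expected = [f"FV{i}" for i in range(1, 189)]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: not a 188-column feature table")
    return FeatureMatrix(ids=[str(i) for i in df.index], values=df.to_numpy(float), labels=None)
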