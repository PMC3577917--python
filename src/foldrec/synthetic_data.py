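"""Synthetic class/fold-labeled sequence generator.

Real training data for fold recognition carries exactly the statistical
structure the 188D featurizer exploits: different structural classes and
folds have systematically different residue compositions.  The generator
emulates that — and only that — so every pipeline stage is testable
without any external database:

* each class gets a residue-frequency profile drawn around a common base,
  each fold a perturbation of its class profile; a ``separation`` scalar
  interpolates between "all profiles identical" (0) and fully divergent
  profiles, and a Dirichlet ``concentration`` controls profile sharpness
  (smaller = spikier, easier to tell apart);
* sequences are sampled i.i.d. from their fold profile at uniform random
  lengths, so composition/content/bivalent features carry signal;
* an optional ``motif`` mode additionally plants a fold-specific
  homogeneous residue block at a fold-specific relative position, which
  moves the positional-distribution descriptors specifically;
* a ``redundancy_rate`` fraction of sequences is re-emitted as point-mutated
  near-duplicates (sharing a family id with their original), giving the
  redundancy filters known ground truth.

It makes no attempt to simulate real protein evolution, secondary
structure, or the true fold-size distribution of any database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .sequence_io import AMINO_ACIDS, CLASS_CODES, HierLabel, LabeledDataset, SequenceRecord

#: Default folds per class, loosely proportional to the relative fold
#: richness of the seven structural classes (all-alpha .. small proteins).
DEFAULT_FOLDS_PER_CLASS = (6, 4, 3, 8, 2, 2, 2)


@dataclass
class GeneratorConfig:
    n_classes: int = 7
    folds_per_class: Union[int, Sequence[int]] = DEFAULT_FOLDS_PER_CLASS
    seqs_per_fold: int = 10
    length_range: tuple[int, int] = (50, 300)
    concentration: float = 1.0
    separation: float = 1.0
    redundancy_rate: float = 0.0
    mutations_per_copy: int = 1
    motif: bool = False
    motif_length: int = 12
    seed: int = 0

    def folds_of(self) -> list[int]:
        if isinstance(self.folds_per_class, int):
            return [self.folds_per_class] * self.n_classes
        fp = list(self.folds_per_class)[: self.n_classes]
        if len(fp) < self.n_classes:
            fp += [fp[-1]] * (self.n_classes - len(fp))
        return fp

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= len(CLASS_CODES):
            raise ValueError(f"n_classes must be in [1, {len(CLASS_CODES)}]")
        if self.seqs_per_fold < 1 or any(f < 1 for f in self.folds_of()):
            raise ValueError("counts must be >= 1")
        if not 0 <= self.redundancy_rate <= 1:
            raise ValueError("redundancy_rate must be in [0, 1]")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= lo <= hi")


def make_profiles(cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Per-fold residue frequency profiles, keyed by fold id (e.g. "a.1").

    A common base profile (uniform over the 20 residues) anchors everything;
    class profiles are Dirichlet draws pulled away from the base by
    ``separation`` and fold profiles are smaller perturbations of their
    class profile.  With separation 0 every profile equals the base.
    """
    rng = np.random.default_rng(cfg.seed)
    base = np.full(20, 1 / 20)
    alpha = np.full(20, cfg.concentration)
    profiles: dict[str, np.ndarray] = {}
    for ci, n_folds in enumerate(cfg.folds_of()):
        cls = CLASS_CODES[ci]
        class_draw = rng.dirichlet(alpha)
        class_profile = _blend(base, class_draw, cfg.separation)
        for fi in range(1, n_folds + 1):
            fold_draw = rng.dirichlet(alpha)
            profiles[f"{cls}.{fi}"] = _blend(class_profile, fold_draw, 0.5 * cfg.separation)
    return profiles


def _blend(anchor: np.ndarray, draw: np.ndarray, scale: float) -> np.ndarray:
    p = anchor + scale * (draw - anchor)
    p = np.clip(p, 1e-9, None)
    return p / p.sum()


def sample_dataset(
    cfg: GeneratorConfig,
    profiles: Optional[dict[str, np.ndarray]] = None,
    seed: Optional[int] = None,
) -> tuple[LabeledDataset, dict]:
    """Draw a labeled dataset from fold profiles; returns (dataset, truth).

    *profiles* defaults to ``make_profiles(cfg)``; pass the same profiles
    with different *seed* values to obtain train/test splits from identical
    generating distributions.  The truth manifest records the profiles, any
    injected duplicate pairs, and planted motif descriptions.
    """
    if profiles is None:
        profiles = make_profiles(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.length_range
    aa = np.array(list(AMINO_ACIDS))

    records: list[SequenceRecord] = []
    motifs: dict[str, dict] = {}
    for fold_id, profile in profiles.items():
        cls = fold_id.split(".")[0]
        if cfg.motif:
            motif_res = aa[rng.integers(0, 20)]
            motif_pos = float(rng.uniform(0.1, 0.9))
            motifs[fold_id] = {"residue": str(motif_res), "relative_position": motif_pos}
        for s in range(cfg.seqs_per_fold):
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(aa, size=L, p=profile))
            if cfg.motif:
                start = min(max(0, int(motifs[fold_id]["relative_position"] * L)),
                            max(0, L - cfg.motif_length))
                block = motifs[fold_id]["residue"] * min(cfg.motif_length, L)
                seq = seq[:start] + block + seq[start + len(block):]
            rid = f"{fold_id}_s{len(records):04d}"
            fam = f"{fold_id}.f{s:03d}"
            records.append(SequenceRecord(
                id=rid, residues=seq,
                label=HierLabel(class_id=cls, fold_id=fold_id, family_id=fam),
            ))

    duplicate_pairs: list[tuple[str, str]] = []
    n_dup = int(round(cfg.redundancy_rate * len(records)))
    if n_dup:
        originals = rng.choice(len(records), size=n_dup, replace=False)
        for i in sorted(int(i) for i in originals):
            src = records[i]
            seq = list(src.residues)
            for _ in range(cfg.mutations_per_copy):
                pos = int(rng.integers(0, len(seq)))
                seq[pos] = str(aa[rng.integers(0, 20)])
            dup_id = f"{src.id}_dup"
            records.append(replace(src, id=dup_id, residues="".join(seq)))
            duplicate_pairs.append((src.id, dup_id))

    dataset = LabeledDataset(records=records, provenance=f"synthetic(seed={cfg.seed})")
    truth = {
        "profiles": {k: v.tolist() for k, v in profiles.items()},
        "duplicate_pairs": duplicate_pairs,
        "motifs": motifs,
    }
    return dataset, truth
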