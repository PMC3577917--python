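# Methods

## Featurizer

The descriptor treats a protein chain as a string over the 20 standard
one-letter codes, ordered alphabetically (`A C D E F G H I K L M N P Q R S
T V W Y`) wherever a per-residue layout is needed. The eight
physicochemical 3-way partitions are frozen in
`features.PROPERTY_GROUPINGS`; each partition is validated at construction
(disjoint groups, union exactly the 20 residues).

Numerical conventions, chosen once and applied uniformly:

- All descriptors are length-normalized (÷*L* for composition, content and
  distribution positions; ÷(*L*−1) for bivalent frequencies), so every
  feature lies in [0, 1] and sequences of different lengths are comparable.
- The distribution descriptor's quantile index is ⌈p·c⌉ with a floor of 1,
  where *c* is the group's occurrence count — the standard CTD convention;
  it is exact for the "first" and "100%" anchors and makes each group's
  five-tuple non-decreasing.
- A group with no occurrences contributes five zeros (and zero content);
  no sentinel values, so the [0, 1] range is preserved.
- Bivalent (adjacent-pair) counts are unordered: the pair (group 1, group
  2) is the same event as (group 2, group 1), giving exactly three
  cross-group parameters per property; same-group pairs are counted
  nowhere, so the three frequencies sum to at most 1.
- Sequences must be sanitized first (policies: drop offending residues,
  drop the sequence, or map the B/Z/U/O ambiguity codes to D/E/C/K and drop
  X — the default, since it preserves data). Length ≥ 2 is required
  because bivalent features need at least one adjacent pair.

A brute-force re-implementation of the full 188-value definition (plain
loops, no shared code) lives in the test suite and must agree with the
vectorized extractor *exactly* — not approximately — on random sequences.

## Base-classifier pool

The selection layer is deliberately agnostic to the identity of the base
learners: its contract is a pool of 18 diverse, deterministic classifiers.
The registry maps the 18 classical algorithm names to documented
nearest-analog implementations (scikit-learn estimators; the `SMO`/`SVM`
pair is realized as linear-kernel vs RBF-kernel support vector machines).
ZeroR (majority class), OneR (single-attribute rule over equal-frequency
bins) and Decision Stump (exhaustive one-split search) are implemented
natively; they are small enough to verify against hand-computed rules and
anchor the low end of the accuracy spectrum. No behavioral parity with any
historical third-party implementation is attempted or needed, and no
hyperparameter tuning is done: defaults are fixed in the registry, with a
per-entry override hook in the config.

Out-of-fold prediction uses a stratified fold map computed from `(y, folds,
seed)` only — never from X — by dealing each class's shuffled members
cyclically across folds with a per-class offset. Classes smaller than the
fold count are spread as evenly as possible rather than rejected. All 18
classifiers consume the identical fold map, which is what makes their
correctness profiles comparable.

## Selective ensemble

- **Correctness matrix** `B`: rows are classifiers, columns instances,
  entries 1 iff the out-of-fold prediction was correct; row means equal
  out-of-fold accuracies by construction.
- **Preselection**: Euclidean K-Means on the binary rows (k = 9, 10
  restarts, fixed seed); per cluster the most accurate classifier survives
  (ties to registry order); empty clusters contribute nothing. When the
  pool is restricted below k, k is clamped to the pool size.
- **Diversity** is mean pairwise agreement of correctness rows (lower =
  more diverse). Committees of fewer than two members get +∞, realizing
  the "very large number" initialization and guaranteeing the first
  accepted member passes the gate.
- **EFSS**: target accuracy TA starts at 1 and relaxes by 0.05 per circle;
  each circle walks the accuracy-sorted candidate list and accepts the
  head iff vote success *strictly* increases and (diversity *strictly*
  decreases or the committee has fewer than two members); ties reject.
  The chosen committee persists across circles — only the candidate list
  is reset. Committee evaluation reuses the out-of-fold predictions (no
  refit inside the search), which both avoids resubstitution optimism and
  keeps selection at zero extra model fits. The loop terminates because TA
  reaches −0.05 after 21 circles even if no acceptable candidate exists;
  in that degenerate case (every candidate at zero accuracy) the committee
  falls back to the accuracy-sorted head so it is never empty.
- **Vote fusion**: majority over hard labels; ties break toward the label
  with the higher training frequency, then lexicographically. There is no
  weighted or probabilistic fusion and no per-instance dynamic selection.

An exhaustive oracle in the tests replays every acceptance against
independently recomputed success and diversity over all 4,096 binary 3×4
matrices and random pools up to 5×8, and checks the final committee's vote
accuracy is never below the best single selected classifier.

## Hierarchy

Layer-2 models are trained on **true**-class members only, keeping the two
layers independent; a class with fewer than two records or a single
observed fold gets a constant predictor. Routing is hard: the layer-1
class picks the layer-2 model, so a layer-1 error makes the fold prediction
wrong by construction (the per-layer vote tallies are exposed for anyone
who wants to add a reject option). Reported metrics: layer-1 accuracy,
per-class layer-2 accuracy conditional on the true class (matching how
per-subset accuracies are measured when each subset is trained and
evaluated within itself), and end-to-end accuracy (both layers correct),
which is bounded above by layer-1 accuracy and by the class-weighted mean
of layer-2 accuracies. With *N* equiprobable folds and an uninformative
layer 2, end-to-end accuracy sits near layer-1 accuracy / *N*.

## Redundancy filters

- **Identity**: greedy Hobohm-style selection, longest sequence first
  (ties by id), accepting a sequence iff its identity to every accepted
  sequence is below the threshold. Identity is identical positions over
  alignment length in an optimal global alignment under match/mismatch/gap
  = 1/0/−1 — the score only picks the alignment. The output is provably
  internally non-redundant and the filter is idempotent.
- **Edit distance**: unit-cost Levenshtein with a cap, computed by a banded
  dynamic program (edlib) that abandons once the distance provably exceeds
  the cap; the length difference is used as a free pre-filter. The filter
  removes the shorter member of every pair within distance *d*, processing
  longest-first so transitive chains resolve deterministically: a sequence
  is removed only if it is close to a *kept* sequence. An all-pairs join
  is used; sub-quadratic signature indexing is deliberately out of scope at
  the package's working scale.
- **Family-longest**: one record per family id, the longest (ties by id).

Whether identity filtering should be applied globally or per class is not
fixed by the method; the filters operate on whatever dataset they are
given, so either protocol is a one-line composition.

## Evaluation harness

`crossval` defaults to **nested** mode: the entire ensemble build,
including selection from internal out-of-fold predictions, is rerun inside
each training split — the honest generalization estimate. **Reuse** mode
scores the committee's internal out-of-fold vote directly; it reproduces
the cheaper protocol and is reported as such in the `CVReport.mode` field.
The PCA report decomposes the feature **correlation** matrix (so it is
invariant to per-column affine rescaling); zero-variance columns are
dropped with a notice, eigenvalues are reported in descending order with
percent and cumulative contributions, components with eigenvalue above the
threshold (default 3) are retained, and each retained component lists its
top features by absolute loading (unit-norm eigenvector entries).

## Synthetic data

The generator emulates exactly the statistical structure the featurizer
exploits: class- and fold-specific residue composition. A uniform base
profile anchors everything; class profiles are symmetric-Dirichlet draws
pulled away from the base by the `separation` scalar, fold profiles are
half-strength perturbations of their class profile, and sequences are
drawn i.i.d. from their fold profile at uniform random lengths (default
50–300 residues). `concentration` (Dirichlet α, default 1.0) controls
profile sharpness — smaller is spikier and easier to separate. With
`separation=0` every profile collapses to the base and the data carry no
signal. Defaults are 7 classes with fold counts (6, 4, 3, 8, 2, 2, 2) —
loosely proportional to the relative fold richness of the seven real
structural classes, so class imbalance is exercised — and 10 sequences per
fold.

Composition-only signal suffices because 173 of the 188 features are
order-insensitive; an optional `motif` mode plants a fold-specific
homogeneous block at a fold-specific relative position to move the
positional-distribution descriptors specifically. `redundancy_rate`
re-emits that fraction of sequences as point-mutated near-duplicates
sharing the original's family id, giving the redundancy filters exact
ground truth.

What passing tests on this generator do **not** show: performance on real
proteins. Real folds differ in long-range contact topology, not only in
composition; the generator has no evolutionary correlation, no secondary
structure, and no realistic fold-size distribution. Recovery results here
validate the machinery (featurization, selection, routing, determinism),
not biological accuracy claims.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale — typically 3 classes ×
2–3 folds × 10–12 sequences per fold, lengths 60–150, with the full
18-learner pool (about 8 s per hierarchical fit) or a documented 5–6
learner subset where the extra learners add runtime but no coverage. Every
stochastic component (generator, fold assignment, K-Means restarts,
randomized learners) is driven by explicit integer seeds; identical seeds
reproduce identical correctness matrices, cluster selections, committees,
traces and reports, and this is asserted in the acceptance tests.

## Known limitations

- Nearest-analog base learners: results depend on the pool's diversity,
  not on any specific historical implementation; swapping analogs changes
  committees but not the selection semantics.
- Hard routing: layer-1 errors are unrecoverable by design.
- The all-pairs redundancy joins are quadratic; at hundreds of thousands
  of sequences a signature-indexed join would be needed.
- The ensemble evaluates committees on reused out-of-fold predictions;
  in reuse-mode reporting this estimate is optimistic relative to nested
  cross-validation.
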