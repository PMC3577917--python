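import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import foldrec as fr
from oracles import oracle_levenshtein


def rec(rid, seq, fold=None, family=None):
    label = None
    if fold is not None:
        label = fr.HierLabel(class_id=fold.split(".")[0], fold_id=fold, family_id=family)
    return fr.SequenceRecord(id=rid, residues=seq, label=label)


def dataset(*records):
    return fr.LabeledDataset(records=list(records))


class TestPairwiseIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACDE", "ACDE", 1.0),
        ("AAAA", "CCCC", 0.0),
        ("ACDE", "ACD", 0.75),   # 3 identities / alignment length 4
    ])
    def test_hand_alignments(self, a, b, expected):
        assert fr.pairwise_identity(rec("a", a), rec("b", b)) == pytest.approx(expected)

    def test_symmetric(self):
        a, b = rec("a", "ACDEFGHIKL"), rec("b", "ACDEFGHK")
        assert fr.pairwise_identity(a, b) == pytest.approx(fr.pairwise_identity(b, a))


class TestIdentityFilter:
    def test_identical_pair_keeps_one(self):
        ds = dataset(rec("a", "ACDEFGHIKL"), rec("b", "ACDEFGHIKL"))
        kept, rep = fr.identity_filter(ds, 35)
        assert len(kept) == 1 and rep.kept_count == 1
        assert rep.removed_pairs[0][:2] == ("a", "b")   # tie by id: 'a' kept

    def test_dissimilar_all_kept(self):
        ds = dataset(rec("a", "AAAAAAAAAA"), rec("b", "CCCCCCCCCC"), rec("c", "DDDDDDDDDD"))
        kept, rep = fr.identity_filter(ds, 35)
        assert len(kept) == 3 and not rep.removed_pairs

    def test_greedy_keeps_longer_of_similar_pair(self):
        s1 = rec("s1", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
        s2 = rec("s2", "ACDEFGHIKLMNPQRSTVWYACDEFGHI")  # ~93% identical, shorter
        s3 = rec("s3", "WWWWWWYYYYYWWWWWYYYYY")
        kept, rep = fr.identity_filter(dataset(s1, s2, s3), 35)
        assert kept.ids() == ["s1", "s3"]

    def test_output_internally_nonredundant_and_idempotent(self):
        cfg = fr.GeneratorConfig(n_classes=2, folds_per_class=2, seqs_per_fold=6,
                                 length_range=(20, 40), redundancy_rate=0.3,
                                 mutations_per_copy=1, seed=9)
        ds, _ = fr.sample_dataset(cfg)
        kept, _ = fr.identity_filter(ds, 70)
        for i, a in enumerate(kept):
            for b in list(kept)[i + 1:]:
                assert fr.pairwise_identity(a, b) < 0.70
        again, rep2 = fr.identity_filter(kept, 70)
        assert again.ids() == kept.ids() and not rep2.removed_pairs

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            fr.identity_filter(dataset(rec("a", "ACDE")), 0)


class TestEditDistance:
    @pytest.mark.parametrize("a,b,cap,expected", [
        ("ACD", "ACE", 3, 1),
        ("ACD", "ACD", 0, 0),
        ("ACD", "ACDEFGH", 2, None),   # length bound alone exceeds cap
        ("AAAA", "CCCC", 3, None),     # banded DP exceeds cap
    ])
    def test_capped_cases(self, a, b, cap, expected):
        assert fr.edit_distance(rec("a", a), rec("b", b), cap=cap) == expected

    @given(st.text(alphabet="ACDEG", min_size=1, max_size=12),
           st.text(alphabet="ACDEG", min_size=1, max_size=12),
           st.integers(min_value=0, max_value=12))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_full_matrix_oracle(self, a, b, cap):
        truth = oracle_levenshtein(a, b)
        got = fr.edit_distance(rec("a", a), rec("b", b), cap=cap)
        assert got == (truth if truth <= cap else None)


class TestEditDistanceFilter:
    def test_close_pair_shorter_removed(self):
        ds = dataset(rec("a", "ACDEFGHIKL"), rec("b", "ACDEFGHIK"))
        kept, rep = fr.edit_distance_filter(ds, 1)
        assert kept.ids() == ["a"] and rep.removed_pairs == [("a", "b", 1.0)]

    def test_distant_pair_both_kept(self):
        ds = dataset(rec("a", "ACDEFGHIKL"), rec("b", "ACDEFGHMM"))
        kept, _ = fr.edit_distance_filter(ds, 1)
        assert len(kept) == 2

    def test_equal_length_tie_removes_later_id(self):
        ds = dataset(rec("b", "ACDEFGHIKL"), rec("a", "ACDEFGHIKM"))
        kept, rep = fr.edit_distance_filter(ds, 1)
        assert kept.ids() == ["a"] and rep.removed_pairs[0][1] == "b"

    def test_chain_resolved_by_length_priority(self):
        # a-b within d and b-c within d, but a-c beyond d: keeping the longest
        # (a) removes b; c survives because it is only close to the removed b.
        a = rec("a", "AAAAACCCCCDD")
        b = rec("b", "AAAAACCCCCD")
        c = rec("c", "AAAAACCCCC")
        kept, _ = fr.edit_distance_filter(dataset(a, b, c), 1)
        assert kept.ids() == ["a", "c"]

    def test_idempotent(self):
        cfg = fr.GeneratorConfig(n_classes=2, folds_per_class=1, seqs_per_fold=8,
                                 length_range=(15, 25), redundancy_rate=0.4, seed=21)
        ds, _ = fr.sample_dataset(cfg)
        once, _ = fr.edit_distance_filter(ds, 3)
        twice, rep = fr.edit_distance_filter(once, 3)
        assert twice.ids() == once.ids() and not rep.removed_pairs


class TestFamilyLongest:
    def test_one_per_family(self):
        ds = dataset(
            rec("a1", "ACDEF", "a.1", "a.1.f1"), rec("a2", "ACDEFGH", "a.1", "a.1.f1"),
            rec("a3", "ACD", "a.1", "a.1.f1"),
            rec("b1", "MKLMKL", "b.1", "b.1.f1"), rec("b2", "MKL", "b.1", "b.1.f1"),
            rec("b3", "MK", "b.1", "b.1.f1"),
        )
        kept, rep = fr.family_longest(ds)
        assert kept.ids() == ["a2", "b1"] and rep.kept_count == 2

    def test_equal_length_deterministic_pick(self):
        ds = dataset(rec("z", "ACDEF", "a.1", "fam"), rec("a", "MKLPQ", "a.1", "fam"))
        kept, _ = fr.family_longest(ds)
        assert kept.ids() == ["a"]

    def test_count_equals_distinct_families(self):
        cfg = fr.GeneratorConfig(n_classes=2, folds_per_class=2, seqs_per_fold=5,
                                 length_range=(10, 30), redundancy_rate=0.4, seed=31)
        ds, _ = fr.sample_dataset(cfg)
        kept, _ = fr.family_longest(ds)
        families = {r.label.family_id for r in ds}
        assert len(kept) == len(families)

    def test_missing_family_errors(self):
        ds = dataset(rec("a", "ACDE", "a.1"))
        with pytest.raises(ValueError, match="family"):
            fr.family_longest(ds)
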