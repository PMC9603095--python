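import numpy as np
import pytest

from rlpcascade.dataset_builder import (
    ClassScheme,
    DatasetError,
    OTHER_LABEL,
    PRIMARY_SUBFAMILIES,
    assign_folds,
    build_stage1_sets,
    build_stage2_set,
    build_stage3_sets,
    extract_stage1_positive,
    redundancy_filter,
    smote,
)
from rlpcascade.seqio import Interval, SequenceRecord, TopologyAnnotation

FEATURES_FAST = ("AAComposition", "CPAASC")


def _record(seq_id, residues):
    return SequenceRecord(id=seq_id, residues=residues)


def _random_records(rng, n, length=60, prefix="r"):
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return [
        _record(f"{prefix}{i}", "".join(rng.choice(alphabet, size=length)))
        for i in range(n)
    ]


class TestClassScheme:
    def test_default_holds_15_plus_other(self):
        scheme = ClassScheme.default()
        assert len(scheme.labels) == 16
        assert scheme.labels[-1] == OTHER_LABEL
        assert set(PRIMARY_SUBFAMILIES) < set(scheme.labels)

    def test_small_subfamilies_group_to_other(self):
        scheme = ClassScheme.from_counts(
            {"LRR-RLP": 100, "WAK-RLP": 50, "tiny": 3}, min_members=20
        )
        assert scheme.assign("LRR-RLP") == "LRR-RLP"
        assert scheme.assign("tiny") == OTHER_LABEL
        assert scheme.assign("never-seen") == OTHER_LABEL

    def test_n_primary_cap(self):
        counts = {f"fam{i}": 100 - i for i in range(20)}
        scheme = ClassScheme.from_counts(counts, min_members=5, n_primary=15)
        assert len(scheme.labels) == 16


class TestStage1Extraction:
    def _rlk(self, length=500, kin_start=300, kin_end=460):
        ann = TopologyAnnotation(
            sp=True,
            tm_segments=[Interval(250, 271)],
            kinase_domain=Interval(kin_start, kin_end),
        )
        return _record("k1", "A" * length), ann

    def test_truncates_before_kinase(self):
        rec, ann = self._rlk()
        positive = extract_stage1_positive(rec, ann)
        assert len(positive.residues) == 299

    def test_kinase_at_position_one_rejected(self):
        rec = _record("k1", "A" * 300)
        ann = TopologyAnnotation(
            sp=True,
            tm_segments=[Interval(250, 271)],
            kinase_domain=Interval(1, 200),
        )
        with pytest.raises(DatasetError):
            extract_stage1_positive(rec, ann)

    def test_missing_kinase_annotation_rejected(self):
        rec = _record("k1", "A" * 300)
        ann = TopologyAnnotation(sp=True, tm_segments=[Interval(250, 271)])
        with pytest.raises(DatasetError):
            extract_stage1_positive(rec, ann)

    def test_no_signal_peptide_rejected(self):
        rec = _record("k1", "A" * 500)
        ann = TopologyAnnotation(
            sp=False,
            tm_segments=[Interval(250, 271)],
            kinase_domain=Interval(300, 460),
        )
        with pytest.raises(DatasetError):
            extract_stage1_positive(rec, ann)


class TestRedundancyFilter:
    def test_identical_pair_collapses(self):
        records = [_record("a", "MKVLA" * 20), _record("b", "MKVLA" * 20)]
        assert len(redundancy_filter(records)) == 1

    def test_unrelated_pair_retained(self):
        records = [_record("a", "W" * 50), _record("b", "D" * 50)]
        assert len(redundancy_filter(records)) == 2

    def test_ten_copies_plus_one_unrelated(self):
        copies = [_record(f"c{i}", "MKVLAWDE" * 10) for i in range(10)]
        unrelated = [_record("u", "GHGHGHGH" * 10)]
        kept = redundancy_filter(copies + unrelated)
        assert len(kept) == 2
        assert {r.residues for r in kept} == {"MKVLAWDE" * 10, "GHGHGHGH" * 10}

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        records = _random_records(rng, 8, length=40)
        once = redundancy_filter(records)
        twice = redundancy_filter(once)
        assert [r.id for r in once] == [r.id for r in twice]


class TestStageSetCounts:
    def test_stage1_emits_splits_times_feature_types(self):
        rng = np.random.default_rng(0)
        positives = _random_records(rng, 12, prefix="p")
        negatives = _random_records(rng, 40, prefix="n")
        sets = build_stage1_sets(positives, negatives, seed=1,
                                 feature_types=FEATURES_FAST)
        assert len(sets) == 3 * len(FEATURES_FAST)
        # disjoint negative splits
        neg_ids = [
            frozenset(i for i in ts.provenance if i.startswith("n"))
            for ts in sets
            if ts.feature_type == FEATURES_FAST[0]
        ]
        assert len(neg_ids) == 3
        assert not (neg_ids[0] & neg_ids[1] or neg_ids[0] & neg_ids[2])

    def test_stage1_reproducible_by_seed(self):
        rng = np.random.default_rng(0)
        positives = _random_records(rng, 10, prefix="p")
        negatives = _random_records(rng, 40, prefix="n")
        a = build_stage1_sets(positives, negatives, seed=7, feature_types=FEATURES_FAST)
        b = build_stage1_sets(positives, negatives, seed=7, feature_types=FEATURES_FAST)
        assert all(x.provenance == y.provenance for x, y in zip(a, b))

    def test_stage1_rejects_overlapping_pools(self):
        rng = np.random.default_rng(0)
        shared = _random_records(rng, 5, prefix="s")
        with pytest.raises(DatasetError):
            build_stage1_sets(shared, shared, feature_types=FEATURES_FAST)

    def test_stage2_one_set_per_feature_type(self):
        rng = np.random.default_rng(1)
        positives = _random_records(rng, 10, prefix="p")
        rlk = _random_records(rng, 10, prefix="p")  # same ids allowed: prefixed
        sets = build_stage2_set(positives, rlk, feature_types=FEATURES_FAST)
        assert len(sets) == len(FEATURES_FAST)
        assert sorted(sets[0].y.unique()) == ["RLK", "RLP"]

    def test_stage2_empty_positives_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(DatasetError):
            build_stage2_set([], _random_records(rng, 5), feature_types=FEATURES_FAST)

    def test_stage3_subsets_and_downsampling(self):
        rng = np.random.default_rng(2)
        scheme = ClassScheme(labels=("A-RLP", "B-RLP", OTHER_LABEL))
        big = _random_records(rng, 30, prefix="a")
        small = _random_records(rng, 6, prefix="b")
        labels = {r.id: "A-RLP" for r in big} | {r.id: "B-RLP" for r in small}
        sets = build_stage3_sets(
            big + small, labels, scheme, n_subsets=4, per_class_cap=10,
            feature_types=FEATURES_FAST, seed=3,
        )
        assert len(sets) == 4 * len(FEATURES_FAST)
        for ts in sets:
            counts = ts.y.value_counts()
            assert counts["A-RLP"] == 10  # capped
            assert counts["B-RLP"] == 6  # intact

    def test_stage3_default_counts(self, stage_sets):
        assert len(stage_sets["rlp_vs_nrlp"]) == 18
        assert len(stage_sets["rlp_vs_rlk"]) == 6
        assert len(stage_sets["subfamily"]) == 60


class TestSmote:
    def test_balances_counts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(110, 4))
        y = np.array(["A"] * 100 + ["B"] * 10)
        X2, y2 = smote(X, y, seed=1)
        _, counts = np.unique(y2, return_counts=True)
        assert set(counts) == {100}

    def test_originals_untouched_and_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = np.array(["A"] * 25 + ["B"] * 5)
        X2, _ = smote(X, y, seed=1)
        assert np.array_equal(X2[:30], X)

    def test_degenerate_identical_minority(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((20, 2))])
        y = np.array(["B"] * 5 + ["A"] * 20)
        X2, y2 = smote(X, y, seed=1)
        synth = X2[25:]
        assert np.allclose(synth, 0.0)  # all on the degenerate segment

    def test_single_member_minority_rejected(self):
        X = np.vstack([np.zeros((1, 2)), np.ones((5, 2))])
        y = np.array(["B"] + ["A"] * 5)
        with pytest.raises(DatasetError):
            smote(X, y)

    def test_synthetic_points_in_minority_hull_box(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(5, 1, size=(40, 3)), rng.normal(0, 1, size=(8, 3))])
        y = np.array(["A"] * 40 + ["B"] * 8)
        X2, y2 = smote(X, y, seed=4)
        minority = X[40:]
        synth = X2[48:]
        assert np.all(synth >= minority.min(axis=0) - 1e-12)
        assert np.all(synth <= minority.max(axis=0) + 1e-12)


class TestAssignFolds:
    def test_balanced_stratification(self):
        y = np.array(["A", "B"] * 50)
        folds = assign_folds(y, n_folds=10, seed=0)
        for f in range(10):
            mask = folds == f
            assert mask.sum() == 10
            assert (y[mask] == "A").sum() == 5

    def test_reproducible(self):
        y = np.array(["A"] * 30 + ["B"] * 20)
        assert np.array_equal(
            assign_folds(y, seed=5), assign_folds(y, seed=5)
        )

    def test_reduces_folds_for_rare_class(self):
        y = np.array(["A"] * 30 + ["B"] * 4)
        with pytest.warns(UserWarning):
            folds = assign_folds(y, n_folds=10, seed=0)
        assert len(np.unique(folds)) == 4
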