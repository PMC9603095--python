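import numpy as np
import pandas as pd
import pytest

from rlpcascade.dataset_builder import TrainingSet
from rlpcascade.models import (
    ConfusionMatrix,
    METRIC_NAMES,
    ModelError,
    compute_metrics,
    cross_validate,
    metrics_table,
    select_champion,
    train_member,
)


def _training_set(X, y, feature_type="AAComposition", dataset_id="toy"):
    X = pd.DataFrame(np.asarray(X, dtype=float))
    X.index = [f"s{i}" for i in range(len(X))]
    return TrainingSet(
        stage="rlp_vs_nrlp",
        dataset_id=dataset_id,
        feature_type=feature_type,
        X=X,
        y=pd.Series(list(y), index=X.index),
    )


def _separable_set(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 0.2, size=(n, 3)), rng.normal(5, 0.2, size=(n, 3))]
    )
    y = ["NRLP"] * n + ["RLP"] * n
    return _training_set(X, y)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix.binary(tp=50, fp=0, tn=50, fn=0)
        metrics = compute_metrics(cm)
        for name in ("ACC", "F1", "Precision", "Sensitivity", "Specificity", "MCC"):
            assert metrics[name] == 1.0
        assert metrics["FDR"] == 0.0

    def test_total_confusion(self):
        cm = ConfusionMatrix.binary(tp=0, fp=50, tn=0, fn=50)
        with pytest.warns(UserWarning):
            metrics = compute_metrics(cm)
        assert metrics["ACC"] == 0.0
        assert metrics["MCC"] == -1.0

    def test_hand_derived_values(self):
        cm = ConfusionMatrix.binary(tp=40, fp=10, tn=45, fn=5)
        metrics = compute_metrics(cm)
        assert metrics["ACC"] == pytest.approx(0.85)
        assert metrics["Precision"] == pytest.approx(0.8)
        assert metrics["FDR"] == pytest.approx(0.2)
        expected_mcc = (40 * 45 - 10 * 5) / np.sqrt(50 * 45 * 55 * 50)
        assert metrics["MCC"] == pytest.approx(expected_mcc)

    def test_negative_counts_rejected(self):
        with pytest.raises(ModelError):
            ConfusionMatrix.binary(tp=-1, fp=0, tn=1, fn=0)

    def test_brute_force_agreement_binary(self):
        # independent tally straight from prediction/label pairs
        rng = np.random.default_rng(1)
        y_true = rng.choice(["P", "N"], size=200)
        y_pred = rng.choice(["P", "N"], size=200)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, positive="P")
        metrics = compute_metrics(cm)
        tp = np.sum((y_true == "P") & (y_pred == "P"))
        fp = np.sum((y_true == "N") & (y_pred == "P"))
        fn = np.sum((y_true == "P") & (y_pred == "N"))
        tn = np.sum((y_true == "N") & (y_pred == "N"))
        assert metrics["ACC"] == pytest.approx((tp + tn) / 200)
        assert metrics["Precision"] == pytest.approx(tp / (tp + fp))
        assert metrics["Sensitivity"] == pytest.approx(tp / (tp + fn))
        assert metrics["FDR"] == pytest.approx(1 - metrics["Precision"])

    def test_macro_average_is_mean_of_class_suites(self):
        rng = np.random.default_rng(2)
        classes = ["a", "b", "c"]
        y_true = rng.choice(classes, size=300)
        y_pred = rng.choice(classes, size=300)
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes=classes)
        macro = compute_metrics(cm, average="macro")
        per_class_acc = []
        for c in classes:
            tp = np.sum((y_true == c) & (y_pred == c))
            tn = np.sum((y_true != c) & (y_pred != c))
            per_class_acc.append((tp + tn) / 300)
        assert macro["ACC"] == pytest.approx(np.mean(per_class_acc))


class TestTrainMember:
    def test_separable_set_fits_perfectly(self):
        ts = _separable_set()
        member = train_member(ts, "lda", seed=0)
        assert np.mean(member.predict(ts.X) == ts.y.values) == 1.0

    def test_single_class_rejected(self):
        ts = _training_set(np.zeros((6, 2)), ["RLP"] * 6)
        with pytest.raises(ModelError):
            train_member(ts, "lda")

    def test_determinism_by_seed(self):
        ts = _separable_set()
        probe = np.random.default_rng(9).normal(2.5, 1.0, size=(10, 3))
        a = train_member(ts, "mlp", seed=4).predict(probe)
        b = train_member(ts, "mlp", seed=4).predict(probe)
        assert np.array_equal(a, b)

    def test_probabilities_normalised(self):
        ts = _separable_set()
        member = train_member(ts, "knn", seed=0)
        proba = member.predict_proba(ts.X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert proba.min() >= 0.0


class TestCrossValidate:
    def test_separable_scores_perfect(self):
        record = cross_validate(_separable_set(n=50), "lda", n_folds=10, seed=0)
        assert record["ACC"] == 1.0
        assert record["MCC"] == 1.0
        assert record["FDR"] == 0.0

    def test_schema_matches_report_columns(self):
        record = cross_validate(_separable_set(), "knn", n_folds=5, seed=0)
        assert set(METRIC_NAMES) <= set(record)
        table = metrics_table([record])
        assert list(table.columns) == ["Data Set", "Algorithm", *METRIC_NAMES]

    def test_shuffled_labels_give_null_mcc(self):
        rng = np.random.default_rng(3)
        mccs = []
        for rep in range(20):
            X = rng.normal(size=(80, 4))
            y = np.array(["RLP", "NRLP"] * 40)
            rng.shuffle(y)
            ts = _training_set(X, y, dataset_id=f"perm{rep}")
            mccs.append(cross_validate(ts, "lda", n_folds=5, seed=rep)["MCC"])
        assert abs(np.mean(mccs)) < 0.1


class TestSelectChampion:
    def _record(self, algorithm, mcc, acc):
        return {"Algorithm": algorithm, "MCC": mcc, "ACC": acc}

    def test_highest_mcc_wins(self):
        records = [self._record("lda", 0.90, 0.99), self._record("knn", 0.95, 0.90)]
        assert select_champion(records)["Algorithm"] == "knn"

    def test_acc_breaks_mcc_tie(self):
        records = [self._record("lda", 0.9, 0.92), self._record("knn", 0.9, 0.95)]
        assert select_champion(records)["Algorithm"] == "knn"

    def test_registry_order_breaks_full_tie(self):
        records = [self._record("mlp", 0.9, 0.9), self._record("adaboost", 0.9, 0.9)]
        assert select_champion(records)["Algorithm"] == "adaboost"

    def test_empty_rejected(self):
        with pytest.raises(ModelError):
            select_champion([])
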