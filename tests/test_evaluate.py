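"""Metrics, cross-validation splits and review sheets."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from medinq.evaluate import (
    ReviewSheet,
    compute_metrics,
    export_review_sheet,
    fold_assignments,
    kfold_cv,
    score_review,
)


class TestComputeMetrics:
    def test_all_correct(self):
        rep = compute_metrics(["a", "b"], ["a", "b"])
        for lbl in ("a", "b"):
            assert rep.per_label[lbl] == {
                "precision": 1.0, "recall": 1.0, "f1": 1.0
            }

    def test_all_wrong(self):
        rep = compute_metrics(["b", "a"], ["a", "b"])
        assert rep.macro["f1"] == 0.0

    def test_hand_counted_two_label_case(self):
        rep = compute_metrics(["A", "B", "B", "B"], ["A", "A", "B", "B"])
        assert rep.per_label["A"] == pytest.approx(
            {"precision": 1.0, "recall": 0.5, "f1": 2 / 3}
        )
        assert rep.per_label["B"] == pytest.approx(
            {"precision": 2 / 3, "recall": 1.0, "f1": 0.8}
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(["a"], ["a", "b"])

    def test_micro_equals_accuracy_for_single_label_task(self):
        rng = np.random.default_rng(0)
        labels = ["x", "y", "z"]
        gold = [labels[i] for i in rng.integers(0, 3, 100)]
        pred = [labels[i] for i in rng.integers(0, 3, 100)]
        rep = compute_metrics(pred, gold, labels=labels)
        acc = np.mean([p == g for p, g in zip(pred, gold)])
        assert rep.micro["precision"] == pytest.approx(acc)
        assert rep.micro["recall"] == pytest.approx(acc)
        assert rep.micro["f1"] == pytest.approx(acc)

    def test_agrees_with_sklearn_on_random_data(self):
        """Independent cross-check of per-label and averaged metrics."""
        rng = np.random.default_rng(1)
        labels = list("abcde")
        for _ in range(5):
            n = int(rng.integers(20, 200))
            gold = [labels[i] for i in rng.integers(0, 5, n)]
            pred = [labels[i] for i in rng.integers(0, 5, n)]
            rep = compute_metrics(pred, gold, labels=labels)
            for avg in ("micro", "macro", "weighted"):
                p, r, f, _ = precision_recall_fscore_support(
                    gold, pred, labels=labels, average=avg, zero_division=0
                )
                got = getattr(rep, avg)
                assert got["precision"] == pytest.approx(p)
                assert got["recall"] == pytest.approx(r)
                assert got["f1"] == pytest.approx(f)


class TestFolds:
    def test_partition_and_balance(self):
        y = ["a"] * 50 + ["b"] * 50
        folds = fold_assignments(y, 10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 100
        assert sizes.max() - sizes.min() <= 1

    def test_same_seed_identical(self):
        y = ["a"] * 30 + ["b"] * 30
        assert np.array_equal(fold_assignments(y, 5, 7),
                              fold_assignments(y, 5, 7))

    def test_stratification(self):
        y = ["a"] * 90 + ["b"] * 10
        folds = fold_assignments(y, 10, seed=1)
        b_folds = folds[90:]
        assert len(set(b_folds)) == 10  # one minority item per fold

    def test_small_label_falls_back_with_warning(self):
        y = ["a"] * 20 + ["b"] * 2
        with pytest.warns(UserWarning):
            folds = fold_assignments(y, 5, seed=0)
        assert len(np.unique(folds)) == 5

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            fold_assignments(["a", "b"], 1, 0)


class TestKFoldCV:
    @staticmethod
    def _majority_train(X, y):
        vals, counts = np.unique(np.asarray(y, dtype=object),
                                 return_counts=True)
        return vals[np.argmax(counts)]

    @staticmethod
    def _majority_predict(model, X):
        return [model] * X.shape[0]

    def test_each_item_evaluated_once_and_counts_pool(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = ["a"] * 60 + ["b"] * 40
        reports, pooled = kfold_cv(X, y, self._majority_train,
                                   self._majority_predict, k=10, seed=0,
                                   labels=["a", "b"])
        assert len(reports) == 10
        for lbl in ("a", "b"):
            fold_tp = sum(r.counts[lbl].tp for r in reports)
            fold_fp = sum(r.counts[lbl].fp for r in reports)
            fold_fn = sum(r.counts[lbl].fn for r in reports)
            assert (fold_tp, fold_fp, fold_fn) == (
                pooled.counts[lbl].tp, pooled.counts[lbl].fp,
                pooled.counts[lbl].fn,
            )
        assert sum(r.counts["a"].tp + r.counts["a"].fn for r in reports) == 60

    def test_same_seed_identical_reports(self):
        X = np.zeros((40, 1))
        y = ["a", "b"] * 20
        _, p1 = kfold_cv(X, y, self._majority_train, self._majority_predict,
                         k=5, seed=4)
        _, p2 = kfold_cv(X, y, self._majority_train, self._majority_predict,
                         k=5, seed=4)
        assert p1.micro == p2.micro

    def test_fold_metadata_carried(self):
        X = np.zeros((20, 1))
        y = ["a", "b"] * 10
        reports, _ = kfold_cv(X, y, self._majority_train,
                              self._majority_predict, k=5, seed=0)
        assert [r.fold for r in reports] == list(range(5))


class TestReviewSheet:
    def test_sample_is_unique_and_sized(self):
        texts = [f"s{i}" for i in range(5000)]
        preds = ["A"] * 5000
        sheet = export_review_sheet(texts, preds, 1600, seed=0)
        assert len(sheet.rows) == 1600
        assert sheet.rows["sentence"].nunique() == 1600
        assert (sheet.rows["assessment"] == "").all()

    def test_empty_sample(self):
        assert len(export_review_sheet(["a"], ["A"], 0).rows) == 0

    def test_same_seed_same_sample(self):
        texts = [f"s{i}" for i in range(100)]
        s1 = export_review_sheet(texts, ["A"] * 100, 10, seed=5)
        s2 = export_review_sheet(texts, ["A"] * 100, 10, seed=5)
        assert s1.rows.equals(s2.rows)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            export_review_sheet(["a"], ["A"], 2)

    def test_csv_round_trip(self, tmp_path):
        sheet = export_review_sheet([f"s{i}" for i in range(10)],
                                    ["A"] * 10, 5, seed=1)
        path = tmp_path / "sheet.csv"
        sheet.to_csv(path)
        loaded = ReviewSheet.from_csv(path)
        assert loaded.rows["sentence"].tolist() == \
            sheet.rows["sentence"].tolist()


class TestScoreReview:
    def _sheet(self, assessments):
        sheet = export_review_sheet(
            [f"s{i}" for i in range(len(assessments))],
            ["A"] * len(assessments), len(assessments), seed=0,
        )
        sheet.rows["assessment"] = assessments
        return sheet

    def test_accuracy(self):
        out = score_review(self._sheet(["correct"] * 8 + ["incorrect"] * 2))
        assert out["accuracy"] == pytest.approx(0.8)

    def test_all_incomplete(self):
        out = score_review(self._sheet(["incomplete"] * 4))
        assert out["accuracy"] == 0.0
        assert out["breakdown"]["incomplete"] == 4

    def test_counts_conserve(self):
        out = score_review(
            self._sheet(["correct", "incorrect", "incomplete", "correct"])
        )
        assert sum(out["breakdown"].values()) == out["total"] == 4

    def test_blank_assessment_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            score_review(self._sheet(["correct", ""]))

    def test_invalid_value_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            score_review(self._sheet(["maybe"]))
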