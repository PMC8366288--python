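"""Per-label metrics, cross-validation, and expert review sheets.

Metrics are one-versus-rest precision/recall/F1 per label with micro,
macro, and support-weighted averages; F1 is 0 whenever precision + recall
is 0. Cross-validation splits are stratified by label when every label has
at least k instances (falling back to unstratified shuffled folds with a
warning otherwise) and are reproducible under a fixed seed.

For human validation, a uniform random non-overlapping sample of
predictions is exported as a review sheet whose assessment column experts
fill with ``correct``, ``incorrect`` or ``incomplete``; scoring a filled
sheet reports accuracy (correct / total) and the per-assessment breakdown.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "kfold_cv",
    "fold_assignments",
    "ReviewSheet",
    "export_review_sheet",
    "score_review",
]

ASSESSMENTS = ("correct", "incorrect", "incomplete")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    def f1(self) -> float:
        p, r = self.precision(), self.recall()
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class MetricsReport:
    per_label: dict[str, dict[str, float]]
    counts: dict[str, ConfusionCounts]
    micro: dict[str, float]
    macro: dict[str, float]
    weighted: dict[str, float]
    support: dict[str, int]
    fold: int | None = None

    def to_json(self) -> str:
        doc = {
            "fold": self.fold,
            "per_label": self.per_label,
            "micro": self.micro,
            "macro": self.macro,
            "weighted": self.weighted,
            "support": self.support,
        }
        return json.dumps(doc, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": lbl, **vals, "support": self.support[lbl]}
            for lbl, vals in self.per_label.items()
        ]
        rows.append({"label": "micro", **self.micro})
        rows.append({"label": "macro", **self.macro})
        rows.append({"label": "weighted", **self.weighted})
        return pd.DataFrame(rows)


def compute_metrics(predictions: list[str], gold: list[str],
                    labels: list[str] | None = None,
                    fold: int | None = None) -> MetricsReport:
    """Per-label one-versus-rest counts and averaged P/R/F1.

    ``labels`` fixes the label set reported (default: all labels present in
    either list). Predictions outside the label set (for example the
    fallback) still count as false negatives for the gold label.
    """
    if len(predictions) != len(gold):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions, {len(gold)} gold"
        )
    if labels is None:
        labels = sorted(set(gold) | set(predictions))
    counts: dict[str, ConfusionCounts] = {}
    support: dict[str, int] = {}
    for lbl in labels:
        tp = sum(1 for p, g in zip(predictions, gold) if p == lbl and g == lbl)
        fp = sum(1 for p, g in zip(predictions, gold) if p == lbl and g != lbl)
        fn = sum(1 for p, g in zip(predictions, gold) if p != lbl and g == lbl)
        counts[lbl] = ConfusionCounts(tp, fp, fn)
        support[lbl] = tp + fn

    per_label = {
        lbl: {"precision": c.precision(), "recall": c.recall(), "f1": c.f1()}
        for lbl, c in counts.items()
    }
    tp = sum(c.tp for c in counts.values())
    fp = sum(c.fp for c in counts.values())
    fn = sum(c.fn for c in counts.values())
    micro_c = ConfusionCounts(tp, fp, fn)
    micro = {"precision": micro_c.precision(), "recall": micro_c.recall(),
             "f1": micro_c.f1()}
    macro = {
        m: float(np.mean([per_label[lbl][m] for lbl in labels]))
        for m in ("precision", "recall", "f1")
    }
    total = sum(support.values())
    if total:
        weighted = {
            m: float(sum(per_label[lbl][m] * support[lbl] for lbl in labels)
                     / total)
            for m in ("precision", "recall", "f1")
        }
    else:
        weighted = {m: 0.0 for m in ("precision", "recall", "f1")}
    return MetricsReport(per_label, counts, micro, macro, weighted, support,
                         fold)


def fold_assignments(y: list[str], k: int, seed: int) -> np.ndarray:
    """Fold index per item; stratified by label when possible.

    Within each label, items are shuffled and dealt round-robin so fold
    sizes differ by at most one per label. If some label has fewer than k
    instances, falls back to a plain shuffled split with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    labels, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            "some label has fewer than k instances; using unstratified folds",
            stacklevel=2,
        )
        order = rng.permutation(len(y))
        for f, chunk in enumerate(np.array_split(order, k)):
            folds[chunk] = f
        return folds
    offset = 0
    for lbl in labels:
        idx = np.nonzero(y == lbl)[0]
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # stagger so small labels spread across folds
    return folds


def kfold_cv(X, y: list[str], train_fn, predict_fn, k: int = 10,
             seed: int = 0, labels: list[str] | None = None):
    """k-fold cross-validation; returns (per-fold reports, pooled report).

    ``train_fn(X_train, y_train) -> model`` and
    ``predict_fn(model, X_test) -> list of labels``. Every item is
    evaluated exactly once; the pooled report is computed from the union
    of out-of-fold predictions, so its confusion counts equal the sum of
    the per-fold counts.
    """
    y = list(y)
    folds = fold_assignments(y, k, seed)
    y_arr = np.asarray(y, dtype=object)
    reports = []
    pooled_pred = np.empty(len(y), dtype=object)
    for f in range(k):
        test = folds == f
        train = ~test
        model = train_fn(X[np.nonzero(train)[0]], list(y_arr[train]))
        pred = predict_fn(model, X[np.nonzero(test)[0]])
        pooled_pred[test] = pred
        reports.append(
            compute_metrics(list(pred), list(y_arr[test]), labels, fold=f)
        )
    pooled = compute_metrics(list(pooled_pred), y, labels)
    return reports, pooled


@dataclass
class ReviewSheet:
    """Rows experts assess as correct / incorrect / incomplete."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReviewSheet":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(df)


def export_review_sheet(texts: list[str], predictions: list[str],
                        n_sample: int, seed: int = 0) -> ReviewSheet:
    """Uniform random non-overlapping sample with a blank assessment column."""
    if len(texts) != len(predictions):
        raise ValueError("texts and predictions must align")
    if n_sample > len(texts):
        raise ValueError(
            f"cannot sample {n_sample} of {len(texts)} predictions"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(texts), size=n_sample, replace=False)
    idx.sort()
    df = pd.DataFrame({
        "sentence": [texts[i] for i in idx],
        "predicted_subcategory": [predictions[i] for i in idx],
        "assessment": [""] * n_sample,
    })
    return ReviewSheet(df)


def score_review(sheet: ReviewSheet) -> dict:
    """Accuracy (correct / total) and per-assessment counts."""
    values = sheet.rows["assessment"].astype(str).str.strip().str.lower()
    blank = sheet.rows.index[values == ""].tolist()
    if blank:
        raise ValueError(f"blank assessments at rows {blank}")
    bad = sorted(set(values) - set(ASSESSMENTS))
    if bad:
        raise ValueError(f"invalid assessment values {bad}; "
                         f"allowed: {ASSESSMENTS}")
    total = len(values)
    breakdown = {a: int((values == a).sum()) for a in ASSESSMENTS}
    return {
        "total": total,
        "accuracy": breakdown["correct"] / total if total else 0.0,
        "breakdown": breakdown,
    }
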