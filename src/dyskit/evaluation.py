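"""Precision/recall/F1, RMSE, confusion matrices and model selection.

Severity scores are ordinal integers 0-4. Classifiers treat them as plain
categories; ordinality enters only through the RMSE (treating labels as
integers) and the adjacent-error fraction of the confusion matrix. Per-class
precision and recall are computed one-vs-rest (TP/(TP+FP), TP/(TP+FN));
classes with a zero denominator receive 0 and remain in the aggregate.
Multi-class aggregation is the unweighted (macro) mean over classes present
in the true labels; a frequency-weighted mean is available via ``average``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

CLASSES = (0, 1, 2, 3, 4)

#: Tie-break order among model settings: simpler wins on equal validation F1.
SETTING_SIMPLICITY = ("ALL", "SFS", "ALL+HYP", "SFS+HYP")


def _check_labels(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise DataError("true/predicted labels must be equal-length nonempty 1-D")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        if arr.min() < 0 or arr.max() > 4:
            raise DataError(f"{name} labels outside 0-4")
    return y_true, y_pred


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """5x5 count matrix, entry (i, j) = true class i predicted as j."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    cm = np.zeros((5, 5), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def precision_recall_f1(y_true, y_pred, average: str = "macro"):
    """Per-class and aggregate precision, recall and F1.

    Returns ``(per_class, aggregate)`` where ``per_class`` is a DataFrame
    indexed by class with precision/recall/f1/support and ``aggregate`` a
    dict with the macro (or weighted) precision, recall and F1 over the
    classes present in ``y_true``.
    """
    y_true, y_pred = _check_labels(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2.0 * precision * recall / (precision + recall),
            0.0,
        )
    support = cm.sum(axis=1)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": support},
        index=list(CLASSES),
    )
    present = support > 0
    if average == "macro":
        w = present / present.sum()
    elif average == "weighted":
        w = support / support.sum()
    else:
        raise ValueError(f"unknown average {average!r}")
    aggregate = {
        "precision": float(precision @ w),
        "recall": float(recall @ w),
        "f1": float(f1 @ w),
    }
    return per_class, aggregate


def rmse_scores(y_true, y_pred) -> float:
    """Root-mean-square error treating the 0-4 labels as integers."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(np.sqrt(np.mean(np.square(y_true - y_pred))))


def adjacent_error_fraction(cm: np.ndarray):
    """Fraction of misclassifications landing in a neighbouring score.

    Returns None when there are no misclassifications (undefined).
    """
    cm = np.asarray(cm)
    off = cm.copy().astype(float)
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    if total == 0:
        return None
    i, j = np.indices(cm.shape)
    adjacent = off[np.abs(i - j) == 1].sum()
    return float(adjacent / total)


@dataclass
class EvaluationReport:
    """Metrics of one model on one data split."""

    per_class: pd.DataFrame
    precision: float
    recall: float
    f1: float
    rmse: float
    confusion: np.ndarray
    n_samples: int
    average: str = "macro"

    @property
    def adjacent_error_fraction(self):
        return adjacent_error_fraction(self.confusion)

    def to_dict(self) -> dict:
        return {
            "average": self.average,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "rmse": self.rmse,
            "n_samples": self.n_samples,
            "confusion": self.confusion.tolist(),
            "per_class": {
                str(c): {
                    k: float(self.per_class.loc[c, k])
                    for k in ("precision", "recall", "f1", "support")
                }
                for c in self.per_class.index
            },
        }


def evaluate_predictions(y_true, y_pred, average: str = "macro") -> EvaluationReport:
    per_class, agg = precision_recall_f1(y_true, y_pred, average=average)
    return EvaluationReport(
        per_class=per_class,
        precision=agg["precision"],
        recall=agg["recall"],
        f1=agg["f1"],
        rmse=rmse_scores(y_true, y_pred),
        confusion=confusion_matrix(y_true, y_pred),
        n_samples=int(np.asarray(y_true).size),
        average=average,
    )


@dataclass
class BestModelRecord:
    """The winning variant for one dataset (highest validation F1)."""

    dataset_id: str
    algorithm: str
    setting: str
    validation_f1: float
    test_f1: float
    test_precision: float
    test_recall: float
    spec: object = None
    report: EvaluationReport = None


def select_best_model(variants, dataset_id: str = "dataset",
                      algorithm_order=None) -> BestModelRecord:
    """Pick the variant maximizing validation macro F1.

    Ties break toward the simpler setting (ALL < SFS < ALL+HYP < SFS+HYP),
    then toward the earlier algorithm in the family order — never toward the
    higher test score, which would leak the test data into selection.
    """
    variants = list(variants)
    if not variants:
        raise DataError("no variant reports to select from")
    if algorithm_order is None:
        from .training import ALGORITHMS
        algorithm_order = ALGORITHMS

    def rank(v):
        return (
            -v.validation_f1,
            SETTING_SIMPLICITY.index(v.spec.setting),
            list(algorithm_order).index(v.spec.algorithm),
        )

    best = min(variants, key=rank)
    return BestModelRecord(
        dataset_id=dataset_id,
        algorithm=best.spec.algorithm,
        setting=best.spec.setting,
        validation_f1=float(best.validation_f1),
        test_f1=float(best.test_report.f1),
        test_precision=float(best.test_report.precision),
        test_recall=float(best.test_report.recall),
        spec=best.spec,
        report=best.test_report,
    )


def summarize_experiments(best_records) -> pd.DataFrame:
    """Mean +/- sample SD of validation/test metrics across subjects."""
    records = [r for r in best_records if r is not None]
    if not records:
        raise DataError("no records to summarize")
    df = pd.DataFrame(
        {
            "validation_f1": [r.validation_f1 for r in records],
            "test_f1": [r.test_f1 for r in records],
            "test_precision": [r.test_precision for r in records],
            "test_recall": [r.test_recall for r in records],
        }
    )
    out = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    out.loc[:, "n"] = len(records)
    return out
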