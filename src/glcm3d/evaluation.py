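"""Confusion-matrix metrics, the gray-level sweep, and method comparison.

Multiclass performance follows the one-vs-rest reading: for each class i,
TP/FP/TN/FN are taken from the pooled confusion matrix and

    accuracy_i  = (TP_i + TN_i) / (TP_i + TN_i + FP_i + FN_i)
    precision_i =  TP_i / (TP_i + FP_i)
    recall_i    =  TP_i / (TP_i + FN_i)

are macro-averaged (unweighted mean over classes) and reported in percent.
``sweep_gray_levels`` runs the whole pipeline (quantize -> tensor -> features
-> k-fold CV -> metrics) for every gray-level count and feature variant,
producing a table with one row per (level, method).  The
original-vs-invariant comparison is summarized as the mean relative percent
increase of each metric across gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from glcm3d.classification import LabeledFeatureSet, cross_validate
from glcm3d.errors import DegenerateInputError, InvalidInputError
from glcm3d.features import extract_features
from glcm3d.preprocessing import STANDARD_LEVELS, dataset_bounds, quantize


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    true_labels, predicted_labels, classes: tuple[str, ...]
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into a matrix.

    Raises
    ------
    InvalidInputError
        On length mismatch or a label outside ``classes``.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise InvalidInputError("label lists must have equal length")
    unknown = (set(true_labels) | set(predicted_labels)) - set(classes)
    if unknown:
        raise InvalidInputError(f"labels not in class list: {sorted(unknown)}")
    if not true_labels:
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    else:
        counts = _sk_confusion_matrix(
            true_labels, predicted_labels, labels=list(classes)
        ).astype(np.int64)
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def per_class_counts(cm: ConfusionMatrix, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, TN, FN) for the given class."""
    if cls not in cm.classes:
        raise InvalidInputError(f"unknown class {cls!r}")
    i = cm.classes.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, tn, fn


def macro_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, precision, recall) in percent, macro-averaged over classes.

    Per-class precision (recall) is defined as 0 when its denominator is
    zero, keeping the metrics bounded on degenerate folds.

    Raises
    ------
    DegenerateInputError
        If the matrix holds no predictions.
    """
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    accs, precs, recs = [], [], []
    for cls in cm.classes:
        tp, fp, tn, fn = per_class_counts(cm, cls)
        accs.append((tp + tn) / cm.total)
        precs.append(tp / (tp + fp) if tp + fp else 0.0)
        recs.append(tp / (tp + fn) if tp + fn else 0.0)
    return tuple(100.0 * float(np.mean(v)) for v in (accs, precs, recs))


def evaluate_feature_set(
    data: LabeledFeatureSet, k: int = 5, seed: int = 0, standardize: bool = False
) -> dict:
    """Cross-validate one feature set; returns pooled metrics + matrix."""
    res = cross_validate(data, k=k, seed=seed, standardize=standardize)
    cm = confusion_matrix(res.true_labels, res.predicted_labels, res.classes)
    acc, prec, rec = macro_metrics(cm)
    return {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "confusion": cm,
        "cv": res,
    }


def sweep_gray_levels(
    images: list[tuple[str, str, np.ndarray]],
    levels: tuple[int, ...] = STANDARD_LEVELS,
    methods: tuple[str, ...] = ("original", "invariant"),
    k: int = 5,
    seed: int = 0,
    d: int = 1,
    standardize: bool = False,
    bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Quantization sweep over gray-level counts and feature variants.

    Parameters
    ----------
    images : list of (id, label, gray image)
        Preprocessed gray images with class labels.
    levels : tuple of int
        Gray-level counts to evaluate.
    bounds : (lo, hi), optional
        Quantization bounds; defaults to the dataset-wide (global) min-max.

    Returns
    -------
    DataFrame with one row per (gray level, method) and columns
    ``gray_levels, method, accuracy, precision, recall`` (percent).
    """
    if len({lab for _, lab, _ in images}) < 2:
        raise InvalidInputError("sweep requires at least 2 classes")
    if bounds is None:
        bounds = dataset_bounds([im for _, _, im in images])
    lo, hi = bounds
    rows = []
    for n_levels in levels:
        quantized = [
            (img_id, label, quantize(im, n_levels, lo, hi))
            for img_id, label, im in images
        ]
        for method in methods:
            records = [
                (img_id, label, extract_features(q, variant=method, d=d))
                for img_id, label, q in quantized
            ]
            data = LabeledFeatureSet.from_records(records)
            res = evaluate_feature_set(data, k=k, seed=seed, standardize=standardize)
            rows.append(
                {
                    "gray_levels": n_levels,
                    "method": method,
                    "accuracy": round(res["accuracy"], 2),
                    "precision": round(res["precision"], 2),
                    "recall": round(res["recall"], 2),
                }
            )
    return pd.DataFrame(rows)


def relative_increase_summary(orig_col, inv_col) -> float:
    """Mean relative percent increase of one metric across gray levels.

    ``mean over levels of 100 * (inv - orig) / orig``, rounded to 2 decimals
    — the summary used to compare the invariant method with the original one
    over a sweep column.

    Raises
    ------
    InvalidInputError
        On length mismatch or a non-positive baseline value.
    """
    orig = np.asarray(orig_col, dtype=np.float64)
    inv = np.asarray(inv_col, dtype=np.float64)
    if orig.shape != inv.shape or orig.ndim != 1 or orig.size == 0:
        raise InvalidInputError("expected two equal-length 1D value lists")
    if np.any(orig <= 0):
        raise InvalidInputError("baseline values must be positive")
    return float(np.round(np.mean(100.0 * (inv - orig) / orig), 2))


def compare_methods(table: pd.DataFrame) -> dict[str, float]:
    """Relative-increase summary for each metric column of a sweep table."""
    out = {}
    orig = table[table["method"] == "original"].sort_values("gray_levels")
    inv = table[table["method"] == "invariant"].sort_values("gray_levels")
    for metric in ("accuracy", "precision", "recall"):
        out[metric] = relative_increase_summary(
            orig[metric].to_numpy(), inv[metric].to_numpy()
        )
    return out
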