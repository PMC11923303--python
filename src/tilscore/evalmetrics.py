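"""Multi-class evaluation of patch classifiers.

Reports the confusion matrix (fixed class order 0, 1, 2), accuracy,
Cohen's kappa, one-vs-rest AUC, and precision / recall / specificity /
F1 under both micro and macro averaging.  Micro averaging is the
default: for a single multi-class confusion matrix, micro precision =
micro recall = accuracy, which is the signature of metric tables where
those three coincide.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .classify import PatchLabel, Prediction, split_dataset

__all__ = ["MetricsReport", "evaluate", "cross_validate", "CrossValidationReport"]

CLASSES = [0, 1, 2]


@dataclass
class MetricsReport:
    """Confusion matrix (rows = truth, cols = predicted) and scalar
    metrics of one evaluation, micro- and macro-averaged."""

    confusion: np.ndarray
    accuracy: float
    kappa: float
    auc: float | None
    precision: dict[str, float]
    recall: dict[str, float]
    specificity: dict[str, float]
    f1: dict[str, float]
    per_class_specificity: np.ndarray
    averaging: str = "micro"

    def scalar(self, name: str) -> float:
        value = getattr(self, name)
        return value[self.averaging] if isinstance(value, dict) else value

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "per_class_specificity": self.per_class_specificity.tolist(),
            "averaging": self.averaging,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    def confusion_to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in CLASSES],
            columns=[f"pred_{c}" for c in CLASSES],
        )
        frame.to_csv(path, sep="\t")


def _specificity_from_confusion(matrix: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-class TN/(TN+FP), plus micro and macro averages."""
    total = matrix.sum()
    per_class = np.zeros(len(CLASSES))
    tn_sum = fp_sum = 0
    for k in CLASSES:
        fp = matrix[:, k].sum() - matrix[k, k]
        tn = total - matrix[k, :].sum() - fp
        per_class[k] = tn / (tn + fp) if (tn + fp) > 0 else 1.0
        tn_sum += tn
        fp_sum += fp
    micro = tn_sum / (tn_sum + fp_sum) if (tn_sum + fp_sum) > 0 else 1.0
    return per_class, micro, float(per_class.mean())


def evaluate(
    true_labels: Sequence[int],
    predictions: Sequence,
    averaging: str = "micro",
) -> MetricsReport:
    """Score predicted against true patch labels.

    ``predictions`` may be Prediction objects (their probabilities feed
    the one-vs-rest AUC), an (n, 3) probability array, or bare labels
    (AUC is then omitted with a warning).  Truth classes absent from
    ``true_labels`` are excluded from the AUC average, with a warning.
    """
    y_true = np.asarray(true_labels, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")

    probs: np.ndarray | None = None
    preds = list(predictions)
    if preds and isinstance(preds[0], Prediction):
        probs = np.vstack([p.probabilities for p in preds])
        y_pred = np.array([int(p.label) for p in preds])
    else:
        array = np.asarray(preds)
        if array.ndim == 2 and array.shape[1] == 3:
            probs = array.astype(float)
            y_pred = np.argmax(probs, axis=1)
        else:
            y_pred = array.astype(int)
    if len(y_pred) != len(y_true):
        raise ValueError("true_labels and predictions differ in length")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        bad = set(np.unique(arr)) - set(CLASSES)
        if bad:
            raise ValueError(f"{name} labels outside {{0,1,2}}: {sorted(bad)}")

    matrix = confusion_matrix(y_true, y_pred, labels=CLASSES)
    accuracy = float(np.trace(matrix) / matrix.sum())
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=CLASSES))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division handled via zero_division=0
        pr_micro, rc_micro, f1_micro, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=CLASSES, average="micro", zero_division=0
        )
        pr_macro, rc_macro, f1_macro, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=CLASSES, average="macro", zero_division=0
        )
    per_class_spec, spec_micro, spec_macro = _specificity_from_confusion(matrix)

    auc: float | None = None
    if probs is not None:
        present = [c for c in CLASSES if (y_true == c).any()]
        missing = sorted(set(CLASSES) - set(present))
        if missing:
            warnings.warn(f"classes {missing} absent from truth; excluded from AUC")
        if len(present) >= 2:
            per_class_auc = []
            for c in present:
                if len(np.unique(y_true == c)) < 2:
                    continue
                per_class_auc.append(roc_auc_score((y_true == c).astype(int), probs[:, c]))
            auc = float(np.mean(per_class_auc)) if per_class_auc else None
        else:
            warnings.warn("single-class truth; AUC undefined and omitted")
    else:
        warnings.warn("no probabilities supplied; AUC omitted")

    return MetricsReport(
        confusion=matrix,
        accuracy=accuracy,
        kappa=kappa,
        auc=auc,
        precision={"micro": float(pr_micro), "macro": float(pr_macro)},
        recall={"micro": float(rc_micro), "macro": float(rc_macro)},
        specificity={"micro": float(spec_micro), "macro": float(spec_macro)},
        f1={"micro": float(f1_micro), "macro": float(f1_macro)},
        per_class_specificity=per_class_spec,
        averaging=averaging,
    )


@dataclass
class CrossValidationReport:
    """Per-fold held-out reports plus mean/sd of the scalar metrics."""

    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    best_fold: int  # highest held-out accuracy; ties -> lowest index


def cross_validate(
    items: Sequence,
    labels: Sequence[int],
    backend_factory: Callable,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValidationReport:
    """Stratified k-fold evaluation of a classifier backend.

    ``backend_factory(train_items, train_labels)`` must return an object
    with ``predict(item) -> Prediction``; a rule-based backend simply
    ignores its training arguments.  Fold assignment is seeded and
    label-stratified; each fold is evaluated held-out.
    """
    labels = np.asarray(labels, dtype=int)
    assignment = split_dataset(labels, n_folds=n_folds, seed=seed)
    reports: list[MetricsReport] = []
    for fold in range(n_folds):
        test_mask = assignment == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        backend = backend_factory(
            [items[i] for i in train_idx], labels[train_idx]
        )
        predictions = [backend.predict(items[i]) for i in test_idx]
        reports.append(evaluate(labels[test_idx], predictions))

    scalar_names = ["accuracy", "kappa", "precision", "recall", "specificity", "f1"]
    mean = {}
    sd = {}
    for name in scalar_names:
        values = np.array([r.scalar(name) for r in reports])
        mean[name] = float(values.mean())
        sd[name] = float(values.std())
    aucs = [r.auc for r in reports if r.auc is not None]
    if aucs:
        mean["auc"] = float(np.mean(aucs))
        sd["auc"] = float(np.std(aucs))
    accuracies = [r.accuracy for r in reports]
    best_fold = int(np.argmax(accuracies))
    return CrossValidationReport(fold_reports=reports, mean=mean, sd=sd, best_fold=best_fold)
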