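"""Held-out evaluation: confusion matrices and per-class/macro precision.

Precision of class c is TP_c over the column sum of the confusion matrix
(everything predicted as c); the macro value averages over classes that were
actually predicted at least once — classes with an empty column are flagged
and excluded rather than counted as zero.  Window-level predictions are
aggregated to trial level by majority vote (ties broken by summed score)
before scoring, so each recorded grasp counts once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import CNNLSTM
from .synthetic import LabeledDataset
from .training import make_windows

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "precision_score",
    "predict_trials",
    "evaluate_task",
]


@dataclass
class EvalReport:
    confusion: np.ndarray  # rows = true class, columns = predicted
    per_class_precision: np.ndarray  # %, NaN for never-predicted classes
    macro_precision: float  # %
    n_test: int
    class_names: list[str]
    undefined_classes: list[int]

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class_precision": [
                None if np.isnan(p) else float(p) for p in self.per_class_precision
            ],
            "macro_precision": float(self.macro_precision),
            "n_test": int(self.n_test),
            "class_names": list(self.class_names),
            "undefined_classes": list(map(int, self.undefined_classes)),
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def precision_score(confusion: np.ndarray) -> tuple[np.ndarray, float, list[int]]:
    """Per-class and macro precision in percent from a confusion matrix.

    Returns (per_class %, macro %, undefined class indices); classes whose
    column is empty are NaN per-class and excluded from the macro mean.
    """
    cm = np.asarray(confusion, dtype=float)
    col = cm.sum(axis=0)
    if np.all(col == 0):
        raise ValueError("confusion matrix is empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = 100.0 * np.diag(cm) / col
    undefined = [int(i) for i in np.flatnonzero(col == 0)]
    per_class[col == 0] = np.nan
    macro = float(np.nanmean(per_class))
    return per_class, macro, undefined


def predict_trials(
    model: CNNLSTM, dataset: LabeledDataset, part: str | None = "test"
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level (true, predicted) labels via majority vote over windows."""
    X, _, tids = make_windows(dataset, model.config.input_length, part)
    scores = []
    for lo in range(0, X.shape[0], 256):
        scores.append(model.forward(X[lo : lo + 256], train=False))
    scores = np.concatenate(scores, axis=0)
    win_pred = scores.argmax(axis=1)
    trials = np.unique(tids)
    n_classes = model.config.n_classes
    y_true = np.empty(trials.size, dtype=int)
    y_pred = np.empty(trials.size, dtype=int)
    for j, t in enumerate(trials):
        sel = tids == t
        votes = np.bincount(win_pred[sel], minlength=n_classes)
        top = np.flatnonzero(votes == votes.max())
        if top.size == 1:
            y_pred[j] = top[0]
        else:  # tie: highest summed score among tied classes
            sums = scores[sel].sum(axis=0)
            y_pred[j] = top[np.argmax(sums[top])]
        y_true[j] = dataset.labels[t]
    return y_true, y_pred


def evaluate_task(
    model: CNNLSTM, dataset: LabeledDataset, part: str | None = "test"
) -> EvalReport:
    """Score a trained model on a dataset split (deterministic, eval mode)."""
    if model.config.n_classes != dataset.n_classes:
        raise ValueError(
            f"model has {model.config.n_classes} classes, dataset "
            f"{dataset.n_classes}"
        )
    y_true, y_pred = predict_trials(model, dataset, part)
    if y_true.size == 0:
        raise ValueError(f"split {part!r} is empty")
    cm = confusion_matrix(y_true, y_pred, dataset.n_classes)
    per_class, macro, undefined = precision_score(cm)
    return EvalReport(
        confusion=cm,
        per_class_precision=per_class,
        macro_precision=macro,
        n_test=int(y_true.size),
        class_names=list(dataset.class_names),
        undefined_classes=undefined,
    )
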