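"""Per-fold classification metrics and cross-fold aggregation.

Per fold: a confusion matrix (rows = true class, columns = predicted) and
accuracy, balanced accuracy, and macro-averaged precision / recall / F1.
Across folds: arithmetic mean and sample standard deviation of each metric.
Macro (unweighted) averaging is used for the multiclass metrics, consistent
with reporting balanced accuracy; degenerate 0/0 ratios (e.g. a class never
predicted) are defined as 0 with a logged warning so metrics stay defined
on degenerate folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import DataError
from .vit_features import CLASS_NAMES

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "macro_precision",
    "macro_recall",
    "macro_f1",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i][j] = samples of true class i predicted as class j."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_order)
        if counts.shape != (n, n):
            raise DataError(
                f"confusion matrix shape {counts.shape} inconsistent with "
                f"{n} classes"
            )
        if (counts < 0).any():
            raise DataError("confusion matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    balanced_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{f.name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldResult:
    fold_index: int
    metrics: MetricSet
    confusion: ConfusionMatrix | None = None


@dataclass(frozen=True)
class EvalReport:
    """Per-fold results plus mean and sample sd of each metric across folds."""

    per_fold: tuple[FoldResult, ...]
    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


def confusion(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_order: tuple[str, ...] = CLASS_NAMES,
) -> ConfusionMatrix:
    """Confusion matrix over integer-coded labels in the fixed class order."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.shape != y_pred.shape:
        raise DataError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} "
            "predicted labels"
        )
    n = len(class_order)
    labels = np.concatenate([y_true, y_pred])
    if labels.size and (labels.min() < 0 or labels.max() >= n):
        raise DataError(f"labels outside [0, {n}) encountered")
    if y_true.size == 0:
        counts = np.zeros((n, n), dtype=np.int64)
    else:
        counts = _sk_confusion(y_true, y_pred, labels=np.arange(n))
    return ConfusionMatrix(counts, class_order)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, balanced accuracy and macro precision/recall/F1 from counts."""
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise DataError("cannot compute metrics from an empty confusion matrix")
    diag = np.diag(counts)
    col = counts.sum(0)
    row = counts.sum(1)
    if (col == 0).any() or (row == 0).any():
        logger.warning(
            "degenerate confusion matrix (empty class row/column); "
            "0/0 ratios defined as 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return MetricSet(
        accuracy=float(diag.sum() / total),
        balanced_accuracy=float(recall.mean()),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def aggregate(per_fold: list[FoldResult]) -> EvalReport:
    """Mean and sample standard deviation of each metric across folds."""
    if not per_fold:
        raise DataError("cannot aggregate an empty list of fold results")
    values = {
        name: np.array([getattr(r.metrics, name) for r in per_fold])
        for name in METRIC_NAMES
    }
    mean = {name: float(v.mean()) for name, v in values.items()}
    sd = {
        name: float(v.std(ddof=1)) if len(v) > 1 else 0.0
        for name, v in values.items()
    }
    return EvalReport(per_fold=tuple(per_fold), mean=mean, sd=sd)


def evaluate_fold(
    fold_index: int, y_true: np.ndarray, y_pred: np.ndarray
) -> FoldResult:
    cm = confusion(y_true, y_pred)
    return FoldResult(fold_index, metrics_from_confusion(cm), cm)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def report_to_json(report: EvalReport, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "n_folds": report.n_folds,
        "mean": report.mean,
        "sd": report.sd,
        "per_fold": [
            {
                "fold": r.fold_index,
                "metrics": r.metrics.as_dict(),
                "confusion": None if r.confusion is None else r.confusion.counts.tolist(),
            }
            for r in report.per_fold
        ],
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def report_to_csv(report: EvalReport, path: str | Path) -> Path:
    """Flat per-fold metric table (one row per fold)."""
    path = Path(path)
    rows = [
        {"fold": r.fold_index, **r.metrics.as_dict()} for r in report.per_fold
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plot_confusion(cm: ConfusionMatrix, path: str | Path) -> Path:
    """Optional confusion-matrix heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm.counts, cmap="Blues")
    n = len(cm.class_order)
    ax.set_xticks(range(n), cm.class_order)
    ax.set_yticks(range(n), cm.class_order)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
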