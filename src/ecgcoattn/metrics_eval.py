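"""Label-based evaluation: AUC, accuracy, F1, precision, recall.

Metrics are computed per class and macro-averaged with equal class weight,
the convention for multi-label ECG benchmarks.  "Accuracy" in multi-label
mode is the mean over labels of per-label binary accuracy
(TP + TN) / N.  AUC is the area under the ROC curve (trapezoidal, ties at
one half), undefined and excluded from the macro mean for classes with a
single observed label value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "MetricsReport", "binary_auc", "roc_points", "confusion_metrics",
    "macro_auc_score", "evaluate", "plot_roc",
]


def binary_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for one binary label.

    Equals the probability that a random positive outscores a random
    negative, with ties counted one half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, labels: np.ndarray):
    """(FPR, TPR) points of the ROC curve, from (0,0) to (1,1)."""
    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores, float))
    return fpr, tpr


def macro_auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted mean of per-class AUC; single-class columns excluded."""
    aucs = []
    for k in range(labels.shape[1]):
        if len(np.unique(labels[:, k])) == 2:
            aucs.append(binary_auc(scores[:, k], labels[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


def confusion_metrics(pred_binary: np.ndarray, labels: np.ndarray) -> dict:
    """Per-class precision, recall, F1, accuracy plus macro means.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    F1 = 2 P R / (P + R); accuracy = (TP+TN)/N.
    Any zero denominator yields 0 for that metric.
    """
    pred = np.asarray(pred_binary)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {lab.shape}")
    if pred.ndim == 1:
        pred, lab = pred[:, None], lab[:, None]
    n = pred.shape[0]
    tp = ((pred == 1) & (lab == 1)).sum(axis=0).astype(float)
    fp = ((pred == 1) & (lab == 0)).sum(axis=0).astype(float)
    fn = ((pred == 0) & (lab == 1)).sum(axis=0).astype(float)
    tn = ((pred == 0) & (lab == 0)).sum(axis=0).astype(float)

    def safe_div(a, b):
        return np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)

    precision = safe_div(tp, tp + fp)
    recall = safe_div(tp, tp + fn)
    f1 = safe_div(2 * precision * recall, precision + recall)
    accuracy = (tp + tn) / n
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "accuracy": accuracy,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "macro_accuracy": float(accuracy.mean()),
    }


@dataclass
class MetricsReport:
    macro_auc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    per_class: pd.DataFrame
    roc: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "macro_auc": self.macro_auc, "accuracy": self.accuracy,
            "f1": self.f1, "precision": self.precision, "recall": self.recall,
            "per_class": json.loads(
                self.per_class.to_json(orient="records")),
        }

    def save(self, out_dir: str | Path, stem: str = "metrics") -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / f"{stem}.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        self.per_class.to_csv(out_dir / f"{stem}_per_class.csv", index=False)
        return out_dir / f"{stem}.json"


def evaluate(model, x: np.ndarray, y: np.ndarray,
             mode: str = "multilabel", threshold: float = 0.5,
             class_names: list[str] | None = None,
             batch_size: int = 64) -> MetricsReport:
    """Score a model on labeled arrays and assemble the full report.

    Scores come from an eval-mode forward pass; binarization is at
    ``threshold`` for multilabel tasks and argmax for exclusive tasks.
    """
    from .train_loop import predict_scores  # local import, avoids a cycle
    scores = predict_scores(model, x, mode, batch_size)
    return report_from_scores(scores, y, mode, threshold, class_names)


def report_from_scores(scores: np.ndarray, y: np.ndarray,
                       mode: str = "multilabel", threshold: float = 0.5,
                       class_names: list[str] | None = None) -> MetricsReport:
    y = np.asarray(y).astype(int)
    k = y.shape[1]
    names = class_names or [f"class{i}" for i in range(k)]
    if mode == "multilabel":
        pred = (scores >= threshold).astype(int)
    else:
        pred = np.zeros_like(y)
        pred[np.arange(len(y)), scores.argmax(axis=1)] = 1
    cm = confusion_metrics(pred, y)
    aucs, roc = [], {}
    for i, name in enumerate(names):
        if len(np.unique(y[:, i])) == 2:
            aucs.append(binary_auc(scores[:, i], y[:, i]))
            roc[name] = roc_points(scores[:, i], y[:, i])
        else:
            aucs.append(np.nan)     # reported as missing, excluded from macro
    per_class = pd.DataFrame({
        "class": names, "auc": aucs, "f1": cm["f1"],
        "precision": cm["precision"], "recall": cm["recall"],
        "accuracy": cm["accuracy"],
    })
    auc_arr = np.asarray(aucs, dtype=float)
    macro_auc = float(np.nanmean(auc_arr)) if not np.isnan(auc_arr).all() \
        else float("nan")
    return MetricsReport(
        macro_auc=macro_auc, accuracy=cm["macro_accuracy"],
        f1=cm["macro_f1"], precision=cm["macro_precision"],
        recall=cm["macro_recall"], per_class=per_class, roc=roc)


def plot_roc(report: MetricsReport, path: str | Path) -> Path:
    """Render per-class ROC curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (fpr, tpr) in report.roc.items():
        auc = report.per_class.loc[report.per_class["class"] == name,
                                   "auc"].item()
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
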