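"""Final-model assessment: confusion matrix, accuracy/precision/recall/F1,
ROC curve and AUC for a chosen feature mask and classifier.

Scalar metrics follow the standard definitions — accuracy (tp+tn)/total,
precision tp/(tp+fp), recall tp/(tp+fn), F1 the harmonic mean of the
two.  Degenerate denominators yield 0 with a logged warning (needed for
degenerate CV folds).  Multiclass metrics are macro-averaged one-vs-rest
by default; the ROC curve is produced for binary targets and the macro
one-vs-rest AUC for multiclass.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .data_io import Dataset
from .fitness import FitnessSpec, make_classifier, _effective_folds

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "compute_metrics",
    "roc_auc",
    "evaluate_mask",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        t = y_true == positive
        p = y_pred == positive
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
        )

    def as_table(self) -> np.ndarray:
        """2x2 table in [[tn, fp], [fn, tp]] layout."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass
class EvalReport:
    """Assessment of one mask + classifier on one dataset."""

    counts: Union[ConfusionCounts, np.ndarray]
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_points: List[Tuple[float, float]]
    auc: Optional[float]
    averaging: str = "binary"

    def to_dict(self) -> dict:
        counts = (
            vars(self.counts)
            if isinstance(self.counts, ConfusionCounts)
            else np.asarray(self.counts).tolist()
        )
        return {
            "counts": counts,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "averaging": self.averaging,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["accuracy", "precision", "recall", "f1", "auc"])
            writer.writerow([self.accuracy, self.precision, self.recall, self.f1, self.auc])

    def write_roc_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fpr", "tpr"])
            writer.writerows(self.roc_points)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning 0", stacklevel=3)
        return 0.0
    return num / den


def _binary_prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    return precision, recall, f1


def compute_metrics(
    counts: Union[ConfusionCounts, np.ndarray],
    averaging: str = "binary",
) -> dict:
    """Scalar metrics from confusion counts.

    ``counts`` is either binary :class:`ConfusionCounts` or a k x k
    contingency table (rows = true class, columns = predicted class).
    ``averaging`` is ``"binary"`` or ``"macro"`` (unweighted mean of
    per-class one-vs-rest precision/recall/F1).
    """
    if averaging not in ("binary", "macro"):
        raise ValueError("averaging must be 'binary' or 'macro'")
    if isinstance(counts, ConfusionCounts):
        if counts.total < 1:
            raise ValueError("need at least one scored instance")
        if averaging == "binary":
            accuracy = (counts.tp + counts.tn) / counts.total
            precision, recall, f1 = _binary_prf(counts.tp, counts.fp, counts.fn)
            return {
                "accuracy": accuracy,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        counts = counts.as_table()

    table = np.asarray(counts)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    if (table < 0).any() or table.sum() < 1:
        raise ValueError("table needs non-negative counts and >= 1 instance")
    total = table.sum()
    accuracy = np.trace(table) / total
    precisions, recalls, f1s = [], [], []
    for c in range(table.shape[0]):
        tp = table[c, c]
        fp = table[:, c].sum() - tp
        fn = table[c, :].sum() - tp
        p, r, f = _binary_prf(int(tp), int(fp), int(fn))
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return {
        "accuracy": float(accuracy),
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "f1": float(np.mean(f1s)),
    }


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[List[Tuple[float, float]], float]:
    """Step ROC curve and its area for binary labels.

    The curve is the threshold sweep over distinct scores; the area is
    the trapezoid under it, which equals the Mann-Whitney pair statistic
    P(score+ > score-) + 0.5 * P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, _ = roc_curve(labels.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def _cv_scores(model, X, y_enc, folds: int, seed: int):
    """Cross-validated class predictions and positive-class scores."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = cross_val_predict(model, X, y_enc, cv=skf)
    scores = None
    if hasattr(model, "predict_proba") or hasattr(model, "decision_function"):
        method = "predict_proba" if hasattr(model, "predict_proba") else "decision_function"
        try:
            raw = cross_val_predict(model, X, y_enc, cv=skf, method=method)
            scores = raw[:, 1] if raw.ndim == 2 and raw.shape[1] == 2 else raw
        except Exception:
            scores = None
    return y_pred, scores


def evaluate_mask(
    dataset: Dataset,
    mask: np.ndarray,
    spec: FitnessSpec,
    averaging: Optional[str] = None,
) -> EvalReport:
    """Cross-validated assessment of a feature mask with a final classifier.

    Predictions are pooled across stratified CV folds, then scored.
    Binary targets get full ROC points; multiclass targets get macro
    metrics and (when scores are available) a macro one-vs-rest AUC.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != dataset.n_features:
        raise ValueError("mask length does not match dataset feature count")
    if not mask.any():
        raise ValueError("mask must select at least one feature")
    X = dataset.features[:, mask]
    y = dataset.target_encoded
    n_classes = np.unique(y).size
    if averaging is None:
        averaging = "binary" if n_classes == 2 else "macro"

    folds = _effective_folds(y, spec.cv_folds)
    model = make_classifier(spec)
    y_pred, scores = _cv_scores(model, X, y, folds, spec.cv_seed)

    if n_classes == 2:
        counts = ConfusionCounts.from_predictions(y, y_pred, positive=1)
        metrics = compute_metrics(counts, averaging)
        roc_points: List[Tuple[float, float]] = []
        auc_value: Optional[float] = None
        if scores is not None and scores.ndim == 1:
            roc_points, auc_value = roc_auc(scores, y == 1)
    else:
        k = n_classes
        table = np.zeros((k, k), dtype=int)
        for t, p in zip(y, y_pred):
            table[t, p] += 1
        counts = table
        metrics = compute_metrics(table, "macro")
        roc_points = []
        auc_value = None
        if scores is not None and np.ndim(scores) == 2:
            from sklearn.metrics import roc_auc_score

            auc_value = float(
                roc_auc_score(y, scores, multi_class="ovr", average="macro")
            )

    return EvalReport(
        counts=counts,
        accuracy=metrics["accuracy"],
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        roc_points=roc_points,
        auc=auc_value,
        averaging=averaging,
    )


def plot_report(report: EvalReport, path_prefix: str) -> List[str]:
    """Optional confusion-matrix / ROC plots (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    table = (
        report.counts.as_table()
        if isinstance(report.counts, ConfusionCounts)
        else np.asarray(report.counts)
    )
    fig, ax = plt.subplots()
    ax.imshow(table, cmap="Blues")
    for (i, j), v in np.ndenumerate(table):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title("Confusion matrix")
    cm_path = f"{path_prefix}_confusion.png"
    fig.savefig(cm_path)
    plt.close(fig)
    written.append(cm_path)

    if report.roc_points:
        fpr, tpr = zip(*report.roc_points)
        fig, ax = plt.subplots()
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {report.auc:.3f}")
        ax.plot([0, 1], [0, 1], "--", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        ax.set_title("ROC curve")
        roc_path = f"{path_prefix}_roc.png"
        fig.savefig(roc_path)
        plt.close(fig)
        written.append(roc_path)
    return written
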