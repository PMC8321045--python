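"""Classification metrics, confusion matrices and embedding diagnostics.

Reported metrics are overall accuracy, Cohen's kappa, and macro-averaged
f1 / precision / recall ("macro" = unweighted arithmetic mean over all n
classes, empty classes contributing 0 — a conservative convention for
undefined precision/recall). Confusion matrices are emitted raw and in the
two normalized forms used for reading precision (columns sum to 1) and
recall (rows sum to 1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from .io import StandardizedSample, stack_series

__all__ = [
    "MetricsReport",
    "ConfusionPair",
    "evaluate",
    "metrics_from_predictions",
    "embedding_separation",
]


@dataclass
class MetricsReport:
    overall_accuracy: float
    kappa: float
    mean_f1: float
    mean_precision: float
    mean_recall: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    n_samples: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("per_class_precision", "per_class_recall", "per_class_f1"):
            d[k] = [float(v) for v in d[k]]
        return d


@dataclass
class ConfusionPair:
    """Raw counts plus precision- and recall-normalized confusion matrices."""

    raw: np.ndarray
    precision_normalized: np.ndarray  # columns sum to 1 (non-empty columns)
    recall_normalized: np.ndarray  # rows sum to 1 (non-empty rows)


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> tuple[MetricsReport, ConfusionPair]:
    """Compute the full report from label/prediction arrays.

    Macro averages run over *all* ``n_classes`` classes, including ones
    absent from ``y_true`` (their precision/recall/f1 count as 0).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty sample list")
    labels = np.arange(n_classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    raw = confusion_matrix(y_true, y_pred, labels=labels)
    col = raw.sum(axis=0, keepdims=True).astype(float)
    row = raw.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_norm = np.where(col > 0, raw / np.where(col > 0, col, 1.0), 0.0)
        rec_norm = np.where(row > 0, raw / np.where(row > 0, row, 1.0), 0.0)
    report = MetricsReport(
        overall_accuracy=float(accuracy_score(y_true, y_pred)),
        kappa=float(cohen_kappa_score(y_true, y_pred, labels=labels)),
        mean_f1=float(np.mean(f1)),
        mean_precision=float(np.mean(prec)),
        mean_recall=float(np.mean(rec)),
        per_class_precision=prec,
        per_class_recall=rec,
        per_class_f1=f1,
        n_samples=int(len(y_true)),
    )
    return report, ConfusionPair(raw, prec_norm, rec_norm)


def evaluate(
    predictor, samples: Sequence[StandardizedSample], n_classes: int | None = None
) -> tuple[MetricsReport, ConfusionPair]:
    """Run a fitted classifier over standardized samples and score it.

    ``predictor`` is anything with a ``predict(X)`` over (n, T, B) arrays —
    typically a fitted :class:`~tripletlstm.estimators.TripletLSTMClassifier`.
    Prediction is the argmax of the class probabilities; argmax ties break
    toward the lower class index.
    """
    if not samples:
        raise ValueError("empty sample list")
    X, y, _ = stack_series(samples)
    y_pred = predictor.predict(X)
    if n_classes is None:
        n_classes = (
            len(predictor.classes_)
            if hasattr(predictor, "classes_")
            else int(max(y.max(), y_pred.max())) + 1
        )
    return metrics_from_predictions(y, y_pred, n_classes)


def embedding_separation(
    embeddings: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Within/between-class embedding scatter and their Fisher-style ratio.

    Returns mean within-class pairwise distance (classes with < 2 members
    are excluded), mean between-class centroid distance, and
    ``ratio = between / within`` (``inf`` when every within-class pair
    coincides).
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("embedding separation needs >= 2 classes")
    within = []
    centroids = []
    for c in classes:
        pts = embeddings[labels == c]
        centroids.append(pts.mean(axis=0))
        if len(pts) >= 2:
            within.append(float(pdist(pts).mean()))
    centroids = np.vstack(centroids)
    between = float(cdist(centroids, centroids)[np.triu_indices(len(classes), 1)].mean())
    mean_within = float(np.mean(within)) if within else 0.0
    ratio = between / mean_within if mean_within > 0 else float("inf")
    return {
        "within_class_distance": mean_within,
        "between_class_distance": between,
        "ratio": ratio,
    }
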