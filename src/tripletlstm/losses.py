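"""Loss components: inverse-median-frequency weighted cross-entropy, margin
triplet loss, and their weighted combination.

For class frequencies g(k) (class-k count over total) with median g~, the
class weight is w_k = g~ / g(k), so the median-frequency class has weight 1
and rarer classes are up-weighted. The classification loss for a sample of
true class c is -w_c log p_c. The metric loss for a triplet is the hinge
max(0, D(a,p) - D(a,n) + m) with D the (non-squared) Euclidean distance
between embeddings, averaged over the batch. The total objective per
triplet is the sum of the three member cross-entropies plus lambda times
the triplet term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassWeights",
    "LossConfig",
    "class_weights",
    "weighted_cross_entropy",
    "triplet_loss",
    "total_loss",
    "LOG_EPS",
]

#: lower clamp for log arguments, avoiding -inf on confident wrong predictions
LOG_EPS = 1e-12


@dataclass
class ClassWeights:
    """Per-class weights w_k = g~/g(k) with their provenance frequencies."""

    weights: np.ndarray
    frequencies: np.ndarray
    median_frequency: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("class weights must be finite and positive")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class LossConfig:
    """Margin m and combination weight lambda (defaults 1.0, the values at
    which validation-set tuning of the method found its optimum)."""

    margin: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.margin < 0 or self.lam < 0:
            raise ValueError("margin and lambda must be non-negative")


def class_weights(train_labels, n: int) -> ClassWeights:
    """Inverse median frequency weights from the *training* label multiset.

    Every class 0..n-1 must appear at least once (otherwise its frequency is
    zero and the weight undefined).
    """
    labels = np.asarray(train_labels)
    counts = np.bincount(labels, minlength=n)
    if len(counts) > n:
        raise ValueError(f"labels exceed declared class count {n}")
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"classes {empty} have no training samples")
    freq = counts / counts.sum()
    med = float(np.median(freq))
    return ClassWeights(weights=med / freq, frequencies=freq, median_frequency=med)


def _check_one_hot(y: np.ndarray) -> int:
    y = np.asarray(y)
    if y.ndim != 1 or not np.all((y == 0) | (y == 1)) or y.sum() != 1:
        raise ValueError("y must be a one-hot vector")
    return int(np.argmax(y))


def weighted_cross_entropy(probs: np.ndarray, y: np.ndarray, w: ClassWeights) -> float:
    """-w_c log p_c for the one-hot true class c; log clamped at 1e-12."""
    probs = np.asarray(probs, dtype=np.float64)
    c = _check_one_hot(y)
    if len(probs) != len(y) or len(probs) != len(w):
        raise ValueError("probs, y and weights must have equal length")
    return float(-w.weights[c] * np.log(max(probs[c], LOG_EPS)))


def euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise (or vector) Euclidean distance."""
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return np.linalg.norm(d, axis=-1)


def triplet_loss(e_a: np.ndarray, e_p: np.ndarray, e_n: np.ndarray,
                 m: float = 1.0) -> float:
    """Hinge max(0, D(a,p) - D(a,n) + m), averaged over the batch.

    Accepts single embeddings (1-D) or stacked batches (2-D); D is the
    non-squared Euclidean norm.
    """
    e_a, e_p, e_n = (np.asarray(e) for e in (e_a, e_p, e_n))
    if not (e_a.shape == e_p.shape == e_n.shape):
        raise ValueError("embedding shapes must match")
    hinge = np.maximum(0.0, euclidean(e_a, e_p) - euclidean(e_a, e_n) + m)
    return float(np.mean(hinge))


def total_loss(
    probs_p: np.ndarray,
    probs_a: np.ndarray,
    probs_n: np.ndarray,
    labels: tuple[np.ndarray, np.ndarray, np.ndarray],
    e_p: np.ndarray,
    e_a: np.ndarray,
    e_n: np.ndarray,
    w: ClassWeights,
    cfg: LossConfig,
) -> float:
    """Per-triplet total: Lc(p) + Lc(a) + Lc(n) + lambda * Lm(p, a, n).

    ``labels`` carries the one-hot labels of (positive, anchor, negative).
    """
    y_p, y_a, y_n = labels
    ce = (
        weighted_cross_entropy(probs_p, y_p, w)
        + weighted_cross_entropy(probs_a, y_a, w)
        + weighted_cross_entropy(probs_n, y_n, w)
    )
    return ce + cfg.lam * triplet_loss(e_a, e_p, e_n, cfg.margin)
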