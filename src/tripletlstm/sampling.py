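"""Training-triplet construction under two selection protocols.

Setup 1 (region-stratified): the anchor and the negative are drawn from the
same training region, while the positive comes from a *different* training
region. This deliberately manufactures hard positives (same class, shifted
regional profile) and hard-ish negatives (different class, same regional
conditions), exposing inter-region intra-class variance to the metric loss.

Setup 2 (naive): positives share the anchor's class and negatives do not;
regions are ignored and the whole training set is used.

Anchors are drawn uniformly over the training set, with replacement; there
is no online hard-negative mining. One epoch is conventionally one pass of
``len(train)`` triplets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .io import DatasetSplit, StandardizedSample

__all__ = [
    "Triplet",
    "TripletBatch",
    "sample_setup1",
    "sample_setup2",
    "batches",
    "sample_triplet_indices",
]


@dataclass
class Triplet:
    """Ordered (anchor, positive, negative) with its selection protocol tag."""

    anchor: StandardizedSample
    positive: StandardizedSample
    negative: StandardizedSample
    setup_tag: str

    def __post_init__(self) -> None:
        if self.anchor.label != self.positive.label:
            raise ValueError("anchor and positive must share a class")
        if self.anchor.label == self.negative.label:
            raise ValueError("negative must differ in class from the anchor")
        if self.setup_tag == "setup1":
            if self.anchor.region != self.negative.region:
                raise ValueError("setup1: anchor and negative must share a region")
            if self.positive.region == self.anchor.region:
                raise ValueError("setup1: positive must come from another region")


@dataclass
class TripletBatch:
    triplets: list[Triplet]

    def __len__(self) -> int:
        return len(self.triplets)


def _check_setup1_feasible(labels: np.ndarray, regions: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(np.unique(regions)) < 2:
        raise ValueError("setup1 requires a training set spanning >= 2 regions")
    bad = [
        int(c)
        for c in classes
        if len(np.unique(regions[labels == c])) < 2
    ]
    if bad:
        raise ValueError(
            f"setup1 infeasible: classes {bad} are present in only one region "
            "(no cross-region positive exists)"
        )


def sample_triplet_indices(
    labels: np.ndarray,
    regions: np.ndarray | None,
    count: int,
    rng: np.random.Generator,
    setup: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index-level sampler shared by the object API and the trainers.

    Returns (anchor_idx, positive_idx, negative_idx), each of length ``count``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if setup not in (1, 2):
        raise ValueError("setup must be 1 or 2")
    if len(np.unique(labels)) < 2:
        raise ValueError("triplet sampling requires >= 2 classes in the training set")
    if setup == 1:
        if regions is None:
            raise ValueError("setup1 requires region codes")
        regions = np.asarray(regions)
        _check_setup1_feasible(labels, regions)

    anchors = rng.integers(0, n, size=count)
    positives = np.empty(count, dtype=np.int64)
    negatives = np.empty(count, dtype=np.int64)

    if setup == 2:
        pos_pool = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
        neg_pool = {c: np.flatnonzero(labels != c) for c in np.unique(labels)}
        for i, a in enumerate(anchors):
            c = labels[a]
            positives[i] = rng.choice(pos_pool[c])
            negatives[i] = rng.choice(neg_pool[c])
    else:
        # pools keyed by the anchor's (class, region)
        pos_pool = {}
        neg_pool = {}
        for c in np.unique(labels):
            for r in np.unique(regions):
                pos_pool[(c, r)] = np.flatnonzero((labels == c) & (regions != r))
                neg_pool[(c, r)] = np.flatnonzero((labels != c) & (regions == r))
        for i, a in enumerate(anchors):
            key = (labels[a], regions[a])
            if len(neg_pool[key]) == 0:
                raise ValueError(
                    f"setup1 infeasible: no negative in region {key[1]!r} "
                    f"for class {key[0]}"
                )
            positives[i] = rng.choice(pos_pool[key])
            negatives[i] = rng.choice(neg_pool[key])
    return anchors, positives, negatives


def _materialize(
    split: DatasetSplit,
    idx: tuple[np.ndarray, np.ndarray, np.ndarray],
    tag: str,
) -> list[Triplet]:
    train = split.train
    return [
        Triplet(anchor=train[a], positive=train[p], negative=train[g], setup_tag=tag)
        for a, p, g in zip(*idx)
    ]


def sample_setup1(
    split: DatasetSplit, count: int, rng: np.random.Generator
) -> list[Triplet]:
    """Region-stratified triplets: anchor/negative same region, positive from
    another training region. Raises when any class lives in a single region."""
    labels = np.array([s.label for s in split.train])
    regions = np.array([s.region for s in split.train], dtype=object)
    idx = sample_triplet_indices(labels, regions, count, rng, setup=1)
    return _materialize(split, idx, "setup1")


def sample_setup2(
    split: DatasetSplit, count: int, rng: np.random.Generator
) -> list[Triplet]:
    """Naive random triplets over the entire training set (no region rule)."""
    labels = np.array([s.label for s in split.train])
    idx = sample_triplet_indices(labels, None, count, rng, setup=2)
    return _materialize(split, idx, "setup2")


def batches(triplets: Sequence[Triplet], batch_size: int) -> Iterator[TripletBatch]:
    """Order-preserving chunking; the last batch may be short."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    for start in range(0, len(triplets), batch_size):
        yield TripletBatch(list(triplets[start : start + batch_size]))
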