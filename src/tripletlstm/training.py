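"""High-level training entry points over :class:`DatasetSplit` objects.

Thin wrappers around the scikit-learn style estimators: :func:`train` fits
one model on a region-based split with early stopping on validation
accuracy, :func:`multirun` repeats training across distinct seeds and
aggregates test metrics as mean +/- sd, mirroring the usual
multiple-initialization reporting protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .encoder import EncoderConfig
from .estimators import LSTMClassifier, RunRecord, TripletLSTMClassifier, seed_streams
from .evaluation import MetricsReport, evaluate
from .io import DatasetSplit, stack_series
from .losses import LossConfig

__all__ = ["TrainConfig", "RunRecord", "train", "multirun", "seed_streams"]


@dataclass
class TrainConfig:
    """Optimization settings (Adam throughout)."""

    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 20
    patience: int = 5
    seed: int = 0
    triplet_setup: int = 1
    triplets_per_epoch: int | None = None
    loss: LossConfig = field(default_factory=LossConfig)
    weighting: str = "inverse_median_frequency"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def _estimator_from_configs(
    model_cfg: EncoderConfig, train_cfg: TrainConfig, vanilla: bool
):
    common = dict(
        n_classes=model_cfg.n_classes,
        hidden_dim=model_cfg.hidden_dim,
        num_layers=model_cfg.num_layers,
        bidirectional=model_cfg.bidirectional,
        class_weighting=train_cfg.weighting,
        batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate,
        max_epochs=train_cfg.max_epochs,
        patience=train_cfg.patience,
        random_state=train_cfg.seed,
    )
    if vanilla:
        return LSTMClassifier(**common)
    return TripletLSTMClassifier(
        margin=train_cfg.loss.margin,
        lam=train_cfg.loss.lam,
        triplet_setup=train_cfg.triplet_setup,
        triplets_per_epoch=train_cfg.triplets_per_epoch,
        **common,
    )


def train(
    split: DatasetSplit,
    model_cfg: EncoderConfig | None = None,
    train_cfg: TrainConfig | None = None,
    vanilla: bool = False,
) -> tuple[TripletLSTMClassifier | LSTMClassifier, RunRecord]:
    """Fit a (triplet or vanilla) LSTM on a split; returns (estimator, record).

    Early stopping keeps the checkpoint with the best validation accuracy
    when the split has a validation part.
    """
    X, y, regions = stack_series(split.train)
    if model_cfg is None:
        model_cfg = EncoderConfig(
            input_bands=X.shape[2], n_classes=split.class_count
        )
    if train_cfg is None:
        train_cfg = TrainConfig()
    val = None
    if split.validation:
        Xv, yv, _ = stack_series(split.validation)
        val = (Xv, yv)
    est = _estimator_from_configs(model_cfg, train_cfg, vanilla)
    if vanilla:
        est.fit(X, y, validation_data=val)
    else:
        est.fit(X, y, regions=regions, validation_data=val)
    return est, est.history_


def multirun(
    split: DatasetSplit,
    model_cfg: EncoderConfig | None = None,
    train_cfg: TrainConfig | None = None,
    n_runs: int = 5,
    seeds: list[int] | None = None,
    vanilla: bool = False,
) -> dict:
    """Train ``n_runs`` models with distinct seeds; aggregate test metrics.

    Returns per-metric mean and standard deviation (population sd, so a
    single run reports sd = 0) plus the per-run reports.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if train_cfg is None:
        train_cfg = TrainConfig()
    if seeds is None:
        seeds = [train_cfg.seed + i for i in range(n_runs)]
    if len(set(seeds)) != n_runs:
        raise ValueError("seeds must be distinct, one per run")

    reports: list[MetricsReport] = []
    for s in seeds:
        cfg = dataclasses.replace(train_cfg, seed=s)
        est, _ = train(split, model_cfg, cfg, vanilla=vanilla)
        report, _ = evaluate(est, split.test, n_classes=split.class_count)
        reports.append(report)

    keys = ["overall_accuracy", "kappa", "mean_f1", "mean_precision", "mean_recall"]
    agg = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports])
        agg[k] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    agg["per_run"] = [r.to_dict() for r in reports]
    agg["seeds"] = list(seeds)
    return agg
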