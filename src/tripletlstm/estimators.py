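"""Scikit-learn style estimators for the triplet LSTM and its vanilla twin.

:class:`TripletLSTMClassifier` trains three weight-shared bidirectional LSTM
branches: every optimization step draws a batch of (positive, anchor,
negative) triplets, pushes all members through the single shared encoder,
and minimizes the sum of the three inverse-median-frequency weighted
cross-entropies plus ``lam`` times the margin triplet loss on the
embeddings. :class:`LSTMClassifier` is the corresponding plain classifier
(one branch, weighted cross-entropy only); with ``lam = 0`` and a matched
sample stream the two produce identical loss trajectories.

Both follow the scikit-learn estimator contract (``get_params`` /
``set_params``, trailing-underscore fitted attributes) and compose with
model-selection utilities; ``transform`` exposes the learned embedding so a
fitted model can also act as a feature extractor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from ._nn import Adam, softmax
from .encoder import EncoderConfig, EncoderModel
from .losses import LOG_EPS, class_weights
from .sampling import sample_triplet_indices

__all__ = [
    "TripletLSTMClassifier",
    "LSTMClassifier",
    "RunRecord",
    "seed_streams",
]


@dataclass
class RunRecord:
    """Per-epoch training trace and the early-stopping outcome."""

    ce_loss: list[float] = field(default_factory=list)
    triplet_loss: list[float] = field(default_factory=list)
    total_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    batch_total: list[float] = field(default_factory=list)
    batch_ce: list[float] = field(default_factory=list)
    best_epoch: int = -1
    seed: int | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.total_loss)

    @property
    def best_val_accuracy(self) -> float:
        return max(self.val_accuracy) if self.val_accuracy else float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def seed_streams(random_state: int | None):
    """Derive the (init, sampling, shuffle) random streams from one seed.

    Returns ``(init_seedseq, sampling_rng, shuffle_rng)``. Both estimators
    use this same derivation, which is what makes matched-seed equivalence
    harnesses possible.
    """
    ss = np.random.SeedSequence(random_state)
    init_ss, samp_ss, shuf_ss = ss.spawn(3)
    return init_ss, np.random.default_rng(samp_ss), np.random.default_rng(shuf_ss)


def _one_hot_grad_scale(probs, y_idx, w_vec, scale):
    """d(scale * mean_i w_{y_i} CE_i)/dlogits for a batch."""
    n = len(y_idx)
    d = probs.copy()
    d[np.arange(n), y_idx] -= 1.0
    d *= (w_vec[y_idx] * (scale / n))[:, None]
    return d


def _train_step(
    model: EncoderModel,
    opt: Adam,
    Xb: np.ndarray,
    yb: np.ndarray,
    w_vec: np.ndarray,
    ce_scale: float,
    lam: float,
    margin: float,
    triplet_thirds: bool,
) -> tuple[float, float, float]:
    """One forward/backward/Adam step shared by both estimators.

    When ``triplet_thirds`` is true the batch is laid out as
    ``[positives; anchors; negatives]`` in equal thirds and the margin
    triplet term is added on the embeddings.

    Returns (ce, triplet, total) where ``ce`` already carries ``ce_scale``.
    """
    emb, caches = model.forward(Xb, with_cache=True)
    logits = model.logits(emb)
    probs = softmax(logits)
    n_all = len(Xb)
    p_true = np.maximum(probs[np.arange(n_all), yb], LOG_EPS)
    ce = float(ce_scale * np.mean(w_vec[yb] * -np.log(p_true)))
    dlogits = _one_hot_grad_scale(probs, yb, w_vec.astype(probs.dtype), ce_scale)

    trip = 0.0
    demb = np.zeros_like(emb)
    if triplet_thirds:
        n3 = n_all // 3
        e_p, e_a, e_n = emb[:n3], emb[n3 : 2 * n3], emb[2 * n3 :]
        diff_ap = e_a - e_p
        diff_an = e_a - e_n
        d_ap = np.linalg.norm(diff_ap, axis=1)
        d_an = np.linalg.norm(diff_an, axis=1)
        hinge = d_ap - d_an + margin
        active = hinge > 0
        trip = float(np.mean(np.maximum(hinge, 0.0)))
        if lam > 0 and active.any():
            tiny = np.finfo(emb.dtype).tiny
            u_ap = diff_ap / np.maximum(d_ap, tiny)[:, None]
            u_an = diff_an / np.maximum(d_an, tiny)[:, None]
            coef = (lam / n3) * active.astype(emb.dtype)[:, None]
            demb[:n3] -= coef * u_ap
            demb[n3 : 2 * n3] += coef * (u_ap - u_an)
            demb[2 * n3 :] += coef * u_an

    total = ce + lam * trip
    if not np.isfinite(total):
        raise RuntimeError(
            f"non-finite training loss (ce={ce}, triplet={trip}); aborting"
        )
    grads = model.backward(demb, caches, dlogits=dlogits, emb=emb)
    opt.step(model.params, grads)
    return ce, trip, total


def _validate_X(X, n_bands=None):
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError(f"X must be (n_samples, T, B), got shape {X.shape}")
    if n_bands is not None and X.shape[2] != n_bands:
        raise ValueError(f"X has {X.shape[2]} bands, model expects {n_bands}")
    return X


class _RecurrentBase(BaseEstimator):
    """Shared inference surface and fit bookkeeping."""

    def _setup_normalization(self, model, X):
        """Per-band standardization fitted on the training set.

        All-positive, strongly correlated reflectance inputs condition the
        optimization badly; z-scoring them (a fixed affine transform stored
        with the model, not a trainable part) markedly speeds convergence.
        """
        if getattr(self, "standardize_input", True):
            flat = X.reshape(-1, X.shape[2])
            mean = flat.mean(axis=0)
            std = flat.std(axis=0)
            model.set_normalization(mean, std)
            self.input_mean_ = mean
            self.input_std_ = std
        else:
            self.input_mean_ = None
            self.input_std_ = None

    def _init_common(self, X, y):
        X = _validate_X(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        n_classes = self.n_classes or int(classes.max()) + 1
        if classes.min() < 0 or classes.max() >= n_classes:
            raise ValueError("labels must be 0-based integers below n_classes")
        return X, y, n_classes

    def _class_weight_vector(self, y, n_classes):
        if isinstance(self.class_weighting, (list, tuple, np.ndarray)):
            w = np.asarray(self.class_weighting, dtype=np.float64)
            if len(w) != n_classes:
                raise ValueError("explicit class weights have wrong length")
            return w, None
        if self.class_weighting == "inverse_median_frequency":
            cw = class_weights(y, n_classes)
            return cw.weights, cw
        if self.class_weighting in (None, "none"):
            return np.ones(n_classes), None
        raise ValueError(f"unknown class_weighting {self.class_weighting!r}")

    def _val_accuracy(self, model, validation_data):
        if validation_data is None:
            return None
        Xv, yv = validation_data
        pred = self._predict_with(model, Xv)
        return float(np.mean(pred == np.asarray(yv)))

    def _predict_with(self, model, X, chunk=1024):
        X = _validate_X(X, model.config.input_bands)
        out = np.empty(len(X), dtype=np.int64)
        for s in range(0, len(X), chunk):
            probs = model.predict_proba(X[s : s + chunk])
            out[s : s + chunk] = np.argmax(probs, axis=1)
        return out

    # ------------------------------------------------------- fitted surface
    def predict(self, X):
        self._check_fitted()
        return self._predict_with(self.model_, X)

    def predict_proba(self, X):
        self._check_fitted()
        X = _validate_X(X, self.model_.config.input_bands)
        chunks = [
            self.model_.predict_proba(X[s : s + 1024])
            for s in range(0, len(X), 1024)
        ]
        return np.concatenate(chunks, axis=0).astype(np.float64)

    def transform(self, X):
        """Embeddings f(X), shape (n, E)."""
        self._check_fitted()
        X = _validate_X(X, self.model_.config.input_bands)
        chunks = [
            self.model_.forward(X[s : s + 1024]) for s in range(0, len(X), 1024)
        ]
        return np.concatenate(chunks, axis=0).astype(np.float64)

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")

    def _encoder_config(self, n_bands, n_classes):
        return EncoderConfig(
            input_bands=n_bands,
            hidden_dim=self.hidden_dim,
            num_layers=self.num_layers,
            bidirectional=self.bidirectional,
            dropout=0.0,
            n_classes=n_classes,
        )

    def _finalize(self, model, record, best_params):
        if best_params is not None:
            model.set_params_(best_params)
        self.model_ = model
        self.history_ = record
        self.best_epoch_ = record.best_epoch
        return self


class TripletLSTMClassifier(_RecurrentBase, ClassifierMixin, TransformerMixin):
    """Triplet metric-learning LSTM classifier.

    Parameters
    ----------
    triplet_setup : {1, 2}
        1 = region-stratified triplets (anchor and negative share a region,
        positive from another region; requires ``regions`` at fit time);
        2 = naive random triplets.
    lam : float
        Weight of the triplet loss in the total objective (0 disables
        metric learning and the model degenerates to a vanilla LSTM run
        over the triplet member stream).
    margin : float
        Triplet hinge margin m.
    triplets_per_epoch : int or None
        Triplets drawn per epoch; None means one per training sample.
    patience : int
        Early-stopping patience in epochs without strict validation
        accuracy improvement (only when validation data is supplied).
    """

    def __init__(
        self,
        n_classes: int | None = None,
        hidden_dim: int = 128,
        num_layers: int = 1,
        bidirectional: bool = True,
        margin: float = 1.0,
        lam: float = 1.0,
        class_weighting="inverse_median_frequency",
        triplet_setup: int = 1,
        triplets_per_epoch: int | None = None,
        batch_size: int = 256,
        learning_rate: float = 0.001,
        max_epochs: int = 20,
        patience: int = 5,
        standardize_input: bool = True,
        random_state: int | None = None,
        dtype: str = "float32",
    ):
        self.n_classes = n_classes
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.standardize_input = standardize_input
        self.margin = margin
        self.lam = lam
        self.class_weighting = class_weighting
        self.triplet_setup = triplet_setup
        self.triplets_per_epoch = triplets_per_epoch
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state
        self.dtype = dtype

    def fit(self, X, y, regions=None, validation_data=None):
        """Train on standardized series X (n, T, B) with labels y.

        ``regions`` (length-n array of region codes) is required for
        triplet setup 1. ``validation_data = (X_val, y_val)`` enables
        per-epoch validation accuracy and early stopping on its maximum.
        """
        X, y, n_classes = self._init_common(X, y)
        if self.triplet_setup == 1 and regions is None:
            raise ValueError("triplet_setup=1 requires regions")
        regions = None if regions is None else np.asarray(regions, dtype=object)

        init_ss, samp_rng, _ = seed_streams(self.random_state)
        model = EncoderModel(
            self._encoder_config(X.shape[2], n_classes),
            seed=init_ss,
            dtype=np.dtype(self.dtype),
        )
        self._setup_normalization(model, X)
        self.initial_params_ = model.copy_params()
        w_vec, cw = self._class_weight_vector(y, n_classes)
        opt = model.make_optimizer(self.learning_rate)
        record = RunRecord(seed=self.random_state)

        count = self.triplets_per_epoch or len(X)
        best_acc, best_params, since_best = -np.inf, None, 0
        for _epoch in range(self.max_epochs):
            ia, ip, ineg = sample_triplet_indices(
                y, regions, count, samp_rng, setup=self.triplet_setup
            )
            ce_sum = trip_sum = tot_sum = 0.0
            n_batches = 0
            for s in range(0, count, self.batch_size):
                sl = slice(s, min(s + self.batch_size, count))
                Xb = np.concatenate([X[ip[sl]], X[ia[sl]], X[ineg[sl]]])
                yb = np.concatenate([y[ip[sl]], y[ia[sl]], y[ineg[sl]]])
                ce, trip, tot = _train_step(
                    model, opt, Xb, yb, w_vec,
                    ce_scale=3.0, lam=self.lam, margin=self.margin,
                    triplet_thirds=True,
                )
                ce_sum += ce
                trip_sum += trip
                tot_sum += tot
                n_batches += 1
                record.batch_total.append(tot)
                record.batch_ce.append(ce)
            record.ce_loss.append(ce_sum / n_batches)
            record.triplet_loss.append(trip_sum / n_batches)
            record.total_loss.append(tot_sum / n_batches)

            acc = self._val_accuracy(model, validation_data)
            if acc is not None:
                record.val_accuracy.append(acc)
                if acc > best_acc:
                    best_acc, best_params, since_best = acc, model.copy_params(), 0
                    record.best_epoch = _epoch
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if record.best_epoch < 0:
            record.best_epoch = record.n_epochs - 1
        self.classes_ = np.arange(n_classes)
        self.class_weights_ = cw
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self._finalize(model, record, best_params)


class LSTMClassifier(_RecurrentBase, ClassifierMixin, TransformerMixin):
    """Plain (single-branch) LSTM classifier with weighted cross-entropy.

    ``objective_scale`` multiplies the per-batch mean cross-entropy; the
    default 1.0 is the ordinary objective, while 3.0 reproduces the
    per-triplet summation convention of the three-branch network, which is
    what makes exact degeneracy comparisons possible.
    """

    def __init__(
        self,
        n_classes: int | None = None,
        hidden_dim: int = 128,
        num_layers: int = 1,
        bidirectional: bool = True,
        class_weighting="inverse_median_frequency",
        batch_size: int = 256,
        learning_rate: float = 0.001,
        max_epochs: int = 20,
        patience: int = 5,
        shuffle: bool = True,
        objective_scale: float = 1.0,
        standardize_input: bool = True,
        random_state: int | None = None,
        dtype: str = "float32",
    ):
        self.n_classes = n_classes
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.standardize_input = standardize_input
        self.class_weighting = class_weighting
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.shuffle = shuffle
        self.objective_scale = objective_scale
        self.random_state = random_state
        self.dtype = dtype

    def fit(self, X, y, validation_data=None):
        X, y, n_classes = self._init_common(X, y)
        init_ss, _, shuf_rng = seed_streams(self.random_state)
        model = EncoderModel(
            self._encoder_config(X.shape[2], n_classes),
            seed=init_ss,
            dtype=np.dtype(self.dtype),
        )
        self._setup_normalization(model, X)
        self.initial_params_ = model.copy_params()
        w_vec, cw = self._class_weight_vector(y, n_classes)
        opt = model.make_optimizer(self.learning_rate)
        record = RunRecord(seed=self.random_state)

        n = len(X)
        best_acc, best_params, since_best = -np.inf, None, 0
        for _epoch in range(self.max_epochs):
            order = shuf_rng.permutation(n) if self.shuffle else np.arange(n)
            ce_sum = 0.0
            n_batches = 0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                ce, _, tot = _train_step(
                    model, opt, X[idx], y[idx], w_vec,
                    ce_scale=self.objective_scale, lam=0.0, margin=0.0,
                    triplet_thirds=False,
                )
                ce_sum += ce
                n_batches += 1
                record.batch_total.append(tot)
                record.batch_ce.append(ce)
            record.ce_loss.append(ce_sum / n_batches)
            record.triplet_loss.append(0.0)
            record.total_loss.append(ce_sum / n_batches)

            acc = self._val_accuracy(model, validation_data)
            if acc is not None:
                record.val_accuracy.append(acc)
                if acc > best_acc:
                    best_acc, best_params, since_best = acc, model.copy_params(), 0
                    record.best_epoch = _epoch
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if record.best_epoch < 0:
            record.best_epoch = record.n_epochs - 1
        self.classes_ = np.arange(n_classes)
        self.class_weights_ = cw
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self._finalize(model, record, best_params)
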