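"""The weight-shared recurrent encoder f(.) and its softmax head.

The triplet network's three "branches" are a presentation device: there is
exactly one parameter set, and every branch role (anchor / positive /
negative) evaluates the same function. The encoder is a stacked
(bi)directional LSTM; the embedding f(x) is the concatenation of the final
hidden states of the two directions of the top layer (dimension
``H * 2 = 256`` under the defaults), followed by a fully connected layer
and a softmax for classification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, init_lstm, lstm_backward, lstm_forward, softmax
from .io import StandardizedSample

__all__ = [
    "EncoderConfig",
    "EncoderModel",
    "embed",
    "classify",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1
BRANCH_ROLES = ("anchor", "positive", "negative")


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` defaults to 128 per direction; with ``bidirectional`` the
    embedding dimension is ``2 * hidden_dim``. ``dropout`` (on the embedding,
    training mode only) defaults to 0 so inference and tests are
    deterministic.
    """

    input_bands: int = 13
    hidden_dim: int = 128
    num_layers: int = 1
    bidirectional: bool = True
    dropout: float = 0.0
    n_classes: int = 13

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def embedding_dim(self) -> int:
        return self.hidden_dim * (2 if self.bidirectional else 1)


class EncoderModel:
    """Stacked (bi)LSTM encoder with a linear softmax head, NumPy end to end.

    Parameters are stored in a flat dict (``l0_fwd_Wx`` ... ``fc_W``); the
    training loop drives :meth:`forward` / :meth:`backward` directly, while
    :meth:`embed_array` and :meth:`predict_proba` are the inference surface.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        # fixed (non-trainable) per-band input normalization; identity until
        # set_normalization is called with training-set statistics
        self.input_offset = np.zeros(config.input_bands, dtype=self.dtype)
        self.input_scale = np.ones(config.input_bands, dtype=self.dtype)
        rng = np.random.default_rng(seed)
        H = config.hidden_dim
        dirs = ["fwd", "bwd"] if config.bidirectional else ["fwd"]
        self.params: dict[str, np.ndarray] = {}
        in_dim = config.input_bands
        for layer in range(config.num_layers):
            for d in dirs:
                p = init_lstm(rng, in_dim, H, dtype=self.dtype)
                for k, v in p.items():
                    self.params[f"l{layer}_{d}_{k}"] = v
            in_dim = H * len(dirs)
        E = config.embedding_dim
        k = 1.0 / np.sqrt(E)
        self.params["fc_W"] = rng.uniform(-k, k, size=(E, config.n_classes)).astype(
            self.dtype
        )
        self.params["fc_b"] = rng.uniform(-k, k, size=(config.n_classes,)).astype(
            self.dtype
        )

    # ---------------------------------------------------------------- forward
    def forward(self, X: np.ndarray, with_cache: bool = False):
        """Embed a batch (N, T, B) -> (N, E); optionally keep BPTT caches."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        if X.ndim != 3 or X.shape[2] != self.config.input_bands:
            raise ValueError(
                f"expected (N, T, {self.config.input_bands}) input, got {X.shape}"
            )
        X = (X - self.input_offset) / self.input_scale
        cfg = self.config
        caches = []
        inp = X
        for layer in range(cfg.num_layers):
            pf = self._layer_params(layer, "fwd")
            Hf, cf = lstm_forward(inp, **pf)
            if cfg.bidirectional:
                pb = self._layer_params(layer, "bwd")
                Hb_rev, cb = lstm_forward(np.ascontiguousarray(inp[:, ::-1]), **pb)
                out = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
            else:
                Hb_rev, cb = None, None
                out = Hf
            caches.append((cf, cb, Hf, Hb_rev))
            inp = out
        if cfg.bidirectional:
            emb = np.concatenate([caches[-1][2][:, -1], caches[-1][3][:, -1]], axis=1)
        else:
            emb = caches[-1][2][:, -1]
        return (emb, caches) if with_cache else emb

    def logits(self, emb: np.ndarray) -> np.ndarray:
        emb = np.asarray(emb, dtype=self.dtype)
        if emb.shape[-1] != self.config.embedding_dim:
            raise ValueError(
                f"embedding dimension {emb.shape[-1]} != "
                f"model's {self.config.embedding_dim}"
            )
        return emb @ self.params["fc_W"] + self.params["fc_b"]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(self.forward(X)))

    # --------------------------------------------------------------- backward
    def backward(self, demb: np.ndarray, caches, dlogits: np.ndarray | None = None,
                 emb: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Backprop from embedding (and optionally logit) gradients.

        ``demb`` is dL/d(embedding); when ``dlogits`` is given, the fully
        connected head's contribution is added (``emb`` is then required).
        """
        cfg = self.config
        H = cfg.hidden_dim
        grads: dict[str, np.ndarray] = {}
        demb = np.asarray(demb, dtype=self.dtype)
        if dlogits is not None:
            dlogits = np.asarray(dlogits, dtype=self.dtype)
            grads["fc_W"] = emb.T @ dlogits
            grads["fc_b"] = dlogits.sum(axis=0)
            demb = demb + dlogits @ self.params["fc_W"].T
        else:
            grads["fc_W"] = np.zeros_like(self.params["fc_W"])
            grads["fc_b"] = np.zeros_like(self.params["fc_b"])

        N = demb.shape[0]
        cf, cb, Hf, Hb_rev = caches[-1]
        T = Hf.shape[1]
        dHf = np.zeros((N, T, H), dtype=self.dtype)
        dHf[:, -1] = demb[:, :H]
        if cfg.bidirectional:
            dHb_rev = np.zeros((N, T, H), dtype=self.dtype)
            dHb_rev[:, -1] = demb[:, H:]
        for layer in range(cfg.num_layers - 1, -1, -1):
            cf, cb, Hf, Hb_rev = caches[layer]
            pf = self._layer_params(layer, "fwd")
            dXf, gf = lstm_backward(dHf, cf, pf["Wx"], pf["Wh"])
            for k, v in gf.items():
                grads[f"l{layer}_fwd_{k}"] = v
            if cfg.bidirectional:
                pb = self._layer_params(layer, "bwd")
                dXb_rev, gb = lstm_backward(dHb_rev, cb, pb["Wx"], pb["Wh"])
                for k, v in gb.items():
                    grads[f"l{layer}_bwd_{k}"] = v
                dInp = dXf + dXb_rev[:, ::-1]
            else:
                dInp = dXf
            if layer > 0:
                dHf = np.ascontiguousarray(dInp[:, :, :H])
                if cfg.bidirectional:
                    dHb_rev = np.ascontiguousarray(dInp[:, ::-1, H:])
        return grads

    # ------------------------------------------------------------------ utils
    def _layer_params(self, layer: int, d: str) -> dict[str, np.ndarray]:
        return {
            "Wx": self.params[f"l{layer}_{d}_Wx"],
            "Wh": self.params[f"l{layer}_{d}_Wh"],
            "b": self.params[f"l{layer}_{d}_b"],
        }

    def set_normalization(self, mean: np.ndarray, std: np.ndarray) -> None:
        """Fix per-band input standardization (computed on the training set)."""
        std = np.asarray(std, dtype=self.dtype)
        self.input_offset = np.asarray(mean, dtype=self.dtype)
        self.input_scale = np.where(std > 0, std, 1.0).astype(self.dtype)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(lr=lr)


# ------------------------------------------------------------------ op surface
def _as_batch(sample) -> np.ndarray:
    if isinstance(sample, StandardizedSample):
        return sample.series[None]
    arr = np.asarray(sample)
    return arr[None] if arr.ndim == 2 else arr


def embed(model: EncoderModel, sample, branch: str = "anchor") -> np.ndarray:
    """Embed one standardized sample (or array) through a branch role.

    The ``branch`` argument exists only to mirror the triplet wiring; all
    roles share one parameter set, so the output is role-independent.
    """
    if branch not in BRANCH_ROLES:
        raise ValueError(f"branch must be one of {BRANCH_ROLES}")
    single = isinstance(sample, StandardizedSample) or np.asarray(sample).ndim == 2
    out = model.forward(_as_batch(sample))
    return out[0] if single else out


def classify(model: EncoderModel, embedding: np.ndarray) -> np.ndarray:
    """Fully connected layer + softmax over an embedding (vector or batch)."""
    emb = np.asarray(embedding)
    squeeze = emb.ndim == 1
    if squeeze:
        emb = emb[None]
    probs = softmax(model.logits(emb))
    return probs[0] if squeeze else probs


# ------------------------------------------------------------------ checkpoints
def save_checkpoint(
    model: EncoderModel, path: str | Path, label_names: list[str] | None = None
) -> Path:
    """Single-file serialized weights + config + label map (npz with header)."""
    path = Path(path)
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "dtype": model.dtype.name,
        "label_names": label_names,
    }
    np.savez_compressed(
        path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        __input_offset__=model.input_offset, __input_scale__=model.input_scale,
        **model.params,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[EncoderModel, list[str] | None]:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format version {header['format_version']}"
            )
        model = EncoderModel(
            EncoderConfig(**header["config"]), seed=0, dtype=np.dtype(header["dtype"])
        )
        model.set_params_({k: data[k] for k in model.params})
        model.input_offset = data["__input_offset__"]
        model.input_scale = data["__input_scale__"]
    return model, header.get("label_names")
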