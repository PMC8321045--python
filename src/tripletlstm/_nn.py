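"""Minimal NumPy neural-network core: stacked bidirectional LSTM + Adam.

Hand-written forward and backward passes (backpropagation through time)
for a standard LSTM cell with gate order (input, forget, cell, output):

    gates = x_t Wx + h_{t-1} Wh + b
    c_t   = f * c_{t-1} + i * g
    h_t   = o * tanh(c_t)

Only the pieces the encoder needs are implemented; gradients are checked
against central finite differences in the test suite. Arithmetic is done in
a configurable dtype (float32 by default for GEMM throughput).
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_lstm", "lstm_forward", "lstm_backward", "Adam", "softmax"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_lstm(
    rng: np.random.Generator, input_dim: int, hidden_dim: int, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Uniform(-k, k) initialization with k = 1/sqrt(H), the usual RNN default."""
    k = 1.0 / np.sqrt(hidden_dim)
    return {
        "Wx": rng.uniform(-k, k, size=(input_dim, 4 * hidden_dim)).astype(dtype),
        "Wh": rng.uniform(-k, k, size=(hidden_dim, 4 * hidden_dim)).astype(dtype),
        "b": rng.uniform(-k, k, size=(4 * hidden_dim,)).astype(dtype),
    }


def lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run one direction over (N, T, D) input; returns (H_seq, cache).

    H_seq is (N, T, H); the cache holds the per-step gate activations needed
    by :func:`lstm_backward`.
    """
    N, T, D = X.shape
    H = Wh.shape[0]
    G_in = X.reshape(N * T, D) @ Wx
    G_in = G_in.reshape(N, T, 4 * H)
    h = np.zeros((N, H), dtype=X.dtype)
    c = np.zeros((N, H), dtype=X.dtype)
    Hs = np.empty((N, T, H), dtype=X.dtype)
    I = np.empty((N, T, H), dtype=X.dtype)
    F = np.empty((N, T, H), dtype=X.dtype)
    Gc = np.empty((N, T, H), dtype=X.dtype)
    O = np.empty((N, T, H), dtype=X.dtype)
    C = np.empty((N, T, H), dtype=X.dtype)
    TC = np.empty((N, T, H), dtype=X.dtype)
    for t in range(T):
        gates = G_in[:, t] + h @ Wh + b
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H : 2 * H])
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = _sigmoid(gates[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        I[:, t], F[:, t], Gc[:, t], O[:, t] = i, f, g, o
        C[:, t], TC[:, t], Hs[:, t] = c, tc, h
    cache = (X, Hs, I, F, Gc, O, C, TC)
    return Hs, cache


def lstm_backward(dHs: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """BPTT given per-timestep gradients dHs (N, T, H).

    Returns (dX, grads) with grads keyed like the parameter dict.
    """
    X, Hs, I, F, Gc, O, C, TC = cache
    N, T, D = X.shape
    H = Wh.shape[0]
    dGates = np.empty((N, T, 4 * H), dtype=X.dtype)
    dh_next = np.zeros((N, H), dtype=X.dtype)
    dc_next = np.zeros((N, H), dtype=X.dtype)
    for t in range(T - 1, -1, -1):
        dh = dHs[:, t] + dh_next
        i, f, g, o = I[:, t], F[:, t], Gc[:, t], O[:, t]
        tc = TC[:, t]
        c_prev = C[:, t - 1] if t > 0 else np.zeros((N, H), dtype=X.dtype)
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dGates[:, t, :H] = di * i * (1.0 - i)
        dGates[:, t, H : 2 * H] = df * f * (1.0 - f)
        dGates[:, t, 2 * H : 3 * H] = dg * (1.0 - g * g)
        dGates[:, t, 3 * H :] = do * o * (1.0 - o)
        dh_next = dGates[:, t] @ Wh.T
        dc_next = dc * f
    flatG = dGates.reshape(N * T, 4 * H)
    Hprev = np.zeros_like(Hs)
    Hprev[:, 1:] = Hs[:, :-1]
    grads = {
        "Wx": X.reshape(N * T, D).T @ flatG,
        "Wh": Hprev.reshape(N * T, H).T @ flatG,
        "b": flatG.sum(axis=0),
    }
    dX = (flatG @ Wx.T).reshape(N, T, D)
    return dX, grads


class Adam:
    """Standard Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * (g * g)
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            params[k] -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                params[k].dtype
            )
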