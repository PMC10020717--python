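"""Minimal NumPy neural-network core.

Implements exactly what the surrogate and the shape autoencoder need: a
batched LSTM layer with full backpropagation through time, per-timestep
dense layers, sigmoid/tanh activations, a masked MSE loss and an Adam
optimizer with global gradient-norm clipping.  Everything is deterministic
given the initialization seed and batch order.

Analytic gradients are verified against central finite differences in the
test suite; that check is the correctness oracle for this module.

Conventions: sequences are (B, T, F) arrays with a (B, T) validity mask;
LSTM gate order in the packed weight matrices is [i, f, g, o].
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .exceptions import TrainingError


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    return expit(x)


# ---------------------------------------------------------------------------
# parameter initialization


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def init_lstm(rng: np.random.Generator, n_in: int, hidden: int) -> dict[str, np.ndarray]:
    """One LSTM direction: packed input/recurrent weights and bias.

    The forget-gate bias starts at 1 so early training does not wash out
    long-range state.
    """
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0
    return {
        "Wx": glorot(rng, n_in, 4 * hidden),
        "Wh": glorot(rng, hidden, 4 * hidden),
        "b": b,
    }


# ---------------------------------------------------------------------------
# LSTM forward / backward


def lstm_forward(x: np.ndarray, p: dict[str, np.ndarray]):
    """Run one LSTM direction over (B, T, F); returns (B, T, H) and a cache."""
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    cache = []
    for t in range(T):
        z = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((x[:, t], h, c, i, f, g, o, c_new, tc))
        h, c = h_new, c_new
        hs[:, t] = h
    return hs, cache


def lstm_backward(dh_seq: np.ndarray, p: dict[str, np.ndarray], cache):
    """BPTT for one direction; dh_seq is (B, T, H) upstream gradient."""
    B, T, H = dh_seq.shape
    dWx = np.zeros_like(p["Wx"])
    dWh = np.zeros_like(p["Wh"])
    db = np.zeros_like(p["b"])
    dx = np.empty((B, T, p["Wx"].shape[0]))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        xt, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
        dh = dh_seq[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += xt.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ p["Wx"].T
        dh_next = dz @ p["Wh"].T
    return {"Wx": dWx, "Wh": dWh, "b": db}, dx


def reverse_sequences(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each padded sequence within its own valid length."""
    out = np.zeros_like(x)
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, :L][::-1]
    return out


# ---------------------------------------------------------------------------
# Adam


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 1.0) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if not np.isfinite(total):
                raise TrainingError("non-finite gradient norm (training diverged)")
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


# ---------------------------------------------------------------------------
# padding helpers


def pad_sequences(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack variable-length (N_i, F) arrays into (B, T, F) + mask + lengths."""
    lengths = np.array([a.shape[0] for a in arrays])
    T = int(lengths.max())
    F = arrays[0].shape[1]
    x = np.zeros((len(arrays), T, F))
    mask = np.zeros((len(arrays), T), dtype=bool)
    for b, a in enumerate(arrays):
        x[b, : a.shape[0]] = a
        mask[b, : a.shape[0]] = True
    return x, mask, lengths
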