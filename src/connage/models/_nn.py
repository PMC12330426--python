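"""Minimal NumPy neural-network primitives.

Implements exactly what the two brain-age architectures need: Glorot
initialization, an Adam optimizer over a flat parameter dict, and an LSTM
layer with hand-written forward/backward passes. Everything is seeded and
single-threaded, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMDirection:
    """One direction of an LSTM layer (gate order i, f, g, o).

    Parameters live in the shared dict under ``{name}_W`` (stacked
    input+recurrent weights, shape (d+H, 4H)) and ``{name}_b``; the forget
    gate bias is initialized to 1 for gradient flow at the start of training.
    """

    def __init__(self, name: str, input_dim: int, hidden: int,
                 params: dict, rng: np.random.Generator):
        self.name, self.d, self.h = name, input_dim, hidden
        if f"{name}_W" not in params:
            params[f"{name}_W"] = glorot(rng, input_dim + hidden, 4 * hidden)
            b = np.zeros(4 * hidden)
            b[hidden: 2 * hidden] = 1.0
            params[f"{name}_b"] = b
        self.params = params

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """x: (B, T, d) -> hidden states (B, T, H) plus cache for backward."""
        W = self.params[f"{self.name}_W"]
        b = self.params[f"{self.name}_b"]
        B, T, _ = x.shape
        H = self.h
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            zin = np.concatenate([x[:, t], h], axis=1)
            gates = zin @ W + b
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H:2 * H])
            g = np.tanh(gates[:, 2 * H:3 * H])
            o = _sigmoid(gates[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache.append((zin, i, f, g, o, c_prev, tc))
        return hs, cache

    def backward(self, dhs: np.ndarray, cache: list, grads: dict
                 ) -> np.ndarray:
        """dhs: (B, T, H) gradient w.r.t. each output state -> dx (B, T, d)."""
        W = self.params[f"{self.name}_W"]
        B, T, H = dhs.shape
        dW = np.zeros_like(W)
        db = np.zeros(4 * H)
        dx = np.empty((B, T, self.d))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            zin, i, f, g, o, c_prev, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dgates = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            dW += zin.T @ dgates
            db += dgates.sum(axis=0)
            dzin = dgates @ W.T
            dx[:, t] = dzin[:, : self.d]
            dh_next = dzin[:, self.d:]
        grads[f"{self.name}_W"] = grads.get(f"{self.name}_W", 0.0) + dW
        grads[f"{self.name}_b"] = grads.get(f"{self.name}_b", 0.0) + db
        return dx
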