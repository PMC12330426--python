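"""Bidirectional LSTM brain-age regression on dynamic connectivity sequences.

The input per subject is the sequence of vectorized windowed connectivity
matrices (T windows x d features). A stack of bidirectional LSTM layers
(three layers of 128 hidden units and dropout 0.1 between layers by default)
processes the sequence; the final hidden states of the two directions of the
top layer are concatenated and mapped to age by a linear readout.
"""

from __future__ import annotations

import numpy as np

from ._neural import _NeuralBrainAge
from ._nn import LSTMDirection, glorot


class BiLSTMBrainAge(_NeuralBrainAge):
    """Brain-age regressor over (n, T, d) window-feature sequences."""

    _expected_ndim = 3

    def __init__(self, hidden_units=128, recurrent_layers=3, dropout=0.1,
                 learning_rate=1e-3, batch_size=64, epochs=100, n_folds=5,
                 random_state=0, ensemble=False):
        super().__init__(learning_rate=learning_rate, batch_size=batch_size,
                         epochs=epochs, n_folds=n_folds,
                         random_state=random_state, ensemble=ensemble)
        self.hidden_units = hidden_units
        self.recurrent_layers = recurrent_layers
        self.dropout = dropout

    def _layer_dirs(self, params, input_dim, rng=None):
        """(Re)build the LSTMDirection views over the shared parameter dict."""
        rng = rng or np.random.default_rng(0)  # unused when params exist
        h = self.hidden_units
        layers = []
        for layer in range(self.recurrent_layers):
            d = input_dim if layer == 0 else 2 * h
            layers.append(
                (LSTMDirection(f"l{layer}f", d, h, params, rng),
                 LSTMDirection(f"l{layer}b", d, h, params, rng))
            )
        return layers

    def _init_params(self, X, rng):
        params = {}
        self._layer_dirs(params, X.shape[2], rng)
        params["out_w"] = glorot(rng, 2 * self.hidden_units, 1)[:, 0]
        params["out_b"] = np.zeros(1)
        return params

    def _forward(self, params, Xb, train_rng=None):
        h = self.hidden_units
        layers = self._layer_dirs(params, Xb.shape[2])
        seq = Xb
        caches = []
        for li, (fwd, bwd) in enumerate(layers):
            hs_f, cache_f = fwd.forward(seq)
            hs_b_rev, cache_b = bwd.forward(seq[:, ::-1])
            out = np.concatenate([hs_f, hs_b_rev[:, ::-1]], axis=2)
            mask = None
            last = li == len(layers) - 1
            if train_rng is not None and self.dropout > 0 and not last:
                mask = (
                    train_rng.random(out.shape) >= self.dropout
                ) / (1.0 - self.dropout)
                out = out * mask
            caches.append((cache_f, cache_b, mask, seq.shape[2]))
            seq = out
        final = np.concatenate([seq[:, -1, :h], seq[:, 0, h:]], axis=1)
        pred = final @ params["out_w"] + params["out_b"][0]
        return pred, (caches, final, Xb.shape)

    def _backward(self, params, cache, dpred):
        caches, final, x_shape = cache
        h = self.hidden_units
        layers = self._layer_dirs(params, x_shape[2])
        grads = {
            "out_w": final.T @ dpred,
            "out_b": np.array([dpred.sum()]),
        }
        d_final = np.outer(dpred, params["out_w"])  # (B, 2H)

        B, T = x_shape[0], x_shape[1]
        # gradient w.r.t. the top layer's output sequence: only the two
        # direction-final states receive signal from the readout
        d_out = np.zeros((B, T, 2 * h))
        d_out[:, -1, :h] = d_final[:, :h]
        d_out[:, 0, h:] = d_final[:, h:]

        for li in range(len(layers) - 1, -1, -1):
            fwd, bwd = layers[li]
            cache_f, cache_b, mask, _ = caches[li]
            if mask is not None:
                d_out = d_out * mask
            dx_f = fwd.backward(d_out[:, :, :h], cache_f, grads)
            dx_b = bwd.backward(d_out[:, ::-1, h:], cache_b, grads)
            if li > 0:
                d_out = dx_f + dx_b[:, ::-1]
        return grads
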