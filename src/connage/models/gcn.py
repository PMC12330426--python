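"""Graph-convolutional brain-age regression on static connectivity.

The connectivity matrix plays both roles of a graph network input: its
absolute value, row-normalized, is the propagation operator A, and its rows
are the node features (each component described by its connectivity profile).
Each layer computes ``H <- relu(A H W + b)``; node representations are then
global-mean-pooled and a linear readout predicts age.
"""

from __future__ import annotations

import numpy as np

from ._neural import _NeuralBrainAge
from ._nn import glorot


def _propagation_operator(Xb: np.ndarray) -> np.ndarray:
    """Row-normalized |FNC| as the graph propagation matrix (batched)."""
    A = np.abs(Xb)
    return A / A.sum(axis=2, keepdims=True)


class GraphConvBrainAge(_NeuralBrainAge):
    """Brain-age regressor over C x C connectivity matrices.

    Parameters
    ----------
    graph_layer_sizes : tuple of int
        Hidden widths of the graph-convolution layers (ReLU activations;
        the readout is linear).
    learning_rate, batch_size, epochs, n_folds, random_state, ensemble
        Training protocol parameters (Adam on mean absolute error).
    """

    _expected_ndim = 3

    def __init__(self, graph_layer_sizes=(64, 32), learning_rate=1e-3,
                 batch_size=64, epochs=100, n_folds=5, random_state=0,
                 ensemble=False):
        super().__init__(learning_rate=learning_rate, batch_size=batch_size,
                         epochs=epochs, n_folds=n_folds,
                         random_state=random_state, ensemble=ensemble)
        self.graph_layer_sizes = graph_layer_sizes

    def _init_params(self, X, rng):
        c = X.shape[1]
        dims = [c] + list(self.graph_layer_sizes)
        params = {}
        for layer in range(len(dims) - 1):
            params[f"W{layer}"] = glorot(rng, dims[layer], dims[layer + 1])
            params[f"b{layer}"] = np.zeros(dims[layer + 1])
        params["out_w"] = glorot(rng, dims[-1], 1)[:, 0]
        params["out_b"] = np.zeros(1)
        return params

    def _forward(self, params, Xb, train_rng=None):
        A = _propagation_operator(Xb)
        H = Xb
        layer_caches = []
        for layer in range(len(self.graph_layer_sizes)):
            AH = A @ H
            Z = AH @ params[f"W{layer}"] + params[f"b{layer}"]
            layer_caches.append((AH, Z))
            H = np.maximum(Z, 0.0)
        pooled = H.mean(axis=1)
        pred = pooled @ params["out_w"] + params["out_b"][0]
        return pred, (A, layer_caches, pooled, H.shape[1])

    def _backward(self, params, cache, dpred):
        A, layer_caches, pooled, n_nodes = cache
        grads = {
            "out_w": pooled.T @ dpred,
            "out_b": np.array([dpred.sum()]),
        }
        dH = (dpred[:, None, None] * params["out_w"][None, None, :]) / n_nodes
        dH = np.broadcast_to(dH, (len(dpred), n_nodes, len(params["out_w"]))).copy()
        for layer in range(len(self.graph_layer_sizes) - 1, -1, -1):
            AH, Z = layer_caches[layer]
            dZ = dH * (Z > 0.0)
            grads[f"W{layer}"] = np.einsum("bci,bcj->ij", AH, dZ)
            grads[f"b{layer}"] = dZ.sum(axis=(0, 1))
            if layer > 0:
                dAH = dZ @ params[f"W{layer}"].T
                dH = np.einsum("bkc,bkj->bcj", A, dAH)
        return grads
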