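"""Epoch/minibatch training loop shared by the neural families.

Both neural regressors are trained with Adam on mean absolute error
(learning rate 1e-3, batch size 64, 100 epochs by default), targets
standardized internally so the loss is scale-free. The per-epoch validation
MAE curve drives best-epoch selection in the cross-validation protocol.
"""

from __future__ import annotations

import copy

import numpy as np

from ..errors import DivergenceError
from ._base import BaseBrainAge
from ._nn import Adam


class _NeuralBrainAge(BaseBrainAge):
    """Subclasses provide ``_init_params``, ``_forward`` and ``_backward``."""

    def __init__(self, learning_rate=1e-3, batch_size=64, epochs=100,
                 n_folds=5, random_state=0, ensemble=False):
        super().__init__(n_folds=n_folds, random_state=random_state,
                         ensemble=ensemble)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs

    # hooks ---------------------------------------------------------------
    def _init_params(self, X, rng):
        raise NotImplementedError

    def _forward(self, params, Xb, train_rng=None):
        """Return (prediction in standardized units, cache)."""
        raise NotImplementedError

    def _backward(self, params, cache, dpred):
        raise NotImplementedError

    # training ------------------------------------------------------------
    def _run_training(self, X_train, y_train, X_val, y_val, rng):
        y_mean = float(y_train.mean())
        y_std = float(y_train.std())
        if y_std == 0.0:
            y_std = 1.0
        yz = (y_train - y_mean) / y_std

        params = self._init_params(X_train, rng)
        opt = Adam(params, lr=self.learning_rate)
        n_epochs = self.epochs if X_val is not None else getattr(
            self, "_refit_epochs_", self.epochs
        )

        history = []
        best = (np.inf, None, 0)
        n = len(yz)
        for epoch in range(1, n_epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred, cache = self._forward(params, X_train[idx], train_rng=rng)
                resid = pred - yz[idx]
                loss = float(np.mean(np.abs(resid)))
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                dpred = np.sign(resid) / len(idx)
                grads = self._backward(params, cache, dpred)
                opt.step(grads)
            if X_val is not None:
                state = {"params": params, "y_mean": y_mean, "y_std": y_std}
                val_mae = float(
                    np.mean(np.abs(self._predict_state(state, X_val) - y_val))
                )
                history.append(val_mae)
                if val_mae < best[0]:
                    best = (val_mae, copy.deepcopy(params), epoch)

        state = {"params": params, "y_mean": y_mean, "y_std": y_std}
        if X_val is None:
            return state, [], n_epochs, state
        best_state = {"params": best[1], "y_mean": y_mean, "y_std": y_std}
        return state, history, best[2], best_state

    def _predict_state(self, state, X):
        pred, _ = self._forward(state["params"], X, train_rng=None)
        return state["y_mean"] + state["y_std"] * pred
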