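"""Linear (ridge) brain-age baseline.

Not part of the original modeling suite; included as a fast, closed-form,
fully deterministic reference family for testing and smoke runs. Follows the
same cross-validation protocol as the neural models (a single "epoch").
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from ._base import BaseBrainAge


class RidgeBrainAge(BaseBrainAge):
    """Ridge regression on vectorized connectivity features (n x d)."""

    _expected_ndim = 2

    def __init__(self, alpha=1.0, n_folds=5, random_state=0, ensemble=False):
        super().__init__(n_folds=n_folds, random_state=random_state,
                         ensemble=ensemble)
        self.alpha = alpha

    def _run_training(self, X_train, y_train, X_val, y_val, rng):
        model = make_pipeline(
            StandardScaler(), Ridge(alpha=self.alpha, random_state=0)
        )
        model.fit(X_train, y_train)
        if X_val is None:
            return model, [], 1, model
        val_mae = float(np.mean(np.abs(model.predict(X_val) - y_val)))
        return model, [val_mae], 1, model

    def _predict_state(self, state, X):
        return state.predict(X)
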