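"""Shared training protocol for the brain-age regressors.

All model families follow the same scheme: K-fold cross-validation (grouped,
so a subject with multiple scans never spans folds), per-fold validation
curves, selection of the epoch with the best mean validation MAE, and a final
refit on all data at the selected epoch count. The estimators follow the
scikit-learn contract (``fit``/``predict``, ``get_params``, trailing
underscore on fitted attributes) and compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_is_fitted

from ..errors import DivergenceError, InvalidInputError


class BaseBrainAge(BaseEstimator, RegressorMixin):
    """Common cross-validation scaffolding; subclasses define the model family."""

    _expected_ndim = 2

    def __init__(self, n_folds=5, random_state=0, ensemble=False):
        self.n_folds = n_folds
        self.random_state = random_state
        self.ensemble = ensemble

    # -- hooks ------------------------------------------------------------
    def _run_training(self, X_train, y_train, X_val, y_val, rng):
        """Train one model; return (state, history, best_epoch, best_state).

        ``history`` is the per-epoch validation MAE curve (a one-element list
        for closed-form families); ``best_state`` realizes the epoch with the
        lowest validation MAE. With ``X_val=None`` train for
        ``self._refit_epochs_`` epochs and return an empty history.
        """
        raise NotImplementedError

    def _predict_state(self, state, X):
        raise NotImplementedError

    # -- validation -------------------------------------------------------
    def _validate_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != self._expected_ndim:
            raise InvalidInputError(
                f"{type(self).__name__} expects {self._expected_ndim}-D input, "
                f"got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("non-finite values in features")
        return X

    def _validate_fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise InvalidInputError(f"{X.shape[0]} feature rows for {len(y)} ages")
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("non-finite ages")
        if X.shape[0] < 2 * self.n_folds:
            raise InvalidInputError(
                f"need at least {2 * self.n_folds} subjects for {self.n_folds}-fold "
                f"cross-validation, got {X.shape[0]}"
            )
        return X, y

    def _folds(self, X, y, groups):
        if groups is not None:
            splitter = GroupKFold(n_splits=self.n_folds)
            return list(splitter.split(X, y, groups))
        splitter = KFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        return list(splitter.split(X, y))

    # -- protocol ----------------------------------------------------------
    def fit(self, X, y, groups=None):
        """Cross-validate, select the best epoch, refit on all data."""
        X, y = self._validate_fit(X, y)
        folds = self._folds(X, y, groups)

        fold_summaries = []
        fold_states = []
        oof_pred = np.full(len(y), np.nan)
        for k, (train_idx, val_idx) in enumerate(folds):
            rng = np.random.default_rng((self.random_state, k))
            _, history, best_epoch, best_state = self._run_training(
                X[train_idx], y[train_idx], X[val_idx], y[val_idx], rng
            )
            val_pred = self._predict_state(best_state, X[val_idx])
            oof_pred[val_idx] = val_pred
            resid = val_pred - y[val_idx]
            with np.errstate(invalid="ignore"):
                val_r = (
                    float(np.corrcoef(val_pred, y[val_idx])[0, 1])
                    if np.std(val_pred) > 0
                    else float("nan")
                )
            fold_summaries.append(
                {
                    "fold": k,
                    "train_index": train_idx.copy(),
                    "val_index": val_idx.copy(),
                    "best_epoch": best_epoch,
                    "val_mae": float(np.mean(np.abs(resid))),
                    "val_r": val_r,
                    "history": list(history),
                }
            )
            fold_states.append(best_state)

        self.cv_results_ = fold_summaries
        self.best_epoch_ = int(np.median([f["best_epoch"] for f in fold_summaries]))
        self.validation_mae_ = float(np.mean(np.abs(oof_pred - y)))
        self.validation_r_ = float(np.corrcoef(oof_pred, y)[0, 1])
        self.oof_predictions_ = oof_pred

        if self.ensemble:
            self._states_ = fold_states
            self.state_ = None
        else:
            self._refit_epochs_ = self.best_epoch_
            rng = np.random.default_rng((self.random_state, self.n_folds))
            state, _, _, _ = self._run_training(X, y, None, None, rng)
            self.state_ = state
            self._states_ = None
        self.n_features_in_shape_ = X.shape[1:]
        return self

    def predict(self, X):
        check_is_fitted(self, "cv_results_")
        X = self._validate_X(X)
        if X.shape[1:] != self.n_features_in_shape_:
            raise InvalidInputError(
                f"feature shape mismatch: expected {self.n_features_in_shape_}, "
                f"got {X.shape[1:]}"
            )
        if self._states_ is not None:
            preds = np.mean(
                [self._predict_state(s, X) for s in self._states_], axis=0
            )
        else:
            preds = self._predict_state(self.state_, X)
        if not np.all(np.isfinite(preds)):
            raise DivergenceError("model produced non-finite predictions")
        return preds
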