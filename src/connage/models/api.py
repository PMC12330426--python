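"""Functional surface over the estimator classes.

``train_predictor`` / ``predict_age`` / ``evaluate_predictions`` /
``build_subnetwork_models`` wrap the sklearn-style regressors with the
declarative :class:`ModelSpec` / :class:`TrainingConfig` configuration used
by the CLI and pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..atlas import ComponentAtlas
from ..connectivity import subnetwork_indices_in_vector
from ..errors import InvalidInputError
from .bilstm import BiLSTMBrainAge
from .gcn import GraphConvBrainAge
from .ridge import RidgeBrainAge

logger = logging.getLogger(__name__)

FAMILIES = ("graph_conv", "bilstm", "ridge")


@dataclass(frozen=True)
class ModelSpec:
    """Which model family to train and its architecture."""

    family: str = "ridge"
    hidden_units: int = 128
    recurrent_layers: int = 3
    dropout: float = 0.1
    graph_layer_sizes: tuple[int, ...] = (64, 32)
    ridge_penalty: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidInputError(
                f"unknown model family {self.family!r}; choose from {FAMILIES}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidInputError("dropout must be in [0, 1)")
        if self.recurrent_layers < 1 or any(s < 1 for s in self.graph_layer_sizes):
            raise InvalidInputError("layer counts/sizes must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol: Adam on mean absolute error, K-fold CV."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    n_folds: int = 5
    seed: int = 0
    ensemble: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise InvalidInputError("n_folds must be >= 2")
        if self.epochs < 1:
            raise InvalidInputError("epochs must be >= 1")


def make_estimator(spec: ModelSpec, train_cfg: TrainingConfig):
    """Instantiate the estimator class a spec describes."""
    common = dict(
        n_folds=train_cfg.n_folds,
        random_state=train_cfg.seed,
        ensemble=train_cfg.ensemble,
    )
    neural = dict(
        learning_rate=train_cfg.learning_rate,
        batch_size=train_cfg.batch_size,
        epochs=train_cfg.epochs,
        **common,
    )
    if spec.family == "ridge":
        return RidgeBrainAge(alpha=spec.ridge_penalty, **common)
    if spec.family == "graph_conv":
        return GraphConvBrainAge(graph_layer_sizes=spec.graph_layer_sizes, **neural)
    return BiLSTMBrainAge(
        hidden_units=spec.hidden_units,
        recurrent_layers=spec.recurrent_layers,
        dropout=spec.dropout,
        **neural,
    )


def train_predictor(features, ages, spec: ModelSpec, train_cfg: TrainingConfig,
                    groups=None):
    """Cross-validate and fit one brain-age model; returns the fitted estimator."""
    est = make_estimator(spec, train_cfg)
    return est.fit(np.asarray(features, dtype=float), np.asarray(ages, dtype=float),
                   groups=groups)


def predict_age(model, features) -> np.ndarray:
    """Predicted brain age (years) per subject, batch order preserved."""
    return model.predict(np.asarray(features, dtype=float))


def evaluate_predictions(predicted, chronological) -> tuple[float, float]:
    """Pearson r and MAE between predicted and chronological age."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    chronological = np.asarray(chronological, dtype=float).ravel()
    if predicted.shape != chronological.shape or predicted.size < 3:
        raise InvalidInputError("need matched vectors of length >= 3")
    mae = float(np.mean(np.abs(predicted - chronological)))
    if predicted.std() == 0.0 or chronological.std() == 0.0:
        raise InvalidInputError(
            f"correlation undefined for constant input (MAE = {mae:.4f})"
        )
    r = float(np.corrcoef(predicted, chronological)[0, 1])
    return r, mae


def build_subnetwork_models(features, ages, atlas: ComponentAtlas,
                            spec: ModelSpec, train_cfg: TrainingConfig,
                            groups=None) -> dict:
    """One brain-age model per functional network, on within-network edges only.

    ``features`` carries edge features on its last axis in full-vector order
    ((n, d) for static, (n, T, d) for dynamic), except for the graph family,
    which takes (n, C, C) matrices; each network's model sees only its own
    within-network component pairs.
    """
    features = np.asarray(features, dtype=float)
    models = {}
    for network in atlas.networks:
        idx = atlas.network_indices(network)
        if len(idx) < 2:
            logger.warning("skipping network %s: fewer than 2 components", network)
            continue
        if spec.family == "graph_conv":
            sub = features[np.ix_(np.arange(len(features)), idx, idx)]
        else:
            sub = features[..., subnetwork_indices_in_vector(atlas, network)]
        models[network] = train_predictor(sub, ages, spec, train_cfg, groups=groups)
    return models
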