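"""End-to-end pipeline: simulate -> prep -> connectivity -> train -> BAG -> GLM.

Mirrors the study design: brain-age models are fit on the healthy (control)
subjects with chronological age as the label, then applied to every subject;
the resulting brain-age gaps are tested against the cognitive scores in the
covariate-adjusted GLM suite. A run manifest (resolved config, package
version, per-output SHA-256 digests) makes every run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import ComponentAtlas, load_default_atlas, uniform_atlas
from .bag import GLMDesign, compute_bag, run_association_suite
from .connectivity import WindowSpec, dynamic_fnc, static_fnc
from .errors import InvalidInputError
from .features import (
    dfnc_sequences,
    sfnc_features,
    sfnc_matrices,
    top_variance_indices,
)
from .io import write_cohort, write_predictions
from .models import ModelSpec, TrainingConfig, make_estimator
from .prep import PrepConfig, prepare_timecourses
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducibility artifact per run: every stage's parameters."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    design: GLMDesign = field(default_factory=GLMDesign)
    modalities: tuple[str, ...] = ("sfnc", "dfnc")
    subnetworks: bool = False
    max_sequence_features: int | None = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig.from_dict(raw["cohort"])
        for key, klass in (
            ("prep", PrepConfig), ("window", WindowSpec), ("model", ModelSpec),
            ("training", TrainingConfig), ("design", GLMDesign),
        ):
            if key in raw:
                block = dict(raw[key])
                for name, value in block.items():
                    if isinstance(value, list):
                        block[name] = tuple(value)
                kwargs[key] = klass(**block)
        for key in ("modalities", "subnetworks", "max_sequence_features", "seed"):
            if key in raw:
                value = raw[key]
                kwargs[key] = tuple(value) if key == "modalities" else value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["modalities"] = list(self.modalities)
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _atlas_for(n_components: int) -> ComponentAtlas:
    if n_components == 53:
        return load_default_atlas()
    return uniform_atlas(n_components)


def _dfnc_static_summary(sequences: np.ndarray) -> np.ndarray:
    """Mean and SD over windows per edge: a flat dynamic summary for linear models."""
    return np.concatenate(
        [sequences.mean(axis=1), sequences.std(axis=1)], axis=1
    )


def _model_inputs(cfg: PipelineConfig, modality: str, fncs, dfncs):
    """Feature array for (family, modality), plus the reduction indices used."""
    family = cfg.model.family
    if modality == "sfnc":
        if family == "graph_conv":
            return sfnc_matrices(fncs)
        if family == "bilstm":
            raise InvalidInputError("bilstm requires the dfnc modality")
        return sfnc_features(fncs)
    if family == "graph_conv":
        raise InvalidInputError("graph_conv requires the sfnc modality")
    seqs = dfnc_sequences(dfncs)
    if cfg.max_sequence_features is not None:
        keep = top_variance_indices(seqs, cfg.max_sequence_features)
        seqs = seqs[..., keep]
    if family == "ridge":
        return _dfnc_static_summary(seqs)
    return seqs


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and return the run manifest (also written)."""
    started = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    logger.info("simulating cohort: n=%d, C=%d", cohort_cfg.n_subjects,
                cohort_cfg.n_components)
    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, out_dir / "cohort")
    atlas = _atlas_for(cohort_cfg.n_components)

    logger.info("preparing %d scans", len(cohort.timecourses))
    prepared = [prepare_timecourses(ts, config.prep) for ts in cohort.timecourses]

    logger.info("computing connectivity (window=%s)", config.window)
    fncs = [static_fnc(ts) for ts in prepared]
    dfncs = (
        [dynamic_fnc(ts, config.window) for ts in prepared]
        if "dfnc" in config.modalities
        else []
    )

    phen = cohort.phenotypes
    ages = phen["age"].to_numpy(dtype=float)
    controls = phen["diagnosis"].to_numpy() == 0
    if controls.sum() < 2 * config.training.n_folds:
        raise InvalidInputError(
            f"only {int(controls.sum())} control subjects; too few to train"
        )

    bag_tables = []
    predictions_paths = {}
    for modality in config.modalities:
        X = _model_inputs(config, modality, fncs, dfncs)
        est = make_estimator(config.model, config.training)
        est.fit(X[controls], ages[controls])
        logger.info("%s model: validation r=%.3f, MAE=%.2f y", modality,
                    est.validation_r_, est.validation_mae_)
        predicted = est.predict(X)
        pred_table = pd.DataFrame(
            {"subject_id": phen["subject_id"], "predicted_age": predicted}
        )
        path = out_dir / f"predictions_{modality}.csv"
        write_predictions(pred_table, path)
        predictions_paths[modality] = path
        bag_tables.append(compute_bag(pred_table, phen, "wide", modality))

        if config.subnetworks:
            from .connectivity import subnetwork_indices_in_vector

            full_edges = (
                sfnc_features(fncs) if modality == "sfnc" else dfnc_sequences(dfncs)
            )
            matrices = sfnc_matrices(fncs) if config.model.family == "graph_conv" else None
            for network in atlas.networks:
                idx = atlas.network_indices(network)
                if len(idx) < 2:
                    logger.warning("skipping network %s: <2 components", network)
                    continue
                if matrices is not None:
                    Xn = matrices[np.ix_(np.arange(len(matrices)), idx, idx)]
                else:
                    Xn = full_edges[..., subnetwork_indices_in_vector(atlas, network)]
                    if modality == "dfnc" and config.model.family == "ridge":
                        Xn = _dfnc_static_summary(Xn)
                sub_est = make_estimator(config.model, config.training)
                sub_est.fit(Xn[controls], ages[controls])
                sub_pred = pd.DataFrame(
                    {"subject_id": phen["subject_id"],
                     "predicted_age": sub_est.predict(Xn)}
                )
                bag_tables.append(compute_bag(sub_pred, phen, network, modality))

    associations = run_association_suite(bag_tables, phen, design=config.design)
    assoc_path = out_dir / "associations.csv"
    associations.to_csv(assoc_path, index=False)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "outputs": {
            "associations": _digest(assoc_path),
            **{f"predictions_{m}": _digest(p) for m, p in predictions_paths.items()},
        },
        "n_subjects": int(len(phen)),
        "elapsed_seconds": round(time.time() - started, 2),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
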