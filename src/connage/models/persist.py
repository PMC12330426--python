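"""Model bundle persistence.

A bundle is a directory holding the pickled estimator (joblib, the
scikit-learn ecosystem's standard form) next to a human-readable JSON
summary of the architecture and cross-validation results.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib


def _jsonable(value):
    import numpy as np

    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, tuple):
        return list(value)
    return value


def save_model(estimator, out_dir) -> Path:
    """Write a fitted estimator bundle; returns the bundle directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    joblib.dump(estimator, out_dir / "model.joblib")
    summary = {
        "estimator": type(estimator).__name__,
        "params": {k: _jsonable(v) for k, v in estimator.get_params().items()},
        "validation_r": _jsonable(getattr(estimator, "validation_r_", None)),
        "validation_mae": _jsonable(getattr(estimator, "validation_mae_", None)),
        "best_epoch": _jsonable(getattr(estimator, "best_epoch_", None)),
        "folds": [
            {
                "fold": f["fold"],
                "best_epoch": _jsonable(f["best_epoch"]),
                "val_mae": _jsonable(f["val_mae"]),
                "val_r": _jsonable(f["val_r"]),
                "history": [_jsonable(h) for h in f["history"]],
            }
            for f in getattr(estimator, "cv_results_", [])
        ],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return out_dir


def load_model(bundle_dir):
    """Load a fitted estimator from a bundle directory."""
    bundle_dir = Path(bundle_dir)
    return joblib.load(bundle_dir / "model.joblib")
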