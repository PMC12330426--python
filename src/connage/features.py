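"""Feature assembly: connectivity objects -> model-ready arrays."""

from __future__ import annotations

import numpy as np

from .connectivity import DynamicFNC, StaticFNC, vectorize_fnc
from .errors import InvalidInputError


def sfnc_features(fncs: list) -> np.ndarray:
    """Stack static FNCs into an (n_subjects, C(C-1)/2) feature matrix."""
    rows = []
    for f in fncs:
        matrix = f.matrix if isinstance(f, StaticFNC) else np.asarray(f)
        rows.append(vectorize_fnc(matrix))
    return np.stack(rows)


def sfnc_matrices(fncs: list) -> np.ndarray:
    """Stack static FNCs into an (n_subjects, C, C) array (graph-model input)."""
    return np.stack(
        [f.matrix if isinstance(f, StaticFNC) else np.asarray(f) for f in fncs]
    )


def dfnc_sequences(dfncs: list) -> np.ndarray:
    """Stack dynamic FNCs into an (n_subjects, T, C(C-1)/2) sequence array.

    Scans with more windows than the shortest are truncated to the common T
    so the batch is rectangular.
    """
    if not dfncs:
        raise InvalidInputError("empty dynamic FNC list")
    arrays = [d.array if isinstance(d, DynamicFNC) else np.asarray(d) for d in dfncs]
    t_common = min(a.shape[2] for a in arrays)
    iu, ju = np.triu_indices(arrays[0].shape[0], k=1)
    return np.stack([a[iu, ju, :t_common].T for a in arrays])


def top_variance_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` highest-variance features (last axis).

    Unsupervised reduction used to keep biLSTM sequences small at reduced
    scale; variance is pooled over subjects (and windows, for sequences).
    """
    X = np.asarray(X)
    flat = X.reshape(-1, X.shape[-1])
    k = min(k, flat.shape[1])
    var = flat.var(axis=0)
    return np.sort(np.argsort(var)[::-1][:k])
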