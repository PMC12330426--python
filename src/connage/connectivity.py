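"""Static and dynamic functional network connectivity (sFNC / dFNC).

Static FNC is the Pearson correlation between every pair of component time
courses over the full scan, giving a C x C matrix whose strict upper triangle
provides C(C-1)/2 features (1378 for the 53-component template).

Dynamic FNC applies the same correlation within a tapered sliding window: a
rectangular window of ``width_tr`` frames convolved with a truncated Gaussian
kernel (sigma in TR units), slid across the scan with a fixed stride. Each
fully supported window placement yields one correlation matrix, and the
placements stack into a C x C x T array. Within a window the taper values act
as observation weights in the correlation moments, which makes the
uniform-taper case reduce exactly to the static formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .atlas import ComponentAtlas
from .errors import InvalidInputError
from .timecourse import TimecourseMatrix

__all__ = [
    "WindowSpec",
    "StaticFNC",
    "DynamicFNC",
    "pearson_correlation",
    "weighted_pearson",
    "static_fnc",
    "dynamic_fnc",
    "make_tapered_window",
    "vectorize_fnc",
    "devectorize_fnc",
    "subnetwork_block",
    "subnetwork_indices_in_vector",
    "fisher_z",
]


@dataclass(frozen=True)
class WindowSpec:
    """Tapered sliding-window specification (all quantities in TR units)."""

    width_tr: int = 20
    gaussian_sigma: float = 3.0
    stride_tr: int = 1

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise InvalidInputError("window width must be >= 2 TR")
        if self.gaussian_sigma < 0:
            raise InvalidInputError("gaussian_sigma must be >= 0")
        if self.stride_tr < 1:
            raise InvalidInputError("stride must be >= 1 TR")

    @property
    def weights(self) -> np.ndarray:
        return make_tapered_window(self)

    @property
    def support(self) -> int:
        """Number of frames one window placement spans."""
        return self.width_tr + 2 * math.ceil(3 * self.gaussian_sigma)

    def duration_seconds(self, tr_seconds: float) -> float:
        """Nominal window duration (rectangle only), e.g. 20 TR x 0.735 s = 14.7 s."""
        return self.width_tr * tr_seconds


@dataclass(frozen=True)
class StaticFNC:
    matrix: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        _validate_correlation_matrix(self.matrix)


@dataclass(frozen=True)
class DynamicFNC:
    """C x C x T array of windowed correlations plus its window specification."""

    array: np.ndarray
    window: WindowSpec
    subject_id: str = "subject"

    @property
    def n_windows(self) -> int:
        return self.array.shape[2]


def _validate_correlation_matrix(m: np.ndarray, tol: float = 1e-12) -> None:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError(f"correlation matrix must be square, got {m.shape}")
    if np.abs(m - m.T).max() > tol:
        raise InvalidInputError("correlation matrix not symmetric")
    if np.abs(np.diag(m) - 1.0).max() > 1e-10:
        raise InvalidInputError("correlation matrix diagonal not unit")
    if np.abs(m).max() > 1.0 + 1e-10:
        raise InvalidInputError("correlation entries outside [-1, 1]")


# ---------------------------------------------------------------------------
# correlation primitives


def pearson_correlation(x1: np.ndarray, x2: np.ndarray) -> float:
    """Pearson correlation R = sum((x1-m1)(x2-m2)) / sqrt(sum((x1-m1)^2) sum((x2-m2)^2))."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise InvalidInputError(f"length mismatch: {x1.shape} vs {x2.shape}")
    if x1.size < 3:
        raise InvalidInputError("need at least 3 samples for a correlation")
    d1 = x1 - x1.mean()
    d2 = x2 - x2.mean()
    v1 = float(d1 @ d1)
    v2 = float(d2 @ d2)
    if v1 == 0.0 or v2 == 0.0:
        which = "first" if v1 == 0.0 else "second"
        raise InvalidInputError(f"zero variance in {which} input signal")
    return float(np.clip(d1 @ d2 / math.sqrt(v1 * v2), -1.0, 1.0))


def weighted_pearson(x1: np.ndarray, x2: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Pearson correlation with taper values as observation weights.

    Means, variances and the covariance are all taken under the weight
    measure; with uniform weights this is exactly the unweighted formula.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if not (x1.shape == x2.shape == w.shape):
        raise InvalidInputError("signals and weights must have equal length")
    if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
        raise InvalidInputError("weights must be non-negative and sum to 1")
    d1 = x1 - w @ x1
    d2 = x2 - w @ x2
    v1 = float(w @ (d1 * d1))
    v2 = float(w @ (d2 * d2))
    if v1 <= 0.0 or v2 <= 0.0:
        raise InvalidInputError("zero weighted variance")
    return float(np.clip(w @ (d1 * d2) / math.sqrt(v1 * v2), -1.0, 1.0))


def _weighted_corr_matrix(frames: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted correlation matrix of ``frames`` (n x C) under weights ``w`` (sum 1)."""
    mean = w @ frames
    dev = frames - mean
    cov = dev.T @ (dev * w[:, None])
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0)
        raise InvalidInputError(f"zero (weighted) variance in component indices {bad.tolist()}")
    corr = cov / np.outer(sd, sd)
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def static_fnc(ts: TimecourseMatrix) -> StaticFNC:
    """Full-scan Pearson correlation between every component pair."""
    variances = ts.data.var(axis=0)
    if np.any(variances == 0):
        bad = [ts.component_ids[i] for i in np.flatnonzero(variances == 0)]
        raise InvalidInputError(f"zero-variance components: {bad}")
    n = ts.frame_count
    corr = _weighted_corr_matrix(ts.data, np.full(n, 1.0 / n))
    return StaticFNC(matrix=corr, subject_id=ts.subject_id)


# ---------------------------------------------------------------------------
# tapered windows


def make_tapered_window(spec: WindowSpec) -> np.ndarray:
    """Rectangle convolved with a truncated Gaussian, normalized to sum 1.

    The Gaussian kernel is truncated at +/-3 sigma (length 2*ceil(3 sigma)+1)
    and normalized to unit area before the full-mode convolution, so the
    sigma -> 0 limit recovers the uniform rectangular window exactly.
    """
    rect = np.ones(spec.width_tr)
    half = math.ceil(3 * spec.gaussian_sigma)
    if half == 0 or spec.gaussian_sigma < 1e-6:
        kernel = np.ones(1)
    else:
        x = np.arange(-half, half + 1, dtype=float)
        kernel = np.exp(-0.5 * (x / spec.gaussian_sigma) ** 2)
    kernel = kernel / kernel.sum()
    taper = np.convolve(rect, kernel, mode="full")
    return taper / taper.sum()


def dynamic_fnc(ts: TimecourseMatrix, spec: WindowSpec = WindowSpec()) -> DynamicFNC:
    """Windowed correlations stacked into a C x C x T array.

    Only fully supported placements are used: window t covers frames
    ``[t*stride, t*stride + support)`` and T = floor((frames - support)/stride) + 1.
    """
    w = make_tapered_window(spec)
    support = len(w)
    if ts.frame_count < support:
        raise InvalidInputError(
            f"scan of {ts.frame_count} frames shorter than window support {support}"
        )
    n_windows = (ts.frame_count - support) // spec.stride_tr + 1
    c = ts.n_components
    out = np.empty((c, c, n_windows))
    for t in range(n_windows):
        start = t * spec.stride_tr
        out[:, :, t] = _weighted_corr_matrix(ts.data[start : start + support], w)
    return DynamicFNC(array=out, window=spec, subject_id=ts.subject_id)


# ---------------------------------------------------------------------------
# feature vectorization


def vectorize_fnc(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major order; length C(C-1)/2."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {matrix.shape}")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu, ju].copy()


def devectorize_fnc(vector: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_fnc` (symmetric, fixed diagonal)."""
    vector = np.asarray(vector).ravel()
    c = int(round((1 + math.sqrt(1 + 8 * vector.size)) / 2))
    if c * (c - 1) // 2 != vector.size:
        raise InvalidInputError(f"vector length {vector.size} is not C(C-1)/2 for any C")
    out = np.full((c, c), 0.0)
    iu, ju = np.triu_indices(c, k=1)
    out[iu, ju] = vector
    out += out.T
    np.fill_diagonal(out, diagonal)
    return out


def fisher_z(r: np.ndarray, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher z-transform of correlations (optional feature transform)."""
    return np.arctanh(np.clip(np.asarray(r, dtype=float), -clip, clip))


# ---------------------------------------------------------------------------
# sub-network extraction


def subnetwork_block(
    fnc: np.ndarray, atlas: ComponentAtlas, network: str
) -> np.ndarray:
    """Restrict a C x C matrix or C x C x T array to one network's components."""
    idx = atlas.network_indices(network)
    if len(idx) < 2:
        raise InvalidInputError(
            f"network {network!r} has {len(idx)} component(s); need >= 2"
        )
    fnc = np.asarray(fnc)
    if fnc.ndim == 2:
        return fnc[np.ix_(idx, idx)]
    if fnc.ndim == 3:
        return fnc[np.ix_(idx, idx, np.arange(fnc.shape[2]))]
    raise InvalidInputError(f"expected 2-D or 3-D connectivity, got ndim {fnc.ndim}")


def subnetwork_indices_in_vector(atlas: ComponentAtlas, network: str) -> np.ndarray:
    """Positions of one network's within-network edges inside the full feature vector.

    Restricting the matrix then vectorizing equals vectorizing then taking
    these positions, because both follow row-major upper-triangle order.
    """
    idx = set(atlas.network_indices(network).tolist())
    iu, ju = np.triu_indices(atlas.n_components, k=1)
    return np.flatnonzero([(i in idx) and (j in idx) for i, j in zip(iu, ju)])
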