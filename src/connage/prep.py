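"""Post-ICA time-course denoising and duration harmonization.

The preparation chain applied to every scan, in this fixed order:

1. polynomial de-trending (linear, quadratic and cubic by default);
2. optional multiple regression of nuisance regressors (e.g. realignment
   parameters and their temporal derivatives);
3. outlier removal by robust clipping at a scaled-MAD threshold;
4. zero-phase Butterworth low-pass filtering below 0.15 Hz.

Scans from protocols with different repetition times are harmonized by
truncating every scan to the duration of the shortest one; no resampling
across TRs is performed, because connectivity is computed in native sampling
and window widths are specified in TR units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as sps

from .errors import InvalidInputError
from .timecourse import TimecourseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PrepConfig",
    "detrend_polynomial",
    "regress_nuisance",
    "remove_outliers",
    "lowpass_filter",
    "truncate_to_common_duration",
    "prepare_timecourses",
    "temporal_derivatives",
]

MAD_SCALE = 1.4826  # scaled MAD is a consistent sigma estimator for Gaussians


@dataclass(frozen=True)
class PrepConfig:
    """Parameters of the denoising chain."""

    detrend_orders: tuple[int, ...] = (1, 2, 3)
    outlier_mad_threshold: float = 3.5
    lowpass_hz: float = 0.15
    filter_order: int = 5
    use_nuisance: bool = False

    def __post_init__(self) -> None:
        if self.outlier_mad_threshold <= 0:
            raise InvalidInputError("outlier_mad_threshold must be positive")
        if self.lowpass_hz <= 0:
            raise InvalidInputError("lowpass_hz must be positive")
        if self.filter_order < 1:
            raise InvalidInputError("filter_order must be >= 1")


def detrend_polynomial(
    ts: TimecourseMatrix, orders: tuple[int, ...] = (1, 2, 3)
) -> TimecourseMatrix:
    """Remove polynomial trends per component by least squares.

    The basis is the constant plus the requested powers of normalized time
    (Vandermonde over t in [-1, 1]); the projection of each component onto
    that basis is subtracted, so outputs are exactly mean-free.
    """
    orders = tuple(sorted(set(int(o) for o in orders)))
    if any(o < 1 for o in orders):
        raise InvalidInputError("detrend orders must be >= 1")
    n = ts.frame_count
    if orders and max(orders) >= n - 1:
        raise InvalidInputError(
            f"detrend order {max(orders)} needs more than {n} frames"
        )
    t = np.linspace(-1.0, 1.0, n)
    basis = npoly.polyvander(t, max(orders) if orders else 0)
    keep = [0] + [o for o in orders]
    basis = basis[:, keep]
    coef, *_ = np.linalg.lstsq(basis, ts.data, rcond=None)
    return ts.with_data(ts.data - basis @ coef)


def temporal_derivatives(regressors: np.ndarray) -> np.ndarray:
    """Backward-difference temporal derivatives, first row zero."""
    regressors = np.asarray(regressors, dtype=float)
    deriv = np.zeros_like(regressors)
    deriv[1:] = np.diff(regressors, axis=0)
    return deriv


def regress_nuisance(
    ts: TimecourseMatrix,
    regressors: np.ndarray,
    add_derivatives: bool = False,
) -> TimecourseMatrix:
    """Residualize each component on an intercept plus nuisance regressors.

    With ``add_derivatives`` the backward-difference temporal derivatives of
    the regressors are appended, mirroring the standard treatment of
    realignment parameters.
    """
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != ts.frame_count:
        raise InvalidInputError(
            f"regressors have {regressors.shape[0]} rows for {ts.frame_count} frames"
        )
    if add_derivatives:
        regressors = np.hstack([regressors, temporal_derivatives(regressors)])
    design = np.hstack([np.ones((ts.frame_count, 1)), regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns so the caller can fix the design
        bad = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise InvalidInputError(
            f"nuisance design is rank-deficient; collinear regressor columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ coef)


def remove_outliers(
    ts: TimecourseMatrix, mad_threshold: float = 3.5
) -> TimecourseMatrix:
    """Clip per-component outliers at ``mad_threshold`` scaled MADs from the median.

    Values beyond ``median +/- threshold * 1.4826 * MAD`` are clipped to the
    nearest bound; everything else is untouched. Constant components
    (MAD = 0) are passed through with a warning.
    """
    if mad_threshold <= 0:
        raise InvalidInputError("mad_threshold must be positive")
    data = ts.data.copy()
    med = np.median(data, axis=0)
    mad = np.median(np.abs(data - med), axis=0)
    degenerate = mad == 0
    if degenerate.any():
        names = [ts.component_ids[i] for i in np.flatnonzero(degenerate)]
        logger.warning("constant components passed through unchanged: %s", names)
    bound = mad_threshold * MAD_SCALE * mad
    active = ~degenerate
    lo = med[active] - bound[active]
    hi = med[active] + bound[active]
    data[:, active] = np.clip(data[:, active], lo, hi)
    return ts.with_data(data)


def lowpass_filter(
    ts: TimecourseMatrix, cutoff_hz: float = 0.15, order: int = 5
) -> TimecourseMatrix:
    """Zero-phase Butterworth low-pass per component.

    Applied forward-backward (``filtfilt``) so no phase shift is introduced;
    edges are handled by odd-symmetric padding of length 3 x order.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if cutoff_hz >= nyquist:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz at or above Nyquist {nyquist:.4f} Hz "
            f"for TR {ts.tr_seconds} s"
        )
    b, a = sps.butter(order, cutoff_hz / nyquist, btype="low")
    filtered = sps.filtfilt(b, a, ts.data, axis=0, padtype="odd", padlen=3 * order)
    return ts.with_data(filtered)


def truncate_to_common_duration(
    scans: list,
) -> tuple[list, float]:
    """Truncate all scans to the duration of the shortest one.

    The common duration is ``min(frames * TR)`` over the scans; each scan
    keeps its first ``floor(common_duration / TR)`` frames in native sampling.
    Returns the truncated scans and the common duration in seconds.
    """
    if not scans:
        raise InvalidInputError("empty scan list")
    common = min(s.duration_seconds for s in scans)
    out = []
    for s in scans:
        keep = int(math.floor(common / s.tr_seconds + 1e-9))
        out.append(s if keep >= s.frame_count else s.with_data(s.data[:keep]))
    return out, common


def prepare_timecourses(
    ts: TimecourseMatrix,
    config: PrepConfig = PrepConfig(),
    nuisance: np.ndarray | None = None,
) -> TimecourseMatrix:
    """Run the full denoising chain on one scan (fixed order)."""
    out = detrend_polynomial(ts, config.detrend_orders)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance, add_derivatives=True)
    out = remove_outliers(out, config.outlier_mad_threshold)
    out = lowpass_filter(out, config.lowpass_hz, config.filter_order)
    if not np.all(np.isfinite(out.data)):
        raise InvalidInputError(f"non-finite values after preparation of {ts.subject_id}")
    return out
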