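"""Component time-course post-processing ahead of dFNC estimation.

Four cleaning stages, applied in order:

1. polynomial detrending (linear, quadratic and cubic trends removed);
2. nuisance regression against realignment parameters and their temporal
   derivatives;
3. despiking of outliers against a running median (robust z on 1.4826 x MAD);
4. zero-phase low-pass filtering (5th-order Butterworth, forward-backward)
   with a 0.15 Hz cutoff.

All stages preserve the (T x C) shape. Stages 1, 2 and 4 are linear
projections/filters; despiking replaces flagged samples by the local median.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .core import Timecourses, validate_timecourse_matrix

__all__ = [
    "detrend_polynomial",
    "regress_nuisance",
    "despike",
    "lowpass_filter",
    "TimecoursePostprocessor",
]


def _as_matrix(tc) -> np.ndarray:
    if isinstance(tc, Timecourses):
        return tc.data
    return validate_timecourse_matrix(tc)


def _rewrap(tc, data: np.ndarray):
    if isinstance(tc, Timecourses):
        return tc.with_data(data)
    return data


def detrend_polynomial(tc, order: int = 3):
    """Remove the least-squares polynomial trend (incl. intercept) per column.

    Parameters
    ----------
    tc : Timecourses or (T x C) array
    order : {1, 2, 3}
        Highest polynomial degree to remove.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    data = _as_matrix(tc)
    t = data.shape[0]
    if t <= order + 1:
        raise ValueError(f"need T > order + 1 (= {order + 1}), got T={t}")
    # normalized time axis for numerical stability of the Vandermonde basis
    x = np.linspace(-1.0, 1.0, t)
    basis = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(basis, data, rcond=None)
    return _rewrap(tc, data - basis @ coef)


def _with_derivatives(regressors: np.ndarray) -> np.ndarray:
    """Append backward first differences (leading row 0) to the regressors."""
    deriv = np.diff(regressors, axis=0, prepend=regressors[:1])
    deriv[0] = 0.0
    return np.hstack([regressors, deriv])


def regress_nuisance(tc, regressors: np.ndarray, include_derivatives: bool = True):
    """Regress nuisance signals (e.g., 6 realignment parameters) out of each column.

    The design matrix is [intercept, regressors, first differences of the
    regressors]; residuals are orthogonal to all of these. Raises on a
    rank-deficient design, naming the collinear columns.
    """
    data = _as_matrix(tc)
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    if regressors.shape[0] != data.shape[0]:
        raise ValueError(
            f"regressors have {regressors.shape[0]} rows, time courses have {data.shape[0]}"
        )
    design_cols = _with_derivatives(regressors) if include_derivatives else regressors
    design = np.hstack([np.ones((data.shape[0], 1)), design_cols])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = design[:, :1]
        for j in range(1, design.shape[1]):
            cand = np.hstack([kept, design[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(j - 1)  # 0-based index into the regressor block
            else:
                kept = cand
        raise ValueError(f"nuisance design is rank deficient; collinear regressor columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, data, rcond=None)
    return _rewrap(tc, data - design @ coef)


def _leave_center_out_running_median(data: np.ndarray, window: int) -> np.ndarray:
    """Per-column running median over +/- window neighbors, excluding the
    center sample. Excluding the center keeps the residuals nondegenerate —
    an inclusive median frequently equals the center sample exactly,
    collapsing the MAD to zero. Boundaries use antisymmetric (odd) extension,
    which preserves local linear trends so ramp endpoints are not flagged."""
    left = 2.0 * data[:1] - data[window:0:-1]
    right = 2.0 * data[-1:] - data[-2 : -window - 2 : -1]
    padded = np.concatenate([left, data, right], axis=0)
    views = np.lib.stride_tricks.sliding_window_view(padded, 2 * window + 1, axis=0)
    # views: (T, C, 2w+1); drop the center position
    keep = np.delete(np.arange(2 * window + 1), window)
    return np.median(views[:, :, keep], axis=2)


def despike(tc, z_threshold: float = 4.0, window: int = 5):
    """Replace outliers against a per-column running median.

    A sample is a spike when its deviation from the running median of its
    +/- ``window`` neighbors (center excluded) exceeds ``z_threshold`` robust
    standard deviations, where the robust SD is 1.4826 x the median absolute
    deviation of the residuals. When the MAD is zero (locally constant series)
    any nonzero deviation is treated as a spike. Spikes are replaced by the
    running median; everything else is returned bit-identical.
    """
    data = _as_matrix(tc)
    t = data.shape[0]
    if t <= 2 * window:
        raise ValueError(f"need T > 2*window (= {2 * window}), got T={t}")
    runmed = _leave_center_out_running_median(data, window)
    resid = data - runmed
    mad = np.median(np.abs(resid), axis=0)
    robust_sd = 1.4826 * mad
    out = data.copy()
    for j in range(data.shape[1]):
        if robust_sd[j] > 0:
            mask = np.abs(resid[:, j]) > z_threshold * robust_sd[j]
        else:
            mask = np.abs(resid[:, j]) > 0
        out[mask, j] = runmed[mask, j]
    return _rewrap(tc, out)


def lowpass_filter(tc, cutoff_hz: float = 0.15, tr_seconds: float | None = None, order: int = 5):
    """Zero-phase Butterworth low-pass filter, applied per column.

    Forward-backward filtering (``filtfilt``) doubles the effective order and
    cancels phase shifts, so window timing downstream is unaffected.
    """
    data = _as_matrix(tc)
    if tr_seconds is None:
        tr_seconds = tc.tr_seconds if isinstance(tc, Timecourses) else 2.2
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.4f} Hz)")
    b, a = butter(order, cutoff_hz / nyquist)
    return _rewrap(tc, filtfilt(b, a, data, axis=0))


class TimecoursePostprocessor(BaseEstimator, TransformerMixin):
    """Full post-processing chain: detrend -> nuisance -> despike -> low-pass.

    Parameters
    ----------
    detrend_order : int, default 3
        Polynomial detrending order (1-3); 0/None disables.
    nuisance : (T x R) array, optional
        Nuisance regressors (realignment parameters); derivatives are added.
        None skips the stage (simulated cohorts carry no motion).
    apply_despike : bool, default True
    z_threshold : float, default 4.0
    despike_window : int, default 5
        Running-median half-width.
    cutoff_hz : float or None, default 0.15
        Low-pass cutoff; None disables filtering.
    tr_seconds : float, default 2.2
        Used when transforming bare arrays; Timecourses carry their own TR.
    """

    def __init__(
        self,
        detrend_order: int = 3,
        nuisance: np.ndarray | None = None,
        apply_despike: bool = True,
        z_threshold: float = 4.0,
        despike_window: int = 5,
        cutoff_hz: float | None = 0.15,
        tr_seconds: float = 2.2,
    ):
        self.detrend_order = detrend_order
        self.nuisance = nuisance
        self.apply_despike = apply_despike
        self.z_threshold = z_threshold
        self.despike_window = despike_window
        self.cutoff_hz = cutoff_hz
        self.tr_seconds = tr_seconds

    def fit(self, X=None, y=None):
        self.n_stages_ = sum(
            [
                bool(self.detrend_order),
                self.nuisance is not None,
                bool(self.apply_despike),
                self.cutoff_hz is not None,
            ]
        )
        return self

    def transform(self, X):
        """Apply the configured stages in order; shape is preserved."""
        if not hasattr(self, "n_stages_"):
            self.fit()
        out = X
        if self.detrend_order:
            out = detrend_polynomial(out, order=self.detrend_order)
        if self.nuisance is not None:
            out = regress_nuisance(out, self.nuisance)
        if self.apply_despike:
            out = despike(out, z_threshold=self.z_threshold, window=self.despike_window)
        if self.cutoff_hz is not None:
            tr = out.tr_seconds if isinstance(out, Timecourses) else self.tr_seconds
            out = lowpass_filter(out, cutoff_hz=self.cutoff_hz, tr_seconds=tr)
        return out
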