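"""Static and dynamic (tapered sliding-window) functional network connectivity.

The dynamic connectome of a scan is estimated by sliding a tapered window
along the component time courses and computing, inside each window, the
weighted Pearson correlation between every pair of components. The taper is
a rectangle (the nominal window, ``window_trs`` samples) convolved with a
discrete Gaussian, which localizes the estimate in time while avoiding the
hard edges of a boxcar.

Window-count convention: with step 1, windows start at 0, 1, ... while
``start + window_trs <= T - 1``, giving ``T - window_trs`` windows. A scan of
159 retained volumes with a 20-TR window therefore yields 139 windows.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import DFNCTensor, Timecourses, validate_timecourse_matrix

__all__ = [
    "build_taper",
    "weighted_correlation",
    "weighted_correlation_matrix",
    "sliding_window_fnc",
    "static_fnc",
    "vectorize_fnc",
    "unvectorize_fnc",
    "n_pairs",
    "pair_index",
    "SlidingWindowConnectivity",
]


def build_taper(window_trs: int = 20, gaussian_sigma: float = 3.0) -> np.ndarray:
    """Tapered-window weights: a rectangle convolved with a Gaussian.

    The rectangle is ``window_trs`` ones; the Gaussian is a unit-area discrete
    kernel of standard deviation ``gaussian_sigma`` (in TR units) evaluated on
    an integer grid spanning +/- 4 sigma. The central ``window_trs`` samples of
    the full convolution are kept and rescaled to sum to ``window_trs``.

    Returns
    -------
    ndarray of shape (window_trs,)
        Strictly positive, symmetric weights peaking at the center.
    """
    if window_trs < 1:
        raise ValueError("window_trs must be >= 1")
    if gaussian_sigma <= 0:
        raise ValueError("gaussian_sigma must be positive")
    radius = max(1, int(np.ceil(4.0 * gaussian_sigma)))
    grid = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (grid / gaussian_sigma) ** 2)
    kernel /= kernel.sum()
    # central window_trs samples of the full convolution
    full = np.convolve(np.ones(window_trs), kernel, mode="full")
    weights = full[radius : radius + window_trs]
    weights = (weights + weights[::-1]) / 2.0  # exact symmetry despite roundoff
    weights *= window_trs / weights.sum()
    return weights


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation of two equal-length vectors.

    Means, variances and the covariance are all computed under the weights;
    with uniform weights this reduces exactly to the plain Pearson
    correlation. Returns NaN when either input has zero weighted variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y and w must have identical shapes")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    wn = w / w.sum()
    mx = wn @ x
    my = wn @ y
    dx = x - mx
    dy = y - my
    vx = wn @ (dx * dx)
    vy = wn @ (dy * dy)
    # scale-aware zero-variance guard (a constant vector leaves only roundoff)
    tol_x = (1e-12 * max(1.0, np.abs(x).max())) ** 2
    tol_y = (1e-12 * max(1.0, np.abs(y).max())) ** 2
    if vx <= tol_x or vy <= tol_y:
        return float("nan")
    r = (wn @ (dx * dy)) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def weighted_correlation_matrix(segment: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted Pearson correlation matrix of the columns of a (n x C) segment.

    Zero-variance columns produce NaN rows/columns (diagonal kept at 1).
    """
    segment = np.asarray(segment, dtype=float)
    w = np.asarray(w, dtype=float)
    wn = w / w.sum()
    mu = wn @ segment
    centered = segment - mu
    cov = centered.T @ (wn[:, None] * centered)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def sliding_window_fnc(
    tc: Timecourses,
    window_trs: int = 20,
    gaussian_sigma: float = 3.0,
    step: int = 1,
    taper: np.ndarray | None = None,
    kind: str = "correlation",
) -> DFNCTensor:
    """Tapered sliding-window dynamic FNC of one scan.

    Parameters
    ----------
    tc : Timecourses
    window_trs, gaussian_sigma : taper parameters (ignored when `taper` given).
    step : int, default 1
        Stride between window starts.
    kind : {"correlation", "covariance"}
        Windowed estimate; correlation is standard (entries in [-1, 1]).

    Returns
    -------
    DFNCTensor with ``(T - window_trs) // step`` slices at step 1 convention
    (starts run while ``start + window_trs <= T - 1``).
    """
    if kind not in ("correlation", "covariance"):
        raise ValueError(f"kind must be 'correlation' or 'covariance', got {kind!r}")
    data = tc.data
    t = data.shape[0]
    if taper is None:
        taper = build_taper(window_trs, gaussian_sigma)
    else:
        taper = np.asarray(taper, dtype=float)
        window_trs = taper.shape[0]
    if t <= window_trs:
        raise ValueError(f"scan length T={t} must exceed window_trs={window_trs}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(0, t - window_trs, step)
    wn = taper / taper.sum()
    slices = np.empty((starts.shape[0], data.shape[1], data.shape[1]))
    flagged = np.zeros(starts.shape[0], dtype=bool)
    for idx, s in enumerate(starts):
        seg = data[s : s + window_trs]
        if kind == "correlation":
            corr = weighted_correlation_matrix(seg, taper)
            if np.any(np.isnan(corr)):
                flagged[idx] = True
            slices[idx] = corr
        else:
            mu = wn @ seg
            centered = seg - mu
            slices[idx] = centered.T @ (wn[:, None] * centered)
    return DFNCTensor(
        scan_id=tc.scan_id,
        data=slices,
        window_starts=starts,
        window_trs=window_trs,
        flagged_windows=flagged,
    )


def static_fnc(tc: Timecourses) -> np.ndarray:
    """Full-length Pearson correlation matrix (static FNC) of one scan.

    Zero-variance components yield NaN in the affected off-diagonal entries.
    """
    data = validate_timecourse_matrix(tc.data)
    if data.shape[0] < 3:
        raise ValueError("static FNC needs at least 3 time points")
    sd = data.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(data.T)
    corr = np.clip(corr, -1.0, 1.0)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def n_pairs(c: int) -> int:
    """Number of unique component pairs: C(C-1)/2 (1378 for C = 53)."""
    return c * (c - 1) // 2


def pair_index(c: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair ordering: strict lower triangle, row-major.

    Pairs are (1,0), (2,0), (2,1), (3,0), ... as (row, col) index arrays.
    """
    return np.tril_indices(c, k=-1)


def vectorize_fnc(matrix: np.ndarray) -> np.ndarray:
    """Vectorize a symmetric C x C connectome into its C(C-1)/2 unique entries."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    finite = np.isfinite(matrix)
    if not np.allclose(
        np.where(finite & finite.T, matrix, 0.0),
        np.where(finite & finite.T, matrix.T, 0.0),
        atol=1e-10,
        equal_nan=True,
    ):
        raise ValueError("matrix is not symmetric")
    rows, cols = pair_index(matrix.shape[0])
    return matrix[rows, cols]


def unvectorize_fnc(values: np.ndarray, c: int, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric C x C matrix from its vectorized lower triangle."""
    values = np.asarray(values, dtype=float)
    expected = n_pairs(c)
    if values.shape != (expected,):
        raise ValueError(f"expected {expected} values (= C(C-1)/2 for C={c}), got {values.shape}")
    matrix = np.full((c, c), diagonal, dtype=float)
    rows, cols = pair_index(c)
    matrix[rows, cols] = values
    matrix[cols, rows] = values
    return matrix


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transformer mapping a scan's (T x C) time courses to (W x P) window vectors.

    Each output row is one window's vectorized tapered correlation matrix
    (P = C(C-1)/2 pairs, strict lower triangle in row-major order), ready for
    state clustering.

    Parameters
    ----------
    window_trs : int, default 20
        Window length in TRs.
    gaussian_sigma : float, default 3.0
        Taper Gaussian standard deviation in TR units.
    step : int, default 1
        Window stride.
    kind : {"correlation", "covariance"}, default "correlation"
    """

    def __init__(
        self,
        window_trs: int = 20,
        gaussian_sigma: float = 3.0,
        step: int = 1,
        kind: str = "correlation",
    ):
        self.window_trs = window_trs
        self.gaussian_sigma = gaussian_sigma
        self.step = step
        self.kind = kind

    def fit(self, X=None, y=None):
        self.taper_ = build_taper(self.window_trs, self.gaussian_sigma)
        return self

    def transform(self, X) -> np.ndarray:
        """X: (T x C) array or Timecourses; returns (W x P) window vectors."""
        if not hasattr(self, "taper_"):
            self.fit()
        tc = X if isinstance(X, Timecourses) else Timecourses("scan", np.asarray(X, dtype=float))
        tensor = sliding_window_fnc(tc, step=self.step, taper=self.taper_, kind=self.kind)
        rows, cols = pair_index(tensor.n_components)
        return tensor.data[:, rows, cols]

    def tensor(self, tc: Timecourses) -> DFNCTensor:
        """Full (W x C x C) dynamic connectome of one scan."""
        if not hasattr(self, "taper_"):
            self.fit()
        return sliding_window_fnc(tc, step=self.step, taper=self.taper_, kind=self.kind)
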