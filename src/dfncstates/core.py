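"""Shared containers for component time-course analysis.

The atomic input of the pipeline is one scan's matrix of component
(intrinsic connectivity network) activity: T time points by C components,
sampled every ``tr_seconds``. Everything downstream — windowed connectomes,
state labels, temporal features — is keyed by ``scan_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Timecourses", "DFNCTensor", "validate_timecourse_matrix"]


def validate_timecourse_matrix(data: np.ndarray) -> np.ndarray:
    """Coerce to a float 2-D array and check the basic contract (T>=2, C>=2, finite)."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"time courses must be 2-D (T x C), got shape {arr.shape}")
    t, c = arr.shape
    if t < 2 or c < 2:
        raise ValueError(f"need at least 2 time points and 2 components, got T={t}, C={c}")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        raise ValueError(f"non-finite values in time courses, first at (row, col)={tuple(bad[0])}")
    return arr


@dataclass
class Timecourses:
    """One scan's T x C component time-course matrix.

    Parameters
    ----------
    scan_id : str
        Identifier of the scan (unique within a cohort).
    data : ndarray of shape (T, C)
        Component activity; arbitrary units, no missing values.
    tr_seconds : float, default 2.2
        Repetition time (sampling interval) in seconds.
    component_names : list of str, optional
        Length-C labels; generated as ``IC001..`` when absent.
    """

    scan_id: str
    data: np.ndarray
    tr_seconds: float = 2.2
    component_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = validate_timecourse_matrix(self.data)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.component_names is None:
            self.component_names = [f"IC{i + 1:03d}" for i in range(self.n_components)]
        if len(self.component_names) != self.n_components:
            raise ValueError(
                f"component_names has {len(self.component_names)} entries, expected {self.n_components}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "Timecourses":
        """Return a copy of this scan carrying new data (same id, TR, names)."""
        return Timecourses(
            scan_id=self.scan_id,
            data=data,
            tr_seconds=self.tr_seconds,
            component_names=list(self.component_names),
        )


@dataclass
class DFNCTensor:
    """Per-scan stack of windowed C x C correlation matrices.

    ``data[w]`` is the tapered-window correlation matrix of window ``w``,
    which covers time points ``[window_starts[w], window_starts[w] + window_trs)``.
    """

    scan_id: str
    data: np.ndarray  # (W, C, C)
    window_starts: np.ndarray  # (W,)
    window_trs: int
    flagged_windows: np.ndarray = field(default=None)  # bool (W,): zero-variance windows

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError(f"dFNC tensor must be (W, C, C), got {self.data.shape}")
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if self.window_starts.shape[0] != self.data.shape[0]:
            raise ValueError("window_starts length must equal window count")
        if self.flagged_windows is None:
            self.flagged_windows = np.zeros(self.data.shape[0], dtype=bool)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]
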