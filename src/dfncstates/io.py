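"""Plain-text interchange: time-course files, cohort tables, ground truth.

Every artifact is delimited text or JSON: one CSV per scan (header row of
component names, T rows x C columns), a cohort metadata CSV, centroid and
feature tables, and a JSON sidecar holding ground truth (state sequences and
transition matrices) for simulated cohorts.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Timecourses

__all__ = [
    "load_timecourses",
    "write_timecourses",
    "write_cohort",
    "load_cohort_dir",
    "write_json_atomic",
]


def load_timecourses(path, tr_seconds: float = 2.2, scan_id: str | None = None) -> Timecourses:
    """Read one scan's T x C delimited-text matrix (header = component names).

    Malformed rows (short rows, non-numeric or missing entries) are reported
    with their 1-based line number in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-course file not found: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited text: {exc}") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 component columns, got {frame.shape[1]}")
    values = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        row, col = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at line {row + 2}, column "
            f"{frame.columns[col]!r}"
        )
    return Timecourses(
        scan_id=scan_id or path.stem,
        data=values,
        tr_seconds=tr_seconds,
        component_names=[str(c) for c in frame.columns],
    )


def write_timecourses(tc: Timecourses, path) -> Path:
    """Write one scan as delimited text with a component-name header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(tc.data, columns=tc.component_names)
    frame.to_csv(path, index=False, float_format="%.10g")
    return path


def write_json_atomic(obj, path) -> Path:
    """Serialize to JSON via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
    os.replace(tmp, path)
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def write_cohort(cohort, out_dir) -> Path:
    """Write a simulated cohort: per-scan CSVs, metadata table, truth sidecar."""
    out_dir = Path(out_dir)
    tc_dir = out_dir / "timecourses"
    tc_dir.mkdir(parents=True, exist_ok=True)
    for tc in cohort.scans:
        write_timecourses(tc, tc_dir / f"{tc.scan_id}.csv")
    cohort.metadata.to_csv(out_dir / "metadata.csv", index=False)
    truth = {
        "group_transitions": {g: m for g, m in cohort.group_transitions.items()},
        "state_covariances": [sc.matrix for sc in cohort.state_covariances],
        "subjects": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "true_state_sequence": s.true_state_sequence,
                "true_transition_matrix": s.true_transition_matrix,
            }
            for s in cohort.subjects
        ],
        "regimes": {k: v for k, v in cohort.regimes.items()},
    }
    write_json_atomic(truth, out_dir / "ground_truth.json")
    return out_dir


def load_cohort_dir(in_dir, tr_seconds: float = 2.2):
    """Load scans + metadata written by :func:`write_cohort` (truth optional).

    Returns (list of Timecourses in metadata order, metadata DataFrame).
    """
    in_dir = Path(in_dir)
    meta_path = in_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"cohort metadata not found: {meta_path}")
    metadata = pd.read_csv(meta_path)
    scans = []
    for scan_id in metadata["scan_id"]:
        scans.append(load_timecourses(in_dir / "timecourses" / f"{scan_id}.csv", tr_seconds, scan_id))
    return scans, metadata
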