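"""Temporal features of the state vector: transition probabilities and occupancy.

Each scan's window-wise state sequence is summarized by the maximum-likelihood
first-order Markov transition matrix ``a[i, j] = p(s(t+1) = i | s(t) = j)``
(column-stochastic; k^2 features, 9 for k = 3) and the occupancy rate — the
fraction of windows spent in each state (k features).

States are labeled 0..k-1 in arrays; feature columns use the conventional
1-based names (a11, a12, ..., ocr1, ...). The transition block is flattened
row-major over ``a``: a11, a12, ..., a1k, a21, ...
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TransitionMatrix",
    "estimate_transition_matrix",
    "occupancy_rate",
    "feature_table",
    "feature_names",
    "MarkovStateFeaturizer",
]


@dataclass
class TransitionMatrix:
    """Estimated transition probabilities with their underlying counts.

    ``a[i, j]`` estimates p(next = i | current = j); columns with at least one
    observed departure sum to 1. ``empty_columns[j]`` flags states never
    departed from, whose column was filled per the chosen policy.
    """

    a: np.ndarray
    counts: np.ndarray
    k: int
    empty_columns: np.ndarray

    def flatten(self) -> np.ndarray:
        """Row-major flattening: a11, a12, ..., a1k, a21, ..., akk."""
        return self.a.ravel(order="C")


def _validate_labels(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("state vector must be 1-D")
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in 0..{k - 1}, got range [{labels.min()}, {labels.max()}]")
    return labels.astype(int)


def estimate_transition_matrix(
    labels: np.ndarray, k: int, empty_column_policy: str = "uniform"
) -> TransitionMatrix:
    """Maximum-likelihood first-order Markov estimate from one state sequence.

    counts[i, j] = #{t : s(t) = j and s(t+1) = i}; each column is normalized by
    its departure count. Columns with zero departures are filled uniformly with
    1/k (policy ``"uniform"``, keeps feature tables rectangular) or with NaN
    (policy ``"missing"``); either way the column is flagged.
    """
    if empty_column_policy not in ("uniform", "missing"):
        raise ValueError(f"unknown empty_column_policy {empty_column_policy!r}")
    labels = _validate_labels(labels, k)
    if labels.size < 2:
        raise ValueError("need at least 2 windows to estimate transitions")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[1:], labels[:-1]), 1.0)
    departures = counts.sum(axis=0)
    empty = departures == 0
    a = np.zeros((k, k))
    nonzero = ~empty
    a[:, nonzero] = counts[:, nonzero] / departures[nonzero]
    if empty.any():
        a[:, empty] = 1.0 / k if empty_column_policy == "uniform" else np.nan
    return TransitionMatrix(a=a, counts=counts, k=k, empty_columns=empty)


def occupancy_rate(labels: np.ndarray, k: int) -> np.ndarray:
    """Fraction of windows spent in each state; entries sum to 1."""
    labels = _validate_labels(labels, k)
    if labels.size == 0:
        raise ValueError("empty state vector")
    return np.bincount(labels, minlength=k) / labels.size


def feature_names(k: int) -> list[str]:
    """Deterministic column order: a11..akk (row-major), then ocr1..ocrk."""
    names = [f"a{i + 1}{j + 1}" for i in range(k) for j in range(k)]
    names += [f"ocr{s + 1}" for s in range(k)]
    return names


def feature_table(
    state_vectors: dict, k: int, empty_column_policy: str = "uniform"
) -> pd.DataFrame:
    """Per-scan temporal feature table: k^2 transition + k occupancy columns.

    Parameters
    ----------
    state_vectors : mapping scan_id -> label sequence.
    k : state count.

    Returns
    -------
    DataFrame indexed by scan_id with columns ``feature_names(k)`` plus a
    boolean ``any_empty_transition_column`` flag.
    """
    rows = []
    index = []
    flags = []
    for scan_id, labels in state_vectors.items():
        tm = estimate_transition_matrix(labels, k, empty_column_policy=empty_column_policy)
        ocr = occupancy_rate(labels, k)
        rows.append(np.concatenate([tm.flatten(), ocr]))
        flags.append(bool(tm.empty_columns.any()))
        index.append(scan_id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="scan_id"), columns=feature_names(k))
    table["any_empty_transition_column"] = flags
    return table


class MarkovStateFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from per-scan state sequences to the temporal feature table.

    Parameters
    ----------
    k : int, default 3
        Number of states.
    empty_column_policy : {"uniform", "missing"}, default "uniform"
        Fill for transition columns of states never departed from.
    """

    def __init__(self, k: int = 3, empty_column_policy: str = "uniform"):
        self.k = k
        self.empty_column_policy = empty_column_policy

    def fit(self, X=None, y=None):
        self.feature_names_ = feature_names(self.k)
        return self

    def transform(self, X: dict) -> pd.DataFrame:
        """X: mapping scan_id -> label sequence (or list of sequences)."""
        if not hasattr(self, "feature_names_"):
            self.fit()
        if not isinstance(X, dict):
            X = {f"scan{i:04d}": labels for i, labels in enumerate(X)}
        return feature_table(X, self.k, empty_column_policy=self.empty_column_policy)
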