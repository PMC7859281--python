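"""Clustering windowed connectomes into recurring whole-brain states.

All windows of all scans are pooled (rows = windows, columns = vectorized
connectome pairs) and partitioned by k-means under the correlation distance
d(a, b) = 1 - corr(a, b). Row-standardizing each vector (zero mean, unit
norm) turns that distance into half the squared Euclidean distance,
``1 - corr(a, b) = ||a~ - b~||^2 / 2``, so standard Euclidean k-means on the
standardized rows is an exact implementation.

The state count k is selected by the elbow criterion on the ratio of mean
within-cluster distance to mean between-centroid distance, operationalized as
the point of maximal curvature (discrete second difference) of the curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "standardize_rows",
    "correlation_distance",
    "CorrelationKMeans",
    "cluster_windows",
    "ElbowResult",
    "elbow_select_k",
    "assign_state_vectors",
    "subject_state_fnc",
    "match_states",
]


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row and scale it to unit Euclidean norm.

    Constant rows (zero variance) cannot be assigned a correlation distance
    and raise a ValueError.
    """
    X = np.asarray(X, dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = int(np.argwhere(norms[:, 0] == 0)[0, 0])
        raise ValueError(f"row {bad} is constant; correlation distance undefined")
    return centered / norms


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation between two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(1.0 - np.corrcoef(a, b)[0, 1])


class CorrelationKMeans(BaseEstimator, ClusterMixin):
    """K-means over vectorized connectomes under correlation distance.

    Internally rows are standardized and clustered with Euclidean k-means
    (k-means++ seeding, best of ``n_replicates`` restarts by inertia; empty
    clusters are re-seeded by the underlying solver from the farthest points).

    Parameters
    ----------
    n_clusters : int, default 3
    n_replicates : int, default 20
        Independent restarts; the run with lowest inertia wins.
    max_iter : int, default 1000
        Iteration cap per run.
    random_state : int or None
        Seed controlling initialization; fixed seed gives deterministic output.

    Attributes
    ----------
    labels_ : (N,) int array of window-state labels in 0..k-1.
    centroids_ : (k, P) array; per-state mean of the raw member vectors
        (natural connectivity units, used for display and state matching).
    cluster_centers_std_ : (k, P) centroids in standardized space.
    inertia_ : sum over windows of the correlation distance to the assigned
        centroid (= Euclidean inertia / 2).
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_replicates: int = 20,
        max_iter: int = 1000,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_replicates = n_replicates
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError(f"expected (N x P) window vectors with P >= 2, got {X.shape}")
        if X.shape[0] <= self.n_clusters:
            raise ValueError(
                f"need more windows ({X.shape[0]}) than clusters ({self.n_clusters})"
            )
        Xs = standardize_rows(X)
        if np.unique(Xs, axis=0).shape[0] < self.n_clusters:
            raise ValueError("fewer distinct window vectors than clusters")
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_replicates,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        labels = km.fit_predict(Xs)
        self.labels_ = labels
        self.cluster_centers_std_ = km.cluster_centers_
        self.inertia_ = km.inertia_ / 2.0
        self.centroids_ = np.vstack(
            [X[labels == s].mean(axis=0) for s in range(self.n_clusters)]
        )
        self._km = km
        return self

    def predict(self, X) -> np.ndarray:
        Xs = standardize_rows(np.asarray(X, dtype=float))
        return self._km.predict(Xs)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def within_between_ratio(self, X) -> float:
        """Mean within-cluster distance over mean between-cluster distance.

        Both terms are correlation distances on standardized rows: within is
        the mean distance of each point to its centroid; between is the mean
        distance over all pairs of points in different clusters, computed in
        closed form from centroids and within-cluster scatter (for clusters
        i, j the mean squared point-pair distance is R_i/2 + R_j/2 +
        ||c_i - c_j||^2 with R the mean squared point-centroid distance).
        """
        Xs = standardize_rows(np.asarray(X, dtype=float))
        labels = self._km.predict(Xs)
        centers = self.cluster_centers_std_
        k = self.n_clusters
        sq_to_center = np.sum((Xs - centers[labels]) ** 2, axis=1)
        within = 0.5 * np.mean(sq_to_center)
        if k < 2:
            return float("inf")
        counts = np.bincount(labels, minlength=k).astype(float)
        scatter = np.zeros(k)
        for s in range(k):
            if counts[s]:
                scatter[s] = sq_to_center[labels == s].mean()
        num = den = 0.0
        for i, j in itertools.combinations(range(k), 2):
            w = counts[i] * counts[j]
            mean_sq = 0.5 * scatter[i] + 0.5 * scatter[j] + np.sum((centers[i] - centers[j]) ** 2)
            num += w * 0.5 * mean_sq
            den += w
        return float(within / (num / den))


def cluster_windows(
    window_vectors: np.ndarray,
    k: int,
    n_replicates: int = 20,
    max_iter: int = 1000,
    seed: int | None = None,
) -> CorrelationKMeans:
    """Fit correlation-distance k-means on pooled window vectors (thin wrapper)."""
    return CorrelationKMeans(
        n_clusters=k, n_replicates=n_replicates, max_iter=max_iter, random_state=seed
    ).fit(window_vectors)


@dataclass
class ElbowResult:
    selected_k: int
    ks: np.ndarray
    ratio: np.ndarray  # within/between distance ratio per k
    curvature: np.ndarray  # discrete second difference at interior ks
    low_confidence: bool
    models: dict = field(default_factory=dict, repr=False)


def elbow_select_k(
    window_vectors: np.ndarray,
    k_range=range(2, 11),
    n_replicates: int = 20,
    max_iter: int = 1000,
    seed: int | None = None,
    keep_models: bool = False,
) -> ElbowResult:
    """Select the state count by the elbow of the within/between distance ratio.

    For each candidate k the ratio R(k) = (mean within-cluster correlation
    distance) / (mean pairwise between-centroid distance) is computed; the
    selected k maximizes the discrete second difference (curvature) of R. The
    selection is flagged low-confidence when the winning curvature is a small
    fraction (< 0.4) of the curve's total drop — a smooth, structureless curve.
    """
    ks = np.asarray(sorted(k_range), dtype=int)
    if ks.size < 3:
        raise ValueError("k_range must contain at least 3 candidates for curvature")
    X = np.asarray(window_vectors, dtype=float)
    if ks.max() >= X.shape[0]:
        raise ValueError("largest candidate k must be below the number of windows")
    ratios = np.empty(ks.size)
    models = {}
    for i, k in enumerate(ks):
        model = cluster_windows(X, int(k), n_replicates=n_replicates, max_iter=max_iter, seed=seed)
        ratios[i] = model.within_between_ratio(X)
        if keep_models:
            models[int(k)] = model
    curvature = ratios[:-2] - 2 * ratios[1:-1] + ratios[2:]
    best_interior = int(np.argmax(curvature))
    selected = int(ks[best_interior + 1])
    total_drop = float(ratios.max() - ratios.min())
    low_confidence = total_drop <= 0 or (curvature[best_interior] / total_drop) < 0.4
    return ElbowResult(
        selected_k=selected,
        ks=ks,
        ratio=ratios,
        curvature=curvature,
        low_confidence=bool(low_confidence),
        models=models,
    )


def assign_state_vectors(labels: np.ndarray, window_counts: dict) -> dict:
    """Split pooled window labels back into per-scan state vectors.

    Parameters
    ----------
    labels : (N_total,) pooled labels in the concatenation order of the scans.
    window_counts : mapping scan_id -> window count, in concatenation order
        (dicts preserve insertion order).

    Returns
    -------
    dict scan_id -> (W_scan,) label array, original temporal order.
    """
    labels = np.asarray(labels)
    total = sum(window_counts.values())
    if labels.shape[0] != total:
        raise ValueError(
            f"pooled labels have {labels.shape[0]} entries but scans account for {total}"
        )
    out = {}
    offset = 0
    for scan_id, count in window_counts.items():
        if count < 1:
            raise ValueError(f"scan {scan_id!r} has no windows")
        out[scan_id] = labels[offset : offset + count].copy()
        offset += count
    return out


def subject_state_fnc(window_vectors: np.ndarray, state_vector: np.ndarray, k: int) -> np.ndarray:
    """Per-state mean connectome of one scan.

    Returns a (k x P) array; row s is the element-wise mean of the scan's
    windows labeled s, or NaN when the scan never visits state s (missing,
    not zero).
    """
    window_vectors = np.asarray(window_vectors, dtype=float)
    state_vector = np.asarray(state_vector)
    if window_vectors.shape[0] != state_vector.shape[0]:
        raise ValueError("window count and state-vector length disagree")
    out = np.full((k, window_vectors.shape[1]), np.nan)
    for s in range(k):
        mask = state_vector == s
        if mask.any():
            out[s] = window_vectors[mask].mean(axis=0)
    return out


def match_states(centroids_a: np.ndarray, centroids_b: np.ndarray):
    """Optimal one-to-one state matching between two centroid sets.

    Maximizes the total Pearson correlation over all one-to-one assignments
    (Hungarian algorithm, exact). Returns ``(permutation, correlations)``
    where ``permutation[i]`` is the row of B matched to row i of A and
    ``correlations[i]`` the corresponding Pearson correlation.
    """
    A = np.asarray(centroids_a, dtype=float)
    B = np.asarray(centroids_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"centroid sets must share shape, got {A.shape} vs {B.shape}")
    k = A.shape[0]
    As = standardize_rows(A)
    Bs = standardize_rows(B)
    corr = As @ Bs.T
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm, corr[np.arange(k), perm]
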