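"""Conversion classification with ADASYN balancing and a polynomial-kernel SVM.

The prediction target is conversion status: subjects who remain healthy
(majority class, treated as the positive reference) versus subjects who later
convert to very mild dementia (minority class). Class imbalance is corrected
with ADASYN, which synthesizes minority samples preferentially around
minority points that sit among majority neighbors (the hard-to-learn region).

Evaluation protocol (per repeat): generate G = round((m_major - m_minor) *
beta) synthetic minority samples; draw a random majority subset of size G;
train an SVM with kernel k(x1, x2) = (1 + x1'x2)^p on {majority subset +
synthetic minority}, selecting hyperparameters by inner five-fold
cross-validation; evaluate on the real samples excluded from training —
synthetic points never enter any test set. A conventional stratified CV mode
is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "adasyn_oversample",
    "ADASYN",
    "polynomial_kernel",
    "ConfusionCounts",
    "confusion_metrics",
    "ClassificationReport",
    "evaluate_conversion",
]


def polynomial_kernel(x1: np.ndarray, x2: np.ndarray, p: int) -> float:
    """Inhomogeneous polynomial kernel k(x1, x2) = (1 + x1'x2)^p."""
    if int(p) != p or p < 1:
        raise ValueError(f"kernel degree must be a positive integer, got {p}")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("kernel inputs must share dimension")
    return float((1.0 + np.dot(x1, x2)) ** p)


def adasyn_oversample(
    X: np.ndarray,
    y: np.ndarray,
    minority_label=None,
    beta: float = 1.0,
    k_neighbors: int = 5,
    random_state: int | None = None,
):
    """ADASYN: adaptive synthetic oversampling of the minority class.

    For each minority point i, the density ratio r_i = (majority neighbors
    among its k nearest neighbors in the full data) / k decides how many of
    the G = round((m_major - m_minor) * beta) synthetic samples it parents
    (largest-remainder rounding makes the total exactly G). Each synthetic
    sample is x_i + lambda (x_z - x_i) with x_z a random minority neighbor of
    x_i and lambda uniform on [0, 1] — a convex combination of two real
    minority points.

    Returns
    -------
    X_syn : (G, d) synthetic minority samples.
    info : dict with ``parents`` (G, 2) row indices into the minority subset,
        ``lambdas`` (G,), ``density`` (m_minor,) normalized r_i, and
        ``uniform_fallback`` (True when all r_i were zero).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"ADASYN expects exactly 2 classes, got {classes.size}")
    if minority_label is None:
        minority_label = classes[np.argmin(counts)]
    minority_mask = y == minority_label
    m_minor = int(minority_mask.sum())
    m_major = int((~minority_mask).sum())
    if m_minor < k_neighbors + 1:
        raise ValueError(
            f"minority class has {m_minor} samples; need at least k_neighbors + 1 = {k_neighbors + 1}"
        )
    rng = np.random.default_rng(random_state)
    G = int(round((m_major - m_minor) * beta))
    X_min = X[minority_mask]
    if G <= 0:
        empty = np.empty((0, X.shape[1]))
        info = {
            "parents": np.empty((0, 2), dtype=int),
            "lambdas": np.empty(0),
            "density": np.zeros(m_minor),
            "uniform_fallback": False,
            "G": 0,
        }
        return empty, info

    # density ratio: majority fraction among the k nearest neighbors in full data
    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx_all = nn_all.kneighbors(X_min)
    r = np.empty(m_minor)
    min_rows = np.flatnonzero(minority_mask)
    for i in range(m_minor):
        neigh = [j for j in idx_all[i] if j != min_rows[i]][:k_neighbors]
        r[i] = np.sum(~minority_mask[neigh]) / k_neighbors
    uniform_fallback = False
    if r.sum() == 0:
        warnings.warn(
            "ADASYN: minority class fully interior (all density ratios zero); "
            "falling back to uniform allocation",
            RuntimeWarning,
            stacklevel=2,
        )
        r_hat = np.full(m_minor, 1.0 / m_minor)
        uniform_fallback = True
    else:
        r_hat = r / r.sum()

    # largest-remainder allocation so the counts sum to exactly G
    raw = r_hat * G
    g = np.floor(raw).astype(int)
    shortfall = G - g.sum()
    if shortfall > 0:
        order = np.argsort(-(raw - g), kind="stable")
        g[order[:shortfall]] += 1

    # minority-only neighbor graph for interpolation partners
    nn_min = NearestNeighbors(n_neighbors=min(k_neighbors + 1, m_minor)).fit(X_min)
    _, idx_min = nn_min.kneighbors(X_min)
    X_syn = np.empty((G, X.shape[1]))
    parents = np.empty((G, 2), dtype=int)
    lambdas = np.empty(G)
    pos = 0
    for i in range(m_minor):
        partners = idx_min[i][idx_min[i] != i]
        for _ in range(g[i]):
            z = int(rng.choice(partners))
            lam = float(rng.uniform())
            X_syn[pos] = X_min[i] + lam * (X_min[z] - X_min[i])
            parents[pos] = (i, z)
            lambdas[pos] = lam
            pos += 1
    assert pos == G
    info = {
        "parents": parents,
        "lambdas": lambdas,
        "density": r_hat,
        "uniform_fallback": uniform_fallback,
        "G": G,
    }
    return X_syn, info


class ADASYN(BaseEstimator):
    """Estimator-style wrapper around :func:`adasyn_oversample`.

    ``fit_resample(X, y)`` returns the original data with the synthetic
    minority samples appended (synthetic rows last, so callers can keep them
    out of evaluation sets by index).
    """

    def __init__(self, beta: float = 1.0, k_neighbors: int = 5, random_state: int | None = None):
        self.beta = beta
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        minority = classes[np.argmin(counts)]
        X_syn, info = adasyn_oversample(
            X,
            y,
            minority_label=minority,
            beta=self.beta,
            k_neighbors=self.k_neighbors,
            random_state=self.random_state,
        )
        self.synthetic_X_ = X_syn
        self.info_ = info
        self.n_real_ = X.shape[0]
        X_res = np.vstack([X, X_syn])
        y_res = np.concatenate([y, np.full(X_syn.shape[0], minority, dtype=y.dtype)])
        return X_res, y_res


@dataclass
class ConfusionCounts:
    """Confusion counts with the non-converting (majority) class as positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_metrics(c: ConfusionCounts):
    """Accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    A zero denominator yields NaN for that rate (reported missing, not 0).
    """
    if min(c.tp, c.fn, c.tn, c.fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = c.total
    accuracy = (c.tp + c.tn) / total if total > 0 else float("nan")
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return accuracy, sensitivity, specificity


@dataclass
class ClassificationReport:
    """Per-repeat and mean cross-validated performance.

    ``positive_label`` states the convention used in sensitivity/specificity
    (default: the majority, non-converting class); ``flip_positive=True`` in
    :func:`evaluate_conversion` swaps it. ``test_indices`` (row indices into
    the real data) are retained per repeat so leakage of synthetic samples
    into evaluation can be asserted structurally.
    """

    accuracy: list
    sensitivity: list
    specificity: list
    auc: list
    n_repeats: int
    fold_scheme: str
    seed: int | None
    positive_label: object
    best_params: list = field(default_factory=list)
    test_indices: list = field(default_factory=list)
    n_synthetic: int = 0
    warnings: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean(self.specificity))

    @property
    def mean_auc(self) -> float:
        vals = [a for a in self.auc if np.isfinite(a)]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> dict:
        return {
            "accuracy": self.mean_accuracy,
            "sensitivity": self.mean_sensitivity,
            "specificity": self.mean_specificity,
            "auc": self.mean_auc,
            "n_repeats": self.n_repeats,
            "fold_scheme": self.fold_scheme,
            "positive_label": str(self.positive_label),
            "n_synthetic": self.n_synthetic,
        }


def _make_svm(degree: int, c: float) -> Pipeline:
    # gamma=1, coef0=1 make sklearn's poly kernel exactly (1 + x1'x2)^p
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=c)),
        ]
    )


def evaluate_conversion(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    folds: int = 5,
    degrees=(2, 3),
    c_grid=(0.01, 0.1, 1.0, 10.0),
    beta: float = 1.0,
    k_neighbors: int = 5,
    flip_positive: bool = False,
    protocol: str = "adasyn_subset",
    seed: int | None = None,
) -> ClassificationReport:
    """Repeated evaluation of conversion prediction.

    Parameters
    ----------
    X, y : features and binary labels (majority = non-converting).
    protocol : {"adasyn_subset", "stratified_cv"}
        ``adasyn_subset``: per repeat, train on {random majority subset of
        size G + G ADASYN synthetic minority samples}, select (degree, C) by
        inner ``folds``-fold CV on the training set, and test on all real
        samples excluded from training. ``stratified_cv``: conventional
        stratified k-fold with ADASYN applied inside each training fold.
    flip_positive : report sensitivity/specificity with the minority class
        as positive instead of the majority class.

    Returns
    -------
    ClassificationReport with per-repeat metrics; AUC repeats whose test set
    carries a single class are flagged and excluded from the AUC mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must be row-matched")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    positive = minority if flip_positive else majority
    negative = minority if positive is majority else majority
    rng = np.random.default_rng(seed)
    param_grid = {"svm__degree": list(degrees), "svm__C": list(c_grid)}
    report = ClassificationReport(
        accuracy=[],
        sensitivity=[],
        specificity=[],
        auc=[],
        n_repeats=n_repeats,
        fold_scheme=f"{protocol}:{folds}-fold",
        seed=seed,
        positive_label=positive,
    )

    def _score_fold(train_X, train_y, test_X, test_y, test_rows, inner_seed):
        _, train_counts = np.unique(train_y, return_counts=True)
        inner_folds = min(folds, int(train_counts.min()))
        if inner_folds >= 2:
            grid = GridSearchCV(
                _make_svm(2, 1.0),
                param_grid,
                cv=StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=inner_seed),
                scoring="accuracy",
                n_jobs=1,
            )
            grid.fit(train_X, train_y)
            model = grid.best_estimator_
            best_params = dict(grid.best_params_)
        else:
            report.warnings.append("training set too small for inner CV; default hyperparameters")
            model = _make_svm(degrees[0], c_grid[len(c_grid) // 2]).fit(train_X, train_y)
            best_params = {"svm__degree": degrees[0], "svm__C": c_grid[len(c_grid) // 2]}
        pred = model.predict(test_X)
        scores = model.decision_function(test_X)
        tp = int(np.sum((test_y == positive) & (pred == positive)))
        fn = int(np.sum((test_y == positive) & (pred != positive)))
        tn = int(np.sum((test_y == negative) & (pred == negative)))
        fp = int(np.sum((test_y == negative) & (pred != negative)))
        acc, sens, spec = confusion_metrics(ConfusionCounts(tp, fn, tn, fp))
        if np.unique(test_y).size < 2:
            auc = float("nan")
            report.warnings.append("test set with a single class; AUC excluded")
        else:
            # decision_function is signed toward classes_[1]; orient toward `positive`
            sgn = 1.0 if model.classes_[1] == positive else -1.0
            auc = float(roc_auc_score((test_y == positive).astype(int), sgn * scores))
        report.accuracy.append(float(acc))
        report.sensitivity.append(float(sens))
        report.specificity.append(float(spec))
        report.auc.append(auc)
        report.best_params.append(best_params)
        report.test_indices.append(np.asarray(test_rows, dtype=int))

    if protocol == "adasyn_subset":
        major_rows = np.flatnonzero(y == majority)
        for rep in range(n_repeats):
            rep_seed = int(rng.integers(2**31 - 1))
            X_syn, info = adasyn_oversample(
                X,
                y,
                minority_label=minority,
                beta=beta,
                k_neighbors=k_neighbors,
                random_state=rep_seed,
            )
            g = X_syn.shape[0]
            if g == 0:
                raise ValueError(
                    "classes already balanced (no synthetic samples); use protocol='stratified_cv'"
                )
            report.n_synthetic = g
            subset_size = min(g, major_rows.size - 1)
            subset = np.sort(
                np.random.default_rng(rep_seed).choice(major_rows, size=subset_size, replace=False)
            )
            train_X = np.vstack([X[subset], X_syn])
            train_y = np.concatenate(
                [np.full(subset.size, majority, dtype=y.dtype), np.full(g, minority, dtype=y.dtype)]
            )
            test_rows = np.setdiff1d(np.arange(X.shape[0]), subset)
            # structural guard: evaluation rows index real data only
            assert test_rows.max(initial=-1) < X.shape[0]
            _score_fold(train_X, train_y, X[test_rows], y[test_rows], test_rows, rep_seed)
    elif protocol == "stratified_cv":
        for rep in range(n_repeats):
            rep_seed = int(rng.integers(2**31 - 1))
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
            fold_metrics = {"accuracy": [], "sensitivity": [], "specificity": [], "auc": []}
            for tr, te in skf.split(X, y):
                sampler = ADASYN(beta=beta, k_neighbors=k_neighbors, random_state=rep_seed)
                X_res, y_res = sampler.fit_resample(X[tr], y[tr])
                _score_fold(X_res, y_res, X[te], y[te], te, rep_seed)
                report.n_synthetic = sampler.synthetic_X_.shape[0]
                for key in fold_metrics:
                    fold_metrics[key].append(getattr(report, key)[-1])
            # collapse the fold entries of this repeat into their mean
            for key in fold_metrics:
                lst = getattr(report, key)
                del lst[-folds:]
                lst.append(float(np.nanmean(fold_metrics[key])))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return report


class ConversionClassifier(BaseEstimator, ClassifierMixin):
    """Polynomial-kernel SVM with ADASYN balancing, sklearn fit/predict shape.

    Fitting oversamples the minority class with ADASYN, standardizes features
    on the (real + synthetic) training set, and fits SVC with kernel
    (1 + x1'x2)^degree. Prediction and decision_function operate on real data.
    """

    def __init__(
        self,
        degree: int = 2,
        C: float = 1.0,
        beta: float = 1.0,
        k_neighbors: int = 5,
        random_state: int | None = None,
    ):
        self.degree = degree
        self.C = C
        self.beta = beta
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        sampler = ADASYN(
            beta=self.beta, k_neighbors=self.k_neighbors, random_state=self.random_state
        )
        X_res, y_res = sampler.fit_resample(X, y)
        self.sampler_ = sampler
        self.model_ = _make_svm(self.degree, self.C).fit(X_res, y_res)
        self.classes_ = self.model_.named_steps["svm"].classes_
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self.model_.decision_function(np.asarray(X, dtype=float))
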