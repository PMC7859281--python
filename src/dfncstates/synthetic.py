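"""Synthetic cohorts with hidden-state-switching connectivity structure.

The generator emulates the data-generating process the state analysis
assumes: each scan's C-component time series is zero-mean Gaussian whose
instantaneous covariance switches among K latent connectivity states
according to a subject-level Markov chain. Groups (healthy vs impaired)
differ in their transition structure — hence in how much time they occupy
each state — and the clinical score of impaired subjects is linked to their
occupancy of a designated state with a configurable slope (the direction of
the group occupancy difference is a parameter, not a constant).

Regimes switch at a fixed granularity (``samples_per_state_step`` time points
per Markov step, default 10) so ground-truth labels map cleanly onto sliding
windows. Covariances have unit diagonal, making Pearson correlation the
natural estimand of every downstream stage.

Default demographics: healthy subjects' ages are drawn around 69.8 +/- 8.6
years and impaired subjects' around 75.1 +/- 7.9 years, with roughly balanced
gender; impaired clinical scores live in [0.5, 9] and healthy scores are
exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Timecourses

__all__ = [
    "StateCovariance",
    "default_network_blocks",
    "default_block_spec",
    "make_state_covariances",
    "simulate_state_sequence",
    "stationary_distribution",
    "transition_matrix_for_stationary",
    "default_group_transitions",
    "simulate_timecourses",
    "GroundTruthSubject",
    "Cohort",
    "generate_cohort",
    "generate_classification_cohort",
]

NETWORK_NAMES = ("SCN", "ADN", "SMN", "VSN", "CCN", "DMN", "CBN")
# block sizes for C = 53, mirroring the 7 canonical functional domains
_NETWORK_SIZES_53 = (5, 2, 9, 10, 17, 7, 3)


@dataclass
class StateCovariance:
    """One latent state's C x C covariance (unit diagonal, positive definite)."""

    state_id: int
    matrix: np.ndarray
    network_blocks: dict

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("state covariance must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError(f"state {self.state_id}: covariance not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError(f"state {self.state_id}: diagonal must be 1")
        eigvals = np.linalg.eigvalsh(m)
        if eigvals.min() <= 0:
            raise ValueError(f"state {self.state_id}: covariance not positive definite")
        self.matrix = m

    @property
    def n_components(self) -> int:
        return self.matrix.shape[0]


def default_network_blocks(c: int) -> dict:
    """Partition C components into 7 named network blocks (sizes scaled from 53)."""
    sizes = np.array(_NETWORK_SIZES_53, dtype=float) * c / sum(_NETWORK_SIZES_53)
    counts = np.floor(sizes).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() < c:
        counts[np.argmax(sizes - counts)] += 1
    while counts.sum() > c:
        j = np.argmax(counts)
        counts[j] -= 1
    blocks = {}
    start = 0
    for name, n in zip(NETWORK_NAMES, counts):
        blocks[name] = np.arange(start, start + n)
        start += n
    return blocks


def default_block_spec(K: int) -> list:
    """Per-state within/between coupling levels for the default K-state layout.

    The default three states differ in sensorimotor-visual coupling: one
    weakly coupled state with mild SMN-VSN anticorrelation, one moderate
    baseline state, and one strongly coupled state where the sensory blocks
    (ADN/SMN/VSN) correlate with each other and anticorrelate with the rest.
    Extra states beyond three interpolate coupling levels.
    """
    base = [
        {
            "within": {"SCN": 0.45, "ADN": 0.5, "SMN": 0.5, "VSN": 0.5, "CCN": 0.25, "DMN": 0.3, "CBN": 0.45},
            "between": 0.0,
            "pairs": {("SMN", "VSN"): -0.25, ("SCN", "CBN"): 0.30},
        },
        {"within": 0.50, "between": 0.12, "pairs": {("SMN", "VSN"): 0.25}},
        {
            "within": {"SCN": 0.4, "ADN": 0.65, "SMN": 0.75, "VSN": 0.75, "CCN": 0.35, "DMN": 0.45, "CBN": 0.5},
            "between": 0.05,
            "pairs": {
                ("SMN", "VSN"): 0.60,
                ("ADN", "SMN"): 0.35,
                ("ADN", "VSN"): 0.35,
                ("SMN", "CCN"): -0.25,
                ("VSN", "CCN"): -0.25,
                ("SMN", "DMN"): -0.25,
                ("VSN", "DMN"): -0.25,
            },
        },
    ]
    if K <= 3:
        return base[:K]
    spec = list(base)
    for extra in range(K - 3):
        w = 0.3 + 0.1 * extra
        spec.append({"within": w, "between": -0.05 * (extra + 1), "pairs": {}})
    return spec


def _nearest_unit_diagonal_pd(template: np.ndarray, min_eig: float) -> np.ndarray:
    """Clip eigenvalues at a floor, then renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh((template + template.T) / 2.0)
    vals = np.maximum(vals, min_eig)
    m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return (m + m.T) / 2.0


def make_state_covariances(
    c: int,
    K: int,
    block_spec: list | None = None,
    blocks: dict | None = None,
    min_eig: float = 0.01,
    repair_tol: float = 0.25,
    max_pairwise_corr: float = 0.9,
) -> list:
    """Build K distinguishable unit-diagonal positive-definite state covariances.

    Each state's template sets within-block couplings and (pairwise or global)
    between-block couplings on a named network partition, then is repaired to
    the nearest positive-definite matrix by eigenvalue clipping at ``min_eig``
    followed by renormalization to unit diagonal.

    Raises
    ------
    ValueError
        If the repair distorts some template entry by more than ``repair_tol``
        (the template is too far from positive definite), naming the state; or
        if two states' vectorized patterns correlate above
        ``max_pairwise_corr`` (not distinguishable).
    """
    if c < 2 or K < 1:
        raise ValueError("need c >= 2 and K >= 1")
    if blocks is None:
        blocks = default_network_blocks(c)
    if block_spec is None:
        block_spec = default_block_spec(K)
    if len(block_spec) != K:
        raise ValueError(f"block_spec has {len(block_spec)} entries, expected K={K}")
    names = list(blocks)
    covs = []
    for s, spec in enumerate(block_spec):
        within = spec.get("within", 0.0)
        between = spec.get("between", 0.0)
        pairs = spec.get("pairs", {})
        levels = list(within.values()) if isinstance(within, dict) else [within]
        for level in [*levels, between, *pairs.values()]:
            if not -1.0 < level < 1.0:
                raise ValueError(f"state {s}: coupling level {level} outside (-1, 1)")
        template = np.full((c, c), float(between))
        for name in names:
            idx = blocks[name]
            w = within[name] if isinstance(within, dict) else within
            template[np.ix_(idx, idx)] = w
        for (na, nb), level in pairs.items():
            ia, ib = blocks[na], blocks[nb]
            template[np.ix_(ia, ib)] = level
            template[np.ix_(ib, ia)] = level
        np.fill_diagonal(template, 1.0)
        matrix = _nearest_unit_diagonal_pd(template, min_eig)
        off = ~np.eye(c, dtype=bool)
        distortion = np.abs(matrix - template)[off].max()
        if distortion > repair_tol:
            raise ValueError(
                f"state {s}: template cannot be repaired to positive definite at floor "
                f"{min_eig} without distorting couplings by {distortion:.3f} (> {repair_tol})"
            )
        covs.append(StateCovariance(state_id=s, matrix=matrix, network_blocks=blocks))
    for i in range(K):
        for j in range(i + 1, K):
            rows, cols = np.tril_indices(c, k=-1)
            vi = covs[i].matrix[rows, cols]
            vj = covs[j].matrix[rows, cols]
            if vi.std() > 0 and vj.std() > 0:
                r = float(np.corrcoef(vi, vj)[0, 1])
                if r >= max_pairwise_corr:
                    raise ValueError(
                        f"states {i} and {j} are not distinguishable (pattern correlation {r:.3f})"
                    )
    return covs


def _validate_transition(transition: np.ndarray) -> np.ndarray:
    t = np.asarray(transition, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(t < -1e-12):
        raise ValueError("transition probabilities must be non-negative")
    colsums = t.sum(axis=0)
    bad = np.flatnonzero(np.abs(colsums - 1.0) > 1e-9)
    if bad.size:
        raise ValueError(
            f"transition matrix columns must sum to 1; column {bad[0]} sums to {colsums[bad[0]]:.6f}"
        )
    return t


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with T pi = pi (column-stochastic convention)."""
    t = _validate_transition(transition)
    vals, vecs = np.linalg.eig(t)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix_for_stationary(pi: np.ndarray, stay: float = 0.85) -> np.ndarray:
    """Column-stochastic matrix with stationary distribution ``pi``.

    T = stay * I + (1 - stay) * pi 1'; higher ``stay`` gives longer dwell
    times without changing the long-run occupancy.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a probability vector")
    if not 0.0 <= stay < 1.0:
        raise ValueError("stay must lie in [0, 1)")
    k = pi.size
    return stay * np.eye(k) + (1.0 - stay) * np.outer(pi, np.ones(k))


def default_group_transitions(
    K: int = 3,
    stay: float = 0.85,
    healthy_favored_state: int = 2,
    impaired_favored_state: int = 0,
    contrast: float = 0.12,
) -> dict:
    """Group transition matrices whose stationary occupancies differ.

    Both groups share a common baseline occupancy (state 2 of 3 dominant, as
    in a baseline-heavy regime); the healthy group shifts ``contrast`` mass
    toward ``healthy_favored_state`` and the impaired group toward
    ``impaired_favored_state``. Which state favors which group is a
    parameter — the direction of the group difference is configurable.
    """
    base = np.full(K, 1.0 / K)
    if K == 3:
        base = np.array([0.24, 0.52, 0.24])
    pi_h = base.copy()
    pi_i = base.copy()
    pi_h[healthy_favored_state] += contrast
    pi_h[impaired_favored_state] -= contrast
    pi_i[impaired_favored_state] += contrast
    pi_i[healthy_favored_state] -= contrast
    if np.any(pi_h <= 0) or np.any(pi_i <= 0):
        raise ValueError("contrast too large for the baseline occupancy")
    return {
        "healthy": transition_matrix_for_stationary(pi_h, stay),
        "impaired": transition_matrix_for_stationary(pi_i, stay),
    }


def simulate_state_sequence(
    transition: np.ndarray,
    L: int,
    initial: np.ndarray | int | None = None,
    seed=None,
) -> np.ndarray:
    """Simulate a length-L Markov state sequence (labels 0..K-1).

    ``transition[i, j]`` is p(next = i | current = j) (column-stochastic).
    ``initial`` may be a start state, a distribution over states, or None
    (stationary distribution).
    """
    t = _validate_transition(transition)
    if L < 1:
        raise ValueError("L must be >= 1")
    k = t.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if initial is None:
        p0 = stationary_distribution(t)
    elif np.isscalar(initial):
        p0 = np.zeros(k)
        p0[int(initial)] = 1.0
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (k,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial must be a state index or a K-simplex vector")
    seq = np.empty(L, dtype=int)
    # cumulative columns let each step be a single uniform draw
    cum = np.cumsum(t, axis=0)
    u = rng.uniform(size=L)
    seq[0] = int(np.searchsorted(np.cumsum(p0), u[0], side="right"))
    for step in range(1, L):
        seq[step] = int(np.searchsorted(cum[:, seq[step - 1]], u[step], side="right"))
    return np.minimum(seq, k - 1)


def simulate_timecourses(
    covariances: list,
    state_sequence: np.ndarray,
    samples_per_state_step: int = 10,
    obs_noise_sd: float = 0.0,
    seed=None,
    scan_id: str = "scan",
    n_timepoints: int | None = None,
    tr_seconds: float = 2.2,
):
    """Draw component time courses under a switching-covariance regime.

    Each Markov step contributes ``samples_per_state_step`` consecutive
    zero-mean Gaussian samples with the step's state covariance, plus
    independent observation noise of SD ``obs_noise_sd``. Optionally truncated
    to ``n_timepoints`` rows (e.g., 159 to mimic a 6-min scan after dummy
    removal).

    Returns
    -------
    (Timecourses, regime) where ``regime`` holds the per-time-point
    ground-truth state label.
    """
    state_sequence = np.asarray(state_sequence, dtype=int)
    if samples_per_state_step < 1:
        raise ValueError("samples_per_state_step must be >= 1")
    K = len(covariances)
    if state_sequence.min() < 0 or state_sequence.max() >= K:
        raise ValueError(
            f"state sequence labels must lie in 0..{K - 1}; got max {state_sequence.max()}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = covariances[0].n_components
    chols = [np.linalg.cholesky(cov.matrix) for cov in covariances]
    t_total = state_sequence.size * samples_per_state_step
    data = np.empty((t_total, c))
    regime = np.repeat(state_sequence, samples_per_state_step)
    for s in range(K):
        mask = regime == s
        n = int(mask.sum())
        if n:
            data[mask] = rng.standard_normal((n, c)) @ chols[s].T
    if obs_noise_sd > 0:
        data += obs_noise_sd * rng.standard_normal(data.shape)
    if n_timepoints is not None:
        if n_timepoints > t_total:
            raise ValueError(f"requested {n_timepoints} time points but only {t_total} generated")
        data = data[:n_timepoints]
        regime = regime[:n_timepoints]
    return Timecourses(scan_id=scan_id, data=data, tr_seconds=tr_seconds), regime


@dataclass
class GroundTruthSubject:
    """Latent truth for one simulated scan."""

    subject_id: str
    group: str  # "healthy" | "impaired"
    true_transition_matrix: np.ndarray
    true_state_sequence: np.ndarray
    age: float
    gender: int
    cdr_sob: float

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "impaired"):
            raise ValueError(f"unknown group {self.group!r}")
        if (self.group == "healthy") != (self.cdr_sob == 0.0):
            raise ValueError("cdr_sob must be 0 exactly for healthy subjects and positive otherwise")


@dataclass
class Cohort:
    """Simulated cohort: scans, metadata, and full ground truth."""

    scans: list  # list[Timecourses]
    metadata: pd.DataFrame  # subject_id, scan_id, group, age, gender, cdr_sob
    subjects: list  # list[GroundTruthSubject]
    state_covariances: list  # list[StateCovariance]
    regimes: dict = field(default_factory=dict)  # scan_id -> per-time-point labels
    group_transitions: dict = field(default_factory=dict)


def generate_cohort(
    n_healthy: int,
    n_impaired: int,
    K: int = 3,
    c: int = 53,
    group_transition_matrices: dict | None = None,
    score_model: dict | None = None,
    covariate_model: dict | None = None,
    state_covariances: list | None = None,
    linked_state: int = 0,
    n_timepoints: int = 159,
    samples_per_state_step: int = 10,
    obs_noise_sd: float = 0.2,
    include_timecourses: bool = True,
    seed: int | None = None,
) -> Cohort:
    """Generate a labeled cohort of switching-covariance scans.

    Parameters
    ----------
    n_healthy, n_impaired : group sizes (scans; one scan per subject).
    group_transition_matrices : {"healthy": T, "impaired": T} column-stochastic
        matrices; defaults differ in occupancy of states 0 and 2 (direction
        configurable via :func:`default_group_transitions`).
    score_model : dict with keys ``slope`` (clinical-score units per unit
        occupancy of ``linked_state``, default 6.0), ``noise_sd`` (default
        0.8) and ``center`` (default 2.7). Impaired scores are
        center + slope * (occupancy - group mean occupancy) + noise, clipped
        to [0.5, 9]; healthy scores are exactly 0.
    covariate_model : dict with per-group age means/SDs and gender
        probability; defaults emulate an elderly cohort (healthy 69.8 +/- 8.6,
        impaired 75.1 +/- 7.9 years).
    linked_state : the state whose occupancy drives the clinical score.
    obs_noise_sd : observation noise SD on top of the unit-variance signal.
    include_timecourses : when False, only latent truth (state sequences),
        covariates and scores are generated — useful for replication studies
        of the feature/association stages where time courses are not needed.

    Returns
    -------
    Cohort. Fully reproducible: identical seeds give bitwise-identical output.
    """
    if n_healthy < 0 or n_impaired < 0 or n_healthy + n_impaired < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    if state_covariances is None and include_timecourses:
        state_covariances = make_state_covariances(c, K)
    if group_transition_matrices is None:
        group_transition_matrices = default_group_transitions(K)
    for name in ("healthy", "impaired"):
        _validate_transition(group_transition_matrices[name])
    score_model = {"slope": 6.0, "noise_sd": 0.8, "center": 2.7, **(score_model or {})}
    covariate_model = {
        "age_mean": {"healthy": 69.83, "impaired": 75.10},
        "age_sd": {"healthy": 8.64, "impaired": 7.85},
        "p_gender": 0.5,
        **(covariate_model or {}),
    }
    if not np.isfinite(score_model["slope"]):
        raise ValueError("score_model slope must be finite")
    L = int(np.ceil(n_timepoints / samples_per_state_step))

    groups = ["healthy"] * n_healthy + ["impaired"] * n_impaired
    scans, subjects, regimes = [], [], {}
    rows = []
    occupancies = np.empty(len(groups))
    sequences = []
    for i, group in enumerate(groups):
        seq = simulate_state_sequence(group_transition_matrices[group], L, seed=rng)
        sequences.append(seq)
        occupancies[i] = np.mean(seq == linked_state)
    mean_occ = {
        g: occupancies[[grp == g for grp in groups]].mean() if g in groups else 0.0
        for g in ("healthy", "impaired")
    }
    for i, group in enumerate(groups):
        subject_id = f"sub{i + 1:04d}"
        scan_id = f"{subject_id}_scan1"
        if include_timecourses:
            tc, regime = simulate_timecourses(
                state_covariances,
                sequences[i],
                samples_per_state_step=samples_per_state_step,
                obs_noise_sd=obs_noise_sd,
                seed=rng,
                scan_id=scan_id,
                n_timepoints=n_timepoints,
            )
        else:
            tc, regime = None, None
        age = float(
            rng.normal(covariate_model["age_mean"][group], covariate_model["age_sd"][group])
        )
        gender = int(rng.uniform() < covariate_model["p_gender"])
        if group == "healthy":
            cdr = 0.0
        else:
            cdr = (
                score_model["center"]
                + score_model["slope"] * (occupancies[i] - mean_occ["impaired"])
                + score_model["noise_sd"] * rng.standard_normal()
            )
            cdr = float(np.clip(cdr, 0.5, 9.0))
        subjects.append(
            GroundTruthSubject(
                subject_id=subject_id,
                group=group,
                true_transition_matrix=group_transition_matrices[group],
                true_state_sequence=sequences[i],
                age=age,
                gender=gender,
                cdr_sob=cdr,
            )
        )
        if include_timecourses:
            scans.append(tc)
            regimes[scan_id] = regime
        rows.append((subject_id, scan_id, group, age, gender, cdr))
    metadata = pd.DataFrame(
        rows, columns=["subject_id", "scan_id", "group", "age", "gender", "cdr_sob"]
    )
    return Cohort(
        scans=scans,
        metadata=metadata,
        subjects=subjects,
        state_covariances=state_covariances or [],
        regimes=regimes,
        group_transitions=dict(group_transition_matrices),
    )


def temporal_feature_families(cohort: Cohort, K: int | None = None):
    """Temporal feature families from a cohort's ground-truth state sequences.

    Convenience for replication studies of the association stage: computes the
    transition (``hmm``) and occupancy (``ocr``) feature tables directly from
    each subject's true state sequence, bypassing time-course simulation and
    clustering.

    Returns
    -------
    (families, clinical) where families maps ``"hmm"``/``"ocr"`` to per-scan
    DataFrames and clinical carries scan_id, cdr_sob, age, gender.
    """
    from .features import feature_table  # local import to avoid cycle

    if K is None:
        K = int(max(s.true_state_sequence.max() for s in cohort.subjects)) + 1
    seqs = {
        row.scan_id: subj.true_state_sequence
        for row, subj in zip(cohort.metadata.itertuples(), cohort.subjects)
    }
    feats = feature_table(seqs, K).drop(columns=["any_empty_transition_column"])
    families = {
        "hmm": feats[[c for c in feats.columns if not c.startswith("ocr")]],
        "ocr": feats[[c for c in feats.columns if c.startswith("ocr")]],
    }
    clinical = cohort.metadata[["scan_id", "cdr_sob", "age", "gender"]]
    return families, clinical


def generate_classification_cohort(
    n_major: int = 85,
    n_minor: int = 40,
    n_features: int = 12,
    effect_size: float = 2.0,
    seed: int | None = None,
):
    """Two Gaussian clouds for classifier evaluation.

    The minority cloud's mean is shifted by a vector of Euclidean length
    ``effect_size`` (isotropic unit covariance in both classes), so the
    optimal AUC is Phi(effect_size / sqrt(2)).

    Returns
    -------
    (X, y) with y = 0 for the n_major majority rows, 1 for the n_minor
    minority rows.
    """
    if n_minor < 2 or n_major < n_minor:
        raise ValueError("need n_major >= n_minor >= 2")
    rng = np.random.default_rng(seed)
    shift = np.full(n_features, effect_size / np.sqrt(n_features))
    X_major = rng.standard_normal((n_major, n_features))
    X_minor = rng.standard_normal((n_minor, n_features)) + shift
    X = np.vstack([X_major, X_minor])
    y = np.concatenate([np.zeros(n_major, dtype=int), np.ones(n_minor, dtype=int)])
    return X, y
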