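"""Covariate-adjusted association between connectivity features and a clinical score.

Each feature is related to the score by partial correlation controlling for
age and gender: both variables are residualized on [intercept, covariates] by
least squares and the Pearson correlation of the residuals is tested with a
t statistic on n - q - 2 degrees of freedom. P values are adjusted within
feature family (state-specific connectivity, occupancy, transition
probabilities) by the Benjamini-Hochberg step-up procedure.

Scans with a missing value for a feature (e.g., a state the scan never
visits) are dropped pairwise for that feature only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "partial_correlation",
    "bh_adjust",
    "run_association",
    "two_sample_ttest",
]


def partial_correlation(x, y, covariates=None):
    """Partial Pearson correlation of x and y controlling for covariates.

    Parameters
    ----------
    x, y : (n,) arrays.
    covariates : (n, q) array or None
        Control variables; None reduces to the plain Pearson correlation.

    Returns
    -------
    (r, p, n_used) : partial correlation, two-sided p value from
        t = r sqrt(df / (1 - r^2)) with df = n - q - 2, and the number of
        pairwise-complete observations used. When exactly one variable is
        fully explained by the covariates the result is (0, 1, n) — nothing
        remains to correlate; when both residuals are degenerate it is
        (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.shape[0], 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != x.shape[0]:
            Z = Z.T
    if x.shape != y.shape or Z.shape[0] != x.shape[0]:
        raise ValueError("x, y and covariates must share the sample dimension")
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[keep], y[keep], Z[keep]
    n = x.shape[0]
    q = Z.shape[1]
    if n <= q + 2:
        raise ValueError(f"need n > q + 2 complete observations, got n={n}, q={q}")
    design = np.hstack([np.ones((n, 1)), Z])
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    deg_x = np.linalg.norm(rx) <= 1e-10 * max(1.0, np.linalg.norm(x))
    deg_y = np.linalg.norm(ry) <= 1e-10 * max(1.0, np.linalg.norm(y))
    if deg_x and deg_y:
        return float("nan"), float("nan"), n
    if deg_x or deg_y:
        # one variable fully explained by the covariates: nothing left to
        # correlate, so the partial correlation is zero by convention
        return 0.0, 1.0, n
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - q - 2
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p, n


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up, clipped at 1).

    On the sorted sequence, adjusted_(i) = min_{j >= i} m p_(j) / j, mapped
    back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AssociationResult:
    """Tidy association table plus run metadata."""

    table: pd.DataFrame
    alpha: float
    covariates: tuple
    warnings: list


def run_association(
    feature_families: dict,
    clinical: pd.DataFrame,
    score_column: str = "cdr_sob",
    covariate_columns: tuple = ("age", "gender"),
    alpha: float = 0.05,
) -> AssociationResult:
    """Partial-correlation screen of every feature family against the score.

    Parameters
    ----------
    feature_families : mapping family name -> DataFrame (index scan_id,
        columns features). Typical families: ``state_fnc_1..k`` (C(C-1)/2
        connectivity features each), ``ocr`` (k features), ``hmm`` (k^2
        features). BH adjustment runs independently within each family.
    clinical : DataFrame with scan_id index or column, the score column and
        the covariate columns.
    alpha : significance level on the adjusted p values.

    Returns
    -------
    AssociationResult; ``table`` rows carry (family, feature, n_used,
    partial_r, p_raw, p_adjusted, significant).
    """
    clin = clinical.copy()
    if "scan_id" in clin.columns:
        clin = clin.set_index("scan_id")
    needed = [score_column, *covariate_columns]
    missing = [c for c in needed if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    warnings_list = []
    rows = []
    for family, feats in feature_families.items():
        feats = feats.copy()
        if "scan_id" in getattr(feats, "columns", []):
            feats = feats.set_index("scan_id")
        joined = feats.join(clin[needed], how="inner")
        if joined.shape[0] < len(covariate_columns) + 3:
            warnings_list.append(f"family {family!r}: too few joined scans, skipped")
            continue
        cov = joined[list(covariate_columns)].to_numpy()
        score = joined[score_column].to_numpy()
        family_rows = []
        for feature in feats.columns:
            x = joined[feature].to_numpy(dtype=float)
            try:
                r, p, n_used = partial_correlation(x, score, cov)
            except ValueError:
                warnings_list.append(f"{family}/{feature}: insufficient complete data")
                continue
            if not np.isfinite(p):
                warnings_list.append(f"{family}/{feature}: degenerate residual variance")
                continue
            family_rows.append((family, feature, n_used, r, p))
        if not family_rows:
            warnings_list.append(f"family {family!r}: no usable features")
            continue
        fam = pd.DataFrame(
            family_rows, columns=["family", "feature", "n_used", "partial_r", "p_raw"]
        )
        fam["p_adjusted"] = bh_adjust(fam["p_raw"].to_numpy())
        fam["significant"] = fam["p_adjusted"] < alpha
        rows.append(fam)
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["family", "feature", "n_used", "partial_r", "p_raw", "p_adjusted", "significant"]
        )
    )
    return AssociationResult(
        table=table, alpha=alpha, covariates=tuple(covariate_columns), warnings=warnings_list
    )


def two_sample_ttest(a, b):
    """Pooled-variance two-sample t test with its degrees of freedom.

    Returns ``(t, p, df)`` where df = n_a + n_b - 2 (123 for groups of 85
    and 40).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue), a.size + b.size - 2
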