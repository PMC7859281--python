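"""End-to-end orchestration: simulate -> postproc -> dfnc -> states -> features
-> associate -> classify, with a serializable config and a run manifest.

Every stage writes plain-text tables under the run's output directory and
registers its outputs (with SHA-256 checksums) in the manifest; re-running
with an identical config and seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import evaluate_conversion
from .features import feature_table
from .io import load_cohort_dir, write_cohort, write_json_atomic
from .postproc import TimecoursePostprocessor
from .stats import run_association
from .states import assign_state_vectors, cluster_windows, elbow_select_k, subject_state_fnc
from .synthetic import generate_cohort
from .windows import SlidingWindowConnectivity, static_fnc, vectorize_fnc

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Serializes to/from YAML; unknown keys are rejected on load.
    """

    out_dir: str = "run"
    in_dir: str | None = None  # existing cohort directory; None -> simulate
    seed: int = 0
    # simulate
    n_healthy: int = 40
    n_impaired: int = 20
    n_components: int = 53
    n_states: int = 3
    n_timepoints: int = 159
    obs_noise_sd: float = 0.2
    # postproc
    detrend_order: int = 3
    apply_despike: bool = True
    cutoff_hz: float | None = 0.15
    tr_seconds: float = 2.2
    # dfnc
    window_trs: int = 20
    gaussian_sigma: float = 3.0
    step: int = 1
    # states
    k: int | None = 3  # None -> elbow selection over k_range
    k_range: tuple = (2, 8)
    n_replicates: int = 20
    max_iter: int = 1000
    # associate
    alpha: float = 0.05
    covariates: tuple = ("age", "gender")
    # classify
    run_classification: bool = True
    n_repeats: int = 10
    folds: int = 5
    beta: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("k_range", "covariates"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("k_range", "covariates"):
            d[name] = list(d[name])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.doc = {
            "config": config.to_dict(),
            "version": __version__,
            "stages": [],
            "warnings": [],
        }

    def stage(self, name: str, outputs: list, started: float, **extra):
        self.doc["stages"].append(
            {
                "name": name,
                "wall_seconds": round(time.monotonic() - started, 3),
                "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                **extra,
            }
        )

    def warn(self, message: str):
        self.doc["warnings"].append(message)

    def write(self, path) -> dict:
        write_json_atomic(self.doc, path)
        return self.doc


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages in order; returns the manifest document.

    A failure in stage n raises :class:`PipelineError` naming the stage and
    leaves the outputs of stages < n on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    rng = np.random.default_rng(config.seed)

    # --- stage: simulate or load -------------------------------------------
    stage, t0 = "simulate", time.monotonic()
    try:
        if config.in_dir is None:
            cohort = generate_cohort(
                n_healthy=config.n_healthy,
                n_impaired=config.n_impaired,
                K=config.n_states,
                c=config.n_components,
                n_timepoints=config.n_timepoints,
                obs_noise_sd=config.obs_noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            cohort_dir = write_cohort(cohort, out_dir / "cohort")
            scans, metadata = cohort.scans, cohort.metadata
            manifest.stage(stage, [cohort_dir / "metadata.csv"], t0, n_scans=len(scans))
        else:
            scans, metadata = load_cohort_dir(config.in_dir, tr_seconds=config.tr_seconds)
            manifest.stage("load", [], t0, n_scans=len(scans))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: postproc ----------------------------------------------------
    stage, t0 = "postproc", time.monotonic()
    try:
        post = TimecoursePostprocessor(
            detrend_order=config.detrend_order,
            apply_despike=config.apply_despike,
            cutoff_hz=config.cutoff_hz,
            tr_seconds=config.tr_seconds,
        ).fit()
        cleaned = [post.transform(tc) for tc in scans]
        manifest.stage(stage, [], t0, n_scans=len(cleaned))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: dfnc --------------------------------------------------------
    stage, t0 = "dfnc", time.monotonic()
    try:
        swc = SlidingWindowConnectivity(
            window_trs=config.window_trs, gaussian_sigma=config.gaussian_sigma, step=config.step
        ).fit()
        window_vectors = {tc.scan_id: swc.transform(tc) for tc in cleaned}
        sfnc = {tc.scan_id: vectorize_fnc(static_fnc(tc)) for tc in cleaned}
        sfnc_frame = pd.DataFrame.from_dict(sfnc, orient="index")
        sfnc_frame.index.name = "scan_id"
        sfnc_path = out_dir / "sfnc.csv"
        sfnc_frame.to_csv(sfnc_path, float_format="%.8g")
        manifest.stage(
            stage,
            [sfnc_path],
            t0,
            windows_per_scan={k: int(v.shape[0]) for k, v in window_vectors.items()},
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: states ------------------------------------------------------
    stage, t0 = "states", time.monotonic()
    try:
        pooled = np.vstack(list(window_vectors.values()))
        counts = {k: v.shape[0] for k, v in window_vectors.items()}
        states_seed = int(rng.integers(2**31 - 1))
        if config.k is None:
            elbow = elbow_select_k(
                pooled,
                k_range=range(config.k_range[0], config.k_range[1] + 1),
                n_replicates=config.n_replicates,
                max_iter=config.max_iter,
                seed=states_seed,
            )
            k = elbow.selected_k
            if elbow.low_confidence:
                manifest.warn("elbow selection low-confidence (no sharp curvature)")
        else:
            k = config.k
        model = cluster_windows(
            pooled, k, n_replicates=config.n_replicates, max_iter=config.max_iter, seed=states_seed
        )
        state_vectors = assign_state_vectors(model.labels_, counts)
        centroid_path = out_dir / "state_centroids.csv"
        pd.DataFrame(model.centroids_).to_csv(centroid_path, index=False, float_format="%.8g")
        sv_rows = [
            (scan_id, w, int(s) + 1)
            for scan_id, labels in state_vectors.items()
            for w, s in enumerate(labels)
        ]
        sv_path = out_dir / "state_vectors.csv"
        pd.DataFrame(sv_rows, columns=["scan_id", "window", "state"]).to_csv(sv_path, index=False)
        manifest.stage(stage, [centroid_path, sv_path], t0, k=int(k))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: features ----------------------------------------------------
    stage, t0 = "features", time.monotonic()
    try:
        feats = feature_table(state_vectors, k)
        feat_path = out_dir / "temporal_features.csv"
        feats.to_csv(feat_path, float_format="%.8g")
        manifest.stage(stage, [feat_path], t0, n_features=feats.shape[1] - 1)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: associate ---------------------------------------------------
    stage, t0 = "associate", time.monotonic()
    try:
        feat_cols = feats.drop(columns=["any_empty_transition_column"])
        families = {
            "hmm": feat_cols[[c for c in feat_cols.columns if not c.startswith("ocr")]],
            "ocr": feat_cols[[c for c in feat_cols.columns if c.startswith("ocr")]],
        }
        for s in range(k):
            per_scan = {
                scan_id: subject_state_fnc(window_vectors[scan_id], labels, k)[s]
                for scan_id, labels in state_vectors.items()
            }
            fam = pd.DataFrame.from_dict(per_scan, orient="index")
            fam.index.name = "scan_id"
            fam.columns = [f"pair{j}" for j in range(fam.shape[1])]
            families[f"state_fnc_{s + 1}"] = fam
        assoc = run_association(
            families,
            metadata,
            covariate_columns=config.covariates,
            alpha=config.alpha,
        )
        for w in assoc.warnings:
            manifest.warn(f"associate: {w}")
        assoc_path = out_dir / "associations.csv"
        assoc.table.to_csv(assoc_path, index=False, float_format="%.8g")
        manifest.stage(stage, [assoc_path], t0, n_tests=int(assoc.table.shape[0]))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- stage: classify ----------------------------------------------------
    if config.run_classification:
        stage, t0 = "classify", time.monotonic()
        try:
            meta_idx = metadata.set_index("scan_id")
            sfnc_matrix = sfnc_frame.loc[feats.index].to_numpy()
            feat_matrix = feats.drop(columns=["any_empty_transition_column"]).to_numpy()
            X = np.hstack([sfnc_matrix, feat_matrix])
            y = (meta_idx.loc[feats.index, "group"] == "impaired").astype(int).to_numpy()
            counts = np.bincount(y)
            protocol = "adasyn_subset" if counts.min() != counts.max() else "stratified_cv"
            if protocol == "stratified_cv":
                manifest.warn("classify: balanced classes, using stratified CV (no ADASYN subset)")
            report = evaluate_conversion(
                X,
                y,
                n_repeats=config.n_repeats,
                folds=config.folds,
                beta=config.beta,
                protocol=protocol,
                seed=int(rng.integers(2**31 - 1)),
            )
            for w in report.warnings:
                manifest.warn(f"classify: {w}")
            cls_path = out_dir / "classification.json"
            write_json_atomic(report.summary(), cls_path)
            manifest.stage(stage, [cls_path], t0)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    return manifest.write(out_dir / "manifest.json")
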