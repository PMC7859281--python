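# Methods

## Model and assumptions

The pipeline treats a scan as T samples of a C-dimensional component signal
(C = 53 intrinsic connectivity networks by default, TR = 2.2 s) whose
instantaneous covariance is piecewise constant: at any time the brain
occupies one of K latent connectivity states, each a unit-diagonal,
positive-definite C × C correlation matrix, and switches between states as a
first-order Markov chain. Under that model the tapered sliding-window
Pearson correlation is a noisy local estimate of the active state's
correlation matrix; pooling all subjects' windows and clustering under
correlation distance estimates the state patterns (centroids) and each
scan's window-wise state sequence; and the sequence's maximum-likelihood
transition matrix and occupancy vector are the temporal features.

Assumptions worth stating explicitly:

- **Correlation, not covariance, is the estimand.** States have unit
  variances by construction, so windowed Pearson correlation is unbiased for
  the state pattern; a covariance mode exists (`kind="covariance"`) but the
  analysis and all defaults use correlation, whose entries live on the
  [−1, 1] scale the state figures use.
- **First-order Markov temporal structure** at the granularity of the regime
  switch (see below). The "HMM features" are the transition probabilities of
  the *observed* label sequence — no emission model is fit.
- **Scans are exchangeable rows.** Repeated scans per subject are not
  modeled; association results treat scans independently.

## Synthetic cohort generator

`generate_cohort` draws, per subject: a Markov state sequence from the
subject's group transition matrix; zero-mean Gaussian time courses with the
active state's covariance (Cholesky sampling), plus isotropic observation
noise; age, gender, and a clinical severity score.

What it emulates, and the defaults:

- **State patterns** (`make_state_covariances`): block templates on a
  7-network partition (subcortical, auditory, sensorimotor, visual,
  cognitive-control, default-mode, cerebellar; sizes 5/2/9/10/17/7/3 at
  C = 53). The three default states are a weakly coupled state with mild
  sensorimotor–visual anticorrelation, a moderately coupled baseline, and a
  strongly sensory-coupled state whose sensory blocks anticorrelate with
  cognitive-control and default-mode blocks. Templates are repaired to the
  nearest positive-definite matrix by eigenvalue clipping (floor 0.01) and
  re-normalization to unit diagonal; the repair must not distort any
  coupling by more than 0.25, and any two states must correlate below 0.9 in
  vectorized-pattern space, else the generator refuses. Two block templates
  that are affine in the same within-block indicator correlate at exactly 1
  and are genuinely unclusterable under correlation distance — the
  distinguishability guard exists precisely for that case.
- **Regime granularity**: the chain steps every `samples_per_state_step = 10`
  time points, so dwell times are multiples of 10 samples and ground-truth
  labels map cleanly onto 20-TR windows (a window straddles at most two
  regimes). A 159-volume scan uses a 16-step chain truncated to 159 samples.
- **Group dynamics** (`default_group_transitions`): both groups share a
  baseline-heavy stationary occupancy (0.24, 0.52, 0.24 for K = 3) with
  self-transition weight `stay = 0.85` per step (expected dwell ≈ 67 time
  points); the healthy group shifts 0.12 occupancy mass toward one designated
  state and the impaired group toward another. *Which* state favors which
  group is a parameter (`healthy_favored_state`, `impaired_favored_state`),
  because the direction of this group difference is exactly the kind of
  claim a study may print inconsistently; the default follows the reading
  that healthy subjects spend more time in the strongly sensory-coupled
  state and impaired subjects in the weakly coupled one.
- **Clinical score**: healthy subjects score exactly 0; impaired subjects
  score `center + slope · (occupancy − group mean occupancy) + noise`,
  clipped to [0.5, 9], with defaults center 2.7 (the impaired cohort's
  typical mean), slope 6.0 score units per unit occupancy of the linked
  state, and noise SD 0.8. Occupancy varies across subjects through
  finite-chain sampling, which is what makes the coupling detectable.
- **Covariates**: ages ~ Normal(69.83, 8.64) for healthy and
  Normal(75.10, 7.85) for impaired subjects; gender Bernoulli(0.5), coded
  0/1.
- **Observation noise**: SD 0.2 on top of the unit-variance signal — enough
  to make window estimates realistically noisy without hiding the states.

What the generator does **not** emulate: hemodynamic autocorrelation and
low-pass spectral shape of BOLD, scanner drift and physiological noise
spectra, head motion, spatial (voxel-level) structure, subject-level
variation in the state patterns themselves, and repeated scans per subject.
Passing recovery tests therefore demonstrates the *estimators* are correct
under the model the analysis assumes — not that real fMRI satisfies that
model.

## Numerical choices

- **Taper**: central 20 samples of rect(20) ∗ Gaussian(σ = 3, grid ± 4σ),
  symmetrized against floating-point roundoff and scaled to sum to the
  window length. Weighted Pearson correlation uses the taper as observation
  weights; with uniform weights it equals plain Pearson to 1e−12.
- **Window convention**: starts at 0, 1, … while start + 20 ≤ T − 1, i.e.
  T − 20 windows at step 1 (139 for T = 159). Windows with a zero-variance
  channel are flagged and their affected entries reported missing.
- **Clustering**: rows are centered and scaled to unit norm, then Euclidean
  k-means (k-means++, best of 20 restarts, ≤ 1000 iterations per run) —
  exactly correlation-distance k-means by the identity
  1 − corr = ‖ã − b̃‖²/2. Reported centroids are means of the raw member
  vectors (natural connectivity units). Empty clusters are re-seeded by the
  solver from the farthest points.
- **Elbow**: R(k) = mean within-cluster distance / mean distance between
  points in *different* clusters, the latter computed in closed form from
  centroids and within-cluster scatter. The selected k maximizes the
  discrete second difference of R; the selection is flagged low-confidence
  when that curvature is under 40% of the curve's total drop (a structureless
  Gaussian cloud scores ≈ 0.07). The between-*centroid* variant of the
  denominator was rejected because its curve decays convexly before the true
  state count and mislocates the elbow on well-separated clusters.
- **Transition estimation**: counts[i, j] = #{t: s(t) = j, s(t+1) = i},
  columns normalized by departures. States never departed from get a uniform
  1/k column (flagged) by default, keeping feature tables rectangular for
  classification; a "missing" policy exists for association use.
- **Partial correlation**: residualize both variables on
  [intercept, covariates] and correlate residuals; two-sided p from
  t = r√(df/(1 − r²)), df = n − q − 2; pairwise-complete handling of missing
  features. When the covariates fully explain one variable the partial
  correlation is reported as 0 (p = 1); when both residuals are degenerate
  the result is missing.
- **BH adjustment** within family only (per-state connectivity, occupancy,
  transitions are separate families), via the standard step-up procedure.
- **Despiking**: deviation from the running median of ±5 neighbors with the
  center sample excluded (an inclusive median usually equals the center
  exactly, collapsing the MAD to zero), antisymmetric boundary extension
  (preserves ramps at the series ends), threshold 4 robust SDs
  (1.4826 × MAD); zero-MAD columns treat any nonzero deviation as a spike.
- **Filtering**: 5th-order Butterworth applied forward–backward (zero phase,
  effective order 10). A 0.05 Hz sinusoid retains ≥ 95% amplitude, a
  0.22 Hz sinusoid ≤ 5% at TR 2.2 s. Detrending and nuisance regression are
  each idempotent projections; their *composition* is not (different
  subspaces), and the IIR filter is linear but not a projection, so the full
  chain is only approximately idempotent.
- **SVM kernel**: scikit-learn SVC with `kernel="poly", gamma=1, coef0=1`
  realizes (1 + x₁′x₂)^p exactly; features are standardized on the training
  set because dot-product kernels need comparable scales. The hyperparameter
  grid is degree p ∈ {2, 3} and C ∈ {0.01, 0.1, 1, 10}, selected by inner
  five-fold cross-validated accuracy.

## The evaluation protocol and its bias

The default conversion-classification protocol follows the published
procedure literally: per repeat, generate G ADASYN samples from the full
data, draw a random majority subset of size G, train on {majority subset +
synthetic minority}, select hyperparameters by inner five-fold CV on that
training set, and evaluate on every real sample excluded from training.
Synthetic samples never enter an evaluation set (asserted structurally).

That protocol is nonetheless **optimistically biased**: the synthetic
training points are convex interpolations of the same real minority points
later evaluated, so even label-independent data scores well above chance
(mean AUC ≈ 0.70 at 85/40 with 10 uninformative features). The package keeps
the literal protocol as the default for comparability and provides
`protocol="stratified_cv"` — conventional stratified k-fold with ADASYN
applied inside each training fold only — which is unbiased (shuffle-label
AUC ≈ 0.5) and is what the test suite uses for chance-level calibration.
Headline metrics from the literal protocol should be read with this bias in
mind.

## Problem sizes used in validation

Recovery and calibration experiments run at sizes chosen to make the checks
statistically decisive while staying desk-scale: state recovery on 60 scans
× 139 windows at C = 53 (elbow over k = 2..7 with 5 restarts per candidate,
final model with 20); transition validation on five 20000-step chains per
group (occupancy — a slow-mixing statistic with ≈ 0.012 SD per state per
chain at dwell 0.85 — is checked on the mean over chains); association
calibration on 200 null cohorts and 100 planted-effect cohorts of 150–200
subjects at the feature level (state sequences simulated directly, skipping
time-course synthesis, which changes nothing downstream of the feature
table); classifier checks at the 85/40 study scale.

## Known limitations

- Window-level state labels are only defined up to the window's majority
  regime; windows straddling a regime switch are intrinsically mixed, which
  bounds label accuracy below 100% even at zero noise.
- Occupancy features are compositional (they sum to 1), so a planted
  coupling on one state's occupancy induces opposite-signed associations on
  the others; the association table reports all of them, signed.
- The elbow's low-confidence flag is a heuristic calibrated on canonical
  separable/structureless cases, not a significance test.
- `evaluate_conversion` reports dispersion across repeats, but repeats share
  the same data — they quantify protocol randomness, not sampling error of
  the cohort.
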