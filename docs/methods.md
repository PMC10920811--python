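# Methods

`eegdecode` implements subject-independent decoding of a two-group trait
(group "M" vs "H") from multichannel EEG epochs, together with the
explainability and statistical machinery needed to say *where* in
sensor–frequency space the discriminating signal lives. This note
records the models, the defaults and why, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Signal model and feature spaces

All pipelines start from 2-s epochs sampled at 250 Hz, analyzed in seven
bands: theta1 4–6, theta2 6–8, alpha1 8–10, alpha2 10–12, beta1 12–16,
beta2 16–20, beta3 20–24 Hz (K = 7). Epochs are cut without overlap
starting 5 s after task onset, so early stimulus-driven activity is
excluded, and rejected when any channel's peak-to-peak amplitude leaves
`[ptp_min, ptp_max]` (defaults 1 µV and 150 µV; the mechanism is the
design constraint, the thresholds are data-dependent configuration).

**Covariance pipelines.** A zero-phase Butterworth band-pass bank
(order 4, forward–backward) decomposes each epoch; per epoch and band
the spatial covariance `S` is estimated over time and shrunk toward
scaled identity, `(1−γ)S + γ(tr S/N)I` with γ = 0.05, which preserves
the trace and guarantees positive definiteness at a few hundred samples
per epoch. The feature tensor is `X ∈ R^{K×N×N}`.

- *Supervised (CSP + log-variance)*: per band, filters `W ∈ R^{N×J}`
  solve `S̄₁ w = λ (S̄₁+S̄₂) w` on the class-mean covariances, keeping the
  J largest-λ eigenvectors with `wᵀ(S̄₁+S̄₂)w = 1`. Features are
  `log diag(Wᵀ S_i W) − log diag(Wᵀ S̄₁ W)` — log-variance referenced to
  the first class (group M; an arbitrary but fixed convention recorded in
  the fitted filters). The spec-level sorting rule is "largest
  eigenvalues"; the common both-ends variant can be obtained by passing
  a custom candidate set of filters but is not the default.
- *Riemannian (PCA + tangent space)*: per band, `W` holds the top-J
  eigenvectors of the pooled mean covariance (for equal-length,
  per-epoch-demeaned epochs this equals the covariance of concatenated
  data, so the two common formulations coincide). Projected covariances
  `Wᵀ S_i W` are mapped to the tangent space at their Karcher mean `G`
  under the affine-invariant metric:
  `F_i = Upper(logm(G^{-1/2} Wᵀ S_i W G^{-1/2}))`, with off-diagonal
  entries scaled by √2 so the Euclidean norm of `F_i` equals the
  Riemannian distance to `G` (the isometry convention; switchable).
  Feature count per band is J(J+1)/2.
- *Handcrafted (relative power)*: multitaper PSD per epoch and channel,
  integrated per band, divided by the summed power over the seven bands,
  so each channel's seven values partition to 1 exactly. The denominator
  choice makes the normalization testable; a full-spectrum denominator
  is available by passing explicit totals. Multitaper parameters are
  NW = 2 (1 Hz half-bandwidth on 2-s epochs) with the 2NW−1 = 3
  well-concentrated DPSS tapers: the smoothing window stays narrower
  than the 2-Hz analysis bands, which matters — a wider window measurably
  blurs band-specific effects into neighbours.

Per-band filters are fitted independently and features concatenated
across bands (K·J, K·J(J+1)/2 and N·K features respectively).

## Classification and validation

Folds are leave-subjects-out: each of the (default 10) folds holds out
one test subject per group and one validation subject per group; test
pairs are drawn without replacement while distinct pairs remain.
Everything that is fitted — CSP/PCA filters, Karcher means, classifier
weights — sees training subjects only; J (candidates 2/4/6) and
hyperparameters are chosen by validation balanced accuracy, ties going
to the smaller J and the stronger regularization. A leakage guard raises
if a test subject is ever seen during fitting.

The linear pipelines use L2 logistic regression with C searched over 20
log-spaced values in [1e−10, 1e9]. The tree pipeline uses LightGBM
(leaf-wise growth) over a deliberately small 2×2×2 grid
(learning rate × leaves × min-child-samples) with early stopping on
validation log-loss, single-threaded and seeded for bit-reproducibility;
the grid is scaled to desk-size problems and is a configuration, not a
constraint. Epochs are the unit of prediction (subject-level majority
votes are reported alongside); balanced accuracy is the headline metric
(chance 0.5 regardless of imbalance), AUC is reported with it, and
pipelines are compared fold-wise with the two-sided Wilcoxon signed-rank
test (identical fold vectors are reported as statistic 0, p = 1).

## Explainability

Backward-model filters are converted to forward-model activation
patterns `A = Σ_X W` (taking the extracted-source covariance as
identity, appropriate for uncorrelated components; the full scaling is a
flag). Patterns — not filters — are the topographies to interpret. A rank
report on the stacked multi-band filter confirms the concatenated
projection loses no identifiability.

For the tree ensemble, Shapley values are computed *exactly* under the
interventional convention: a coalition's value is the raw model output
with absent features drawn from an explicit background sample. For one
tree and one background row the game is a sum of per-leaf conjunction
games, whose Shapley values are closed-form in the counts of
"explained-only" and "background-only" path conditions; summing over
leaves, trees and background rows is exact with cost linear in leaves.
Local accuracy (base value + attributions = raw output) is asserted at
1e-6 for every explained epoch, and the implementation is tested against
brute-force coalition enumeration. Feature importance is the mean
absolute attribution, ties broken by name.

## Cluster statistics

Group comparison of band power uses a two-sided cluster-mass permutation
test on **subject-level** mean power — subjects, not epochs, are the
exchangeable unit; epoch-level permutation would be anti-conservative.
Supra-threshold |T| cells are clustered by spatial adjacency within each
band (positive/negative separately); adjacency connects channels within
1.3× the median nearest-neighbour distance (recovering the
4-neighbourhood on a regular grid). The null is the maximum absolute
cluster mass over subject relabellings (1024 by default, exhaustive when
the label space is smaller), and `p = (1+#{null ≥ obs})/(n+1)`, so p
never falls below its resolution. The headline cluster-forming threshold
is T = 6 — very strict for ~10 subjects per group, which makes the
default analysis conservative; calibration experiments use a
conventional |t| ≈ 2.1 threshold so clusters actually form and the
max-statistic calibration is exercised. The Spearman variant correlates
channel-mean band power with a behavioral score per band, with
permutation p-values and the Bonferroni per-band threshold α/K = 0.05/7
≈ 0.00714 reported alongside.

## Synthetic cohorts

The generator draws band-limited sources (order-4 Butterworth-filtered
Gaussian noise, the simplest stationary process matching the
covariance-based analysis), mixes them through a shared random mixing
matrix with unit-norm columns (optionally perturbed per subject), adds
white sensor noise, and plants the group difference as a multiplicative
ratio on chosen sources' variances with per-subject lognormal jitter.
Within each epoch sources are orthogonalized in generation order and
rescaled, so the empirical source covariance is exactly diagonal and the
noiseless sensor covariance equals `A diag(var) Aᵀ` to machine precision
— the anchor for the oracle tests. The cross-band leakage this projection
introduces is O(1/√T) in amplitude and negligible at 500 samples.

Reference conditions (chosen once as a plausible desk-scale cognitive
cohort): 10 subjects per group, 24 channels on a Fibonacci upper
hemisphere, 40 epochs per subject and task, 8 sources, sensor-noise SD
0.3 of source scale, subject jitter SD 0.2 on log source power, and a
2× alpha1 ratio as the planted effect. Cluster-recovery runs localize
the effect source on 6 adjacent channels; Monte-Carlo sweeps
(calibration, effect-size response) use a reduced 8-subject, 16-channel,
10–20-epoch cohort to keep hundreds of runs tractable.

What the synthetic benchmark shows: the pipelines recover a planted
band-specific variance effect across unseen subjects, respond
monotonically to its size, sit at chance when labels are exchangeable,
and localize it spatially. What it does not show: robustness to
non-stationarity, artifacts (ocular/muscle/mains — none are simulated;
an amplitude-based rejection hook exists), realistic volume conduction
(no head-model lead fields), or per-subject topography differences
beyond the optional mixing perturbation. Accuracies on these cohorts are
not predictions of accuracies on real recordings.

One behavior worth knowing: with *relative* power features, a planted
increase in one band mechanically depresses the other bands at the same
channels, so tree-model attributions concentrate on the right channels
but spread across bands there. Channel-level localization is the claim
the feature set identifies; band-level attribution sharing is expected,
not a defect.

## Numerical choices

- Matrix log/exp/sqrt by symmetric eigendecomposition with an eigenvalue
  floor of 1e-12 (relative) against numerically semidefinite inputs.
- Karcher mean: fixed-point iteration on the whitened log-mean,
  initialized at the arithmetic mean, tolerance 1e-8 on the gradient
  Frobenius norm, max 50 iterations, error (with the final gradient
  norm) on non-convergence; input order does not matter beyond
  tolerance.
- CSP via the generalized symmetric eigensolver; eigenvector sign is
  arbitrary and tests compare up to sign.
- Degenerate cases have defined behavior: zero-power channels get
  uniform 1/K relative power with a warning; nonpositive filtered
  variances are floored with a warning; all-epochs-rejected and
  single-class splits raise.
- Determinism: every stochastic step takes a seed; the pipeline derives
  per-stage seeds from one master seed by hashing the stage name, and
  LightGBM runs single-threaded deterministic. Identical configuration
  gives bit-identical cohorts, folds, models and reports.
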