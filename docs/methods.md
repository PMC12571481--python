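# Methods

This note documents the generative model behind the synthetic cohorts, the
analysis pipeline's estimators and conventions, the calibration of the
permutation inference, and the design choices that were genuinely open.

## The scientific setting

A feature-based attention experiment with two sessions. On each attention
trial a color cue indicates which of two grating orientations (leftward vs.
rightward of a reference) to attend; after a variable blank delay
(preparation period) two superimposed gratings appear and the cued
component must be discriminated (stimulus selection period). In the Ping
session a task-irrelevant high-contrast visual impulse is flashed during
the delay. A separate perception task shows single gratings of the same
orientations. The analyses ask in what format the preparatory attentional
template is encoded: a classifier trained on perception-task patterns
generalizes to the preparation period only if the template is sensory-like.
The working model is dual-format: a non-sensory template carries
preparation by default, and a latent sensory-like template exists that the
impulse can reactivate in early visual cortex.

## Generative model (`attnping.synthgen`)

Each ROI `r` of a simulated brain has a mean pattern `mu_r`, a unit
*sensory axis* `s_r` and a unit *attention axis* `a_r`, drawn orthonormal
and both orthogonal to the all-ones voxel vector. Voxel noise is
`Sigma_r = diag(v) + W W'` with heterogeneous variances
`v ~ U(0.5, 1.5)` and `k = 3` shared components of norm 0.5 — a
diagonal-plus-low-rank family under which Mahalanobis distance genuinely
differs from Euclidean distance, so covariance handling is exercised by
every test.

Per attention trial `t` with orientation sign `o ∈ {+1, −1}`
(leftward = +1):

```
preparation: x = mu + eta_t * o * beta_att * a
                 + [Ping] * lambda_r * p_s * rho_t * o * beta_sens * s + eps
selection:   x = mu + eta_t * o * beta_att * a
                 + o * (gamma_T - gamma_D) * beta_sens * s + eps
perception:  x = mu + o * beta_sens * s + eps,     eps ~ N(0, Sigma_r)
```

* `eta_t = 1 + g z_t + xi_{t,r}` is a trial gain whose component `z_t` is
  shared across ROIs; `g` is the coupling that informational connectivity
  must recover. `xi` is ROI-private (SD 0.15).
* `lambda_r ∈ [0, 1]` is the ping reactivation gain — nonzero only in the
  V1 and EVC analogs by default (0.6), zero in IPS/PFC. The ping is a gain
  on the *pre-existing* sensory axis, not a new axis: the latent template
  is a reactivated sensory representation, and with `lambda = 0` the
  preparation-period generalization null is *exactly* true because
  `a ⟂ s`.
* `p_s` is a subject-level reactivation propensity (`N(1, 0.25)`, clipped
  at 0.2) and `rho_t` a trial-level reactivation jitter (`N(1, 0.5)`,
  clipped at 0); they carry the between- and within-subject AMI–behavior
  couplings.
* Reaction times: `RT = rt0 − b_rt (p_s − 1) − [Ping] * slope (rho_t − 1)
  + noise` with `rt0 = 0.9 s`, `b_rt = 0.3 s`, `slope = 0.25 s`,
  noise SD 0.15 s. Stronger reactivation ⇒ faster responses, between and
  within subjects.
* Correctness is Bernoulli with a subject-level accuracy (mean 0.75,
  SD 0.05) — a near-threshold task — so the behavioral filtering path is
  always exercised. Short delays (20% of trials: 1.5/3.5 s; long: 5.5/7.5
  s at 40% each) are generated and later excluded, again to exercise the
  real filtering rules.

Default design: 2 sessions × 20 subjects (14 completing both, reusing
their brain and subject parameters), 4 ROIs × 100 voxels, 6 attention runs
× 40 trials, 3 perception runs × 40 trials, TR 2 s. The expected retained
count is 240 × 0.8 (long) × 0.75 (correct) / 2 ≈ 72 trials per attention
condition, the count the analyses are designed around. All effect
amplitudes are expressed in units of per-voxel noise SD (≈1 after
z-normalization). Because single-trial pattern SNR cannot be pinned
down from group-level statistics alone, the defaults (`beta_sens = beta_att = 1.0`,
`gamma_T − gamma_D = 0.7`, `lambda = 0.6`) were calibrated once so that
cross-validated decoding lands in the 0.6–0.75 range typical of visual
fMRI MVPA, and then frozen.

Seed handling: one master seed; per-subject/per-ROI/per-purpose child
seeds derive deterministically from it (`numpy` `SeedSequence` keys).
Identical `(config, seed)` reproduce bit-identical datasets and files
(HDF5 written with `track_times=False`).

### Time-series mode

`emit_timeseries` renders trials into per-run voxel time series: every
event adds `amplitude × HRF(t − onset)` (canonical double-gamma, unit
peak), on a flat baseline of 100 with i.i.d. Gaussian sampling noise, so
one amplitude unit is one percent signal change. Stimulus onsets also add
a spatially uniform evoked component (0.5) so ROI-mean time courses carry
realistic task-locked structure. The trial-pattern covariance `Sigma_r` is
*not* embedded in the time series — this mode exists to test window
extraction and the mean-BOLD control, not to duplicate the pattern
generator. Because the signal axes are orthogonal to the uniform voxel
direction, pattern-gain fluctuations (including `g`) cannot move ROI-mean
BOLD at all: the dissociation between informational and mean-signal
connectivity is true by construction, which is exactly the null the
control analysis is supposed to confirm.

Not modeled: physiological noise, motion, retinotopic spatial structure,
eye position, autocorrelated scanner noise. Passing tests therefore show
that the estimators recover these effects under idealized noise; they do
not certify robustness to structured artifacts in real data.

## Pattern pipeline (`attnping.patterns`)

* Per run: linear detrend, discrete-cosine high-pass regression with
  cutoff 0.01 Hz (basis functions with frequency `k / (2 N TR)` below the
  cutoff), then percent signal change `100 · x / mean_raw`. DCT regression
  was chosen because it is deterministic and exactly reproducible by an
  explicit projector matrix, which the tests exploit.
* Window extraction averages samples whose acquisition onset lies in
  `[onset + 4 s, onset + 6 s)` (half-open, sample-onset timing). With
  TR = 2 s this selects exactly one volume. A 2-s averaging window at
  TR = 2 s can contain one or two volumes depending on how sample timing
  is referenced; the half-open sample-onset convention used here is a
  documented choice and is configurable.
* Filtering: runs with accuracy < 50% (computed over the whole run,
  before trial-level exclusion) are dropped whole; then attention trials
  are kept only if long-delay and correct, perception trials if correct.
  Filtering is idempotent.
* z-normalization: per voxel across all trials of a task/period group,
  pooling both orientation conditions (so condition differences survive),
  population-SD convention (divide by n). The two-trial toy `(1, 3)`
  normalizes to `(−1, +1)` under this convention.
* Distances and decoders operate on z-normalized patterns by default
  (consistent with normalized responses feeding all multivariate
  analyses); raw patterns can be passed where needed.

## Decoding (`attnping.decode`)

Fisher linear discriminant: `w ∝ Σ̂⁻¹ (μ̂₁ − μ̂₂)` with pooled
within-class covariance `S = (scatter₁ + scatter₂)/(n − 2)` and shrinkage
`Σ̂ = (1 − α) S + α (tr S / V) I`, default `α = 0.1`. With 100 voxels and
~120 training trials raw inversion is fragile; the discriminant itself
does not dictate a regularizer, so the shrinkage intensity is exposed and
the exact formula is pinned by closed-form oracle tests. Bias places the
boundary midway between projected class means (the designs are balanced);
decision-value ties go deterministically to the first class in label
order. Leave-one-run-out cross-validation reports per-fold and
trial-weighted pooled accuracy. Cross-task generalization fits once on all
perception trials (no cross-validation — training and test come from
different tasks) and scores attention trials of the requested period.

For permutation nulls the FLD is refit thousands of times with only the
labels changing. `BatchFLDSolver` exploits the identity
`pooled scatter = total scatter − (n₁n₂/n) d d'` to reduce each refit to a
diagonal-plus-rank-one solve after one eigendecomposition per fold
(Sherman–Morrison), which is exactly equal to naive refitting (asserted to
1e-9 in the tests) at ~O(V²) per permutation instead of O(V³).

## Geometry (`attnping.geometry`)

Mahalanobis distance of each attention trial to the distribution of each
perceived orientation, with the covariance pooled over the two perception
conditions (each centered on its own mean) and shrunk with the same `α` as
the decoder — the distance definition leaves the covariance estimator
open; pooling over the reference conditions matches the FLD convention. Cell means give the 2×2 attended ×
perceived table; `D_same`/`D_different` average matched/mismatched pairs
and `AMI = (D_different − D_same)/(D_different + D_same)`, undefined (an
error, not a silent 0) when both distances vanish. Trial-wise AMI uses the
same references per single trial; the cross-validated variant for
connectivity estimates the references and covariance from the other runs
only. The stimulus-selection-period analysis reuses `distance_table` with
`period="selection"`. Trial sorting takes the top/bottom `⌊qN⌋` trials by
AMI (descending, stable sort), default q = 0.25.

## Connectivity (`attnping.connectivity`)

Per ROI, the leave-one-run-out trial-wise AMI series (acquisition order:
trials concatenated across runs, then correlated — correlating per run and
averaging would be a near-equivalent alternative)
is Pearson-correlated between ROI pairs and Fisher z-transformed with |r|
clipped to 1 − 1e−6 so self- and degenerate correlations stay finite.
Trials are aligned across ROIs by (run, trial index) identifiers, so
filtered trials drop consistently everywhere. The control analysis
correlates run-concatenated ROI-mean time courses the same way.

## Inference (`attnping.inference`)

Per subject, training labels are shuffled *within run* (preserving per-run
class balance and avoiding degenerate folds), the decoder refit, and accuracy computed on
the unshuffled test assignments; `n_perm` defaults to 200 in the scaled
pipeline configuration (1000 in the reference-design setting). Group level:
element-wise mean of subject nulls; the observed group-mean accuracy is
significant when it exceeds the null's 95th percentile, and the add-one
p-value `(1 + #{null ≥ obs})/(1 + n_perm)` is reported alongside.
Bonferroni (`min(1, p·m)`, m = number of ROIs) covers multi-region
comparisons.

### Calibration of the permutation scheme

A property worth knowing when using this test: shuffling *only the
training labels* is exactly exchangeable with the observed statistic for
the single-fit cross-task scheme — measured type-I of the group-level rule
is 4.5–5.8% over 600 signal-free experiments, matching the 5.45% analytic
rate of the interpolated-95th-percentile rule at `n_perm = 200`. For
leave-one-run-out accuracy, however, the observed statistic reuses one
coherent labeling across folds and is over-dispersed relative to the
train-shuffle null: measured group-level type-I grows from ~7% (4 runs ×
12 trials) to ~12% (6 runs × 40 trials). `permutation_null(...,
shuffle_test=True)` provides a full-relabeling LORO null that restores
exchangeability (measured 5.7%). The default remains the conventional
train-only shuffle; for LORO decoding of strong effects the
anti-conservativeness is immaterial, but null claims based on LORO
permutation p-values should use the full-relabeling option. The pipeline's
calibration experiment (`experiments.permutation_calibration`) therefore
evaluates the cross-task test, whose null is the scientifically relevant
one (no preparation-period signal: `beta_att = 0`, `lambda = 0`).

Session contrasts (Ping vs. No-Ping) are exported as per-subject tidy
tables for standard ANOVA tooling; the pipeline itself offers only a
two-sample mean difference with an optional permutation p-value.

## Validation experiments (`attnping.experiments`)

Problem sizes were chosen to run the whole battery in minutes on one CPU:

* calibration: 500 experiments × 6 subjects × 200 permutations on a
  1-ROI/16-voxel design (calibration is a property of the test statistic,
  not of the design size); signal-free cohorts use accuracy 0.85 so the
  behavioral run-exclusion rule does not empty the small runs.
* dual-format recovery: 20 full reference-design cohorts (2 × 20 subjects,
  4 ROIs × 100 voxels, ~72 trials/condition) scored against the expected
  Bonferroni-corrected significance pattern. With six true-null cells per
  cohort the expected false-positive failure rate is ~6% per cohort, so
  the target recovery rate of ≥ 90% over 20 cohorts leaves the intended
  margin.
* geometry: 20 single-subject replicates with and without the latent gain.
* connectivity: g ∈ {0, 0.3, 0.6} × 10 cohorts × 10 subjects on a
  two-ROI design, with the mean-BOLD control computed from emitted
  attention-run time series of the same subjects.
* behavior: 10 cohorts × 20 Ping-arm subjects with and without the RT
  couplings.

## Known limitations

* Gaussian, temporally white noise; no hemodynamic nonlinearity; the
  time-series mode omits the trial-pattern covariance structure.
* The conventional train-only-shuffle LORO permutation null is
  anti-conservative (quantified above).
* Voxel selection from larger ROI masks is not modeled: synthetic ROIs are
  generated at exactly the analyzed voxel count, and real-data voxel
  selection is deliberately not implemented.
* Omnibus mixed ANOVAs and Bayes factors are out of scope; the pipeline
  emits the per-subject tables those consume.
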