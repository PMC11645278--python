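# Methods

## O-information connectivity

For a subject's T×R signal matrix, each column is rank-transformed to a
standard-normal margin, Φ⁻¹(rank/(T+1)) with average ranks for ties (the
+1 denominator keeps the quantiles finite). Differential entropies are the
closed-form Gaussian entropies of the sample covariance of the transformed
data, H = ½·ln((2πe)ᵏ det Σ), in nats. The connectivity entry (i, j) is the
three-block O-information of ({i}, {j}, all remaining regions): positive
where the triplet is redundancy-dominated, negative where synergy
dominates, zero under independence. Because only ranks enter, the matrix is
exactly invariant to strictly monotone per-region transforms.

Numerical choices: covariances are regularized with 1e−8·I before the
Cholesky log-determinant; single-variable and leave-one-out entropies are
computed once per subject and reused across pairs, while the pair terms
H(i, j) and H(rest) are evaluated per pair directly (at 82 regions a full
matrix costs ≈ 0.4 s, so no down-dating tricks are needed; the test suite
checks exact agreement with a naive sub-determinant oracle). Entropy log
base only rescales Ω and is removed by normalization. No small-sample bias
correction is applied; tests use T large enough (≥ 300 per subject,
20,000–50,000 for estimator checks) that the bias is immaterial.

Normalization to [−1, 1] divides each subject's matrix by its maximum
absolute off-diagonal entry. This is one of several maps that realize a
[−1, 1] range; it preserves signs and within-subject structure and is
idempotent. It is a documented package choice.

## Synthetic cohort generator

Each subject has an *effective age* a_eff = age + δ(region group) +
δ(diagnosis) + δ(sex×region×diagnosis). Defaults: δ_LAC = 5, δ_MCI = 3,
δ_AD = 8, δ_bvFTD = 6, δ_F×LAC×AD = 2 years — signs and ordering mirror
the reported brain-age-gap gradients (controls < MCI < dementia; LAC above
non-LAC by about five years). Ages are uniform on [40, 90] by default.

Signals follow a latent-factor model chosen so redundancy and synergy can
be dialed independently (the O-information responds to both):

* all regions load weakly (0.2) on a shared factor g ~ N(0, 1);
* *hub* regions (first ⌈R/4⌉ by default) load with λ(a_eff) = 1.0 +
  0.02·(a_eff − 65), so hub redundancy grows with effective age;
* each *synergy triplet* (i, j, k) rewrites x_k = w(a_eff)·(x_i + x_j) +
  residual, w(a_eff) = 0.5 + 0.01·(a_eff − 65);
* unit-SD region noise, an additive per-scanner site offset, and (for
  fMRI-like data) a baseline level of 200 giving realistic tSNR;
* EEG-like series are low-pass filtered (4th-order Butterworth, 12 Hz,
  forward–backward) with the same filter on every channel, which preserves
  the zero-lag correlation structure the Ω estimator reads.

The slope values were chosen once so that hub-pair Ω roughly doubles to
triples across the adult age range — a strong but not degenerate signal;
with both slopes at zero the Ω matrices are statistically independent of
age (tested). Every draw is a pure function of (config.seed, subject id)
via a CRC-based per-subject stream.

What the generator does *not* emulate: hemodynamics or neural-mass
dynamics, spatial geometry of the parcellation, realistic frequency
content beyond the single low-pass, age-varying noise levels, missing
data, or scanner differences beyond additive offsets. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it assumes — not that it would achieve comparable accuracy on clinical
recordings.

Artifact injection replaces a stated fraction of fixed-length segments
(20 samples for fMRI-like, one second for EEG-like) with either transient
spikes of ten series-SDs or near-constant signal, and records which
segments were corrupted so quality metrics can be validated against ground
truth.

## Graph pipeline and augmentation

Node features are the rows of the normalized Ω matrix; the same matrix is
the weighted adjacency. Samples with any non-finite feature or target are
filtered out with a log entry. The hold-out split is stratified on five
equal-width age bins (bin count is a package default; with too few samples
per bin the split falls back to unstratified with a warning), test
fraction 0.20, and 5-fold stratified cross-validation folds partition the
training ids.

Augmentation linearly interpolates connectivity matrices of age-adjacent
training subjects within each stratum: subjects are sorted by age, an
adjacent pair is drawn with replacement, and the target age is uniform
strictly between the parents' ages, M_t = (1−α)M₁ + αM₂ with
α = (a_t−a₁)/(a₂−a₁). The default 500 augmented samples are split equally
across the two region strata. Augmented samples are flagged, carry their
parent ids, and are only ever added to training folds and the final
retraining set — never to validation or test data (augmenting evaluation
data would corrupt it).

## GCN brain-age regressor

Â = D̃^{−1/2}(A + I)D̃^{−1/2} with D̃ᵢᵢ = Σⱼ|Aᵢⱼ| + 1: absolute-value
degrees keep the normalization well defined for signed Ω weights, and the
unit self-loop bounds degrees away from zero. The network is
H₁ = ReLU(Â X W₀ + b₀), dropout (rate 0.5) on H₁ during training,
H₂ = Â H₁ W₁ + b₁ with one output channel per node, prediction = mean over
nodes. Hidden width 64, Glorot-uniform initialization, full-batch Adam
(β = 0.9/0.999) on MSE. The implementation is direct NumPy with
hand-written gradients — the model is small enough that this is exact,
fast, and bit-reproducible from the seed; the forward pass is verified
against an independent per-sample dense implementation.

Grid search covers learning rates × epoch counts (package default
{1e−2, 1e−3, 1e−4} × {100, 200, 400}); for each learning rate one seeded
trajectory is trained to the largest epoch count and snapshotted at each
grid epoch, which is identical to training each cell separately with the
same seed. The cell with minimum mean validation MSE wins, ties broken
toward smaller learning rate then fewer epochs; the final model is
retrained on the full training portion. Single-channel output followed by
mean pooling was chosen over pool-then-linear readout for parsimony; both
realize "average pooling" readouts.

## Evaluation statistics

* Brain-age gap and MDE are predicted − chronological, so positive values
  mean systematic overprediction ("older" brains). r.m.s.e. ≥ |MDE| always.
* Cohen's f² = R²/(1−R²); OLS fit metrics come from statsmodels.
* Subsample permutation test: the observed statistic is the full-group
  mean difference. The null distribution subsamples the larger group to
  the smaller's size at each iteration, then permutes labels within the
  subsample; p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + iterations), so p is
  never zero. Recomputing the observed statistic per subsample iteration
  was rejected: the two draws would be exchangeable under the null and the
  p-value would concentrate near 0.5 instead of being uniform. With equal
  group sizes the procedure reduces to the standard permutation test and
  its type-I error is calibrated (checked at α = 0.05 over 500 null
  replicates). With unequal sizes the subsampled null is slightly
  over-dispersed, making the test mildly conservative.
* Chi-square tests are Pearson's, with Yates continuity correction applied
  to 2×2 tables by default (flag-exposed): the published 2×2 sex statistic
  is only reproduced with the correction (64.62 corrected vs 65.48 raw).
* One-way ANOVA reports ηp² = SS_between/(SS_between + SS_within).
* Covariate adjustment regresses gaps on age/education with an intercept
  and returns residuals plus the grand mean.

## Importance

Node ablation zeroes a node's feature row and its adjacency row/column;
edge ablation zeroes one symmetric entry; the score is the absolute
prediction change. Masking, rather than graph shrinkage, keeps the input
dimension fixed. Per-sample deltas are computed once; each bootstrap
replicate then resamples test subjects with replacement, averages, and
divides by the replicate's maximum score, so the across-replicate mean of
the top feature sits at or just below 1. Reports give means, percentile
99% CIs, and descending ranks for nodes and the top-k edges.

A caveat found during validation: with mean pooling, masking *any* node
shifts the prediction by a baseline amount unrelated to its information
content, so node deltas of uninformative nodes are noise around that
baseline rather than near zero. Node and summed-edge ablation reliably
agree on *which* node is informative, but their rank correlation across
uninformative nodes is not meaningful; the consistency test asserts
agreement on the top node only.

## Exposome models

Country-level indicators (Gini, PM2.5, communicable and noncommunicable
burdens, or GII) are joined to subjects by country and combined with
binary diagnosis/sex/region codes; outcomes are brain-age gaps. The
protocol is 10-fold CV on a 90/10 split, repeated 10 times (both counts
configurable), with gradient-boosted trees (scikit-learn; 300 trees,
depth 3, learning rate 0.05 by default; an optional exhaustive grid over
these hyperparameters is evaluated on an inner training split only).
Per fold, three importances are computed: permutation importance (10
shuffles), impurity (MDI) share, and mean |Shapley| attribution. Shapley
values use exact coalition enumeration against a background sample of the
training fold (≤ 12 predictors; exact with respect to the empirical
background distribution — additivity is asserted in tests; per-fold the
explained rows are capped at 30 and the background at 64 for speed).
A predictor is significant only when the lower percentile-99% CI bound of
its importance, across all repeats×folds, exceeds zero under *all three*
methods. Missing indicator values are refused rather than imputed.

## Quality and harmonization

fMRI ODQ: non-overlapping 20-sample segments; a segment is good when the
median across regions of (segment mean / segment SD) exceeds 50, the
across-region coefficient of variation of tSNR is below 0.5, and no sample
deviates from the segment median by more than 5 per-region robust SDs.
The robust SD is a whole-series MAD estimate, so a spike cannot inflate
the local scale and mask itself; the thresholds (CV < 0.5, |z| > 5) are
package parameters. EEG ODQ: 1-second segments with four rules — flat
(channel SD below 1e−3 of the recording's median channel SD), artifact
(99th-percentile/median absolute amplitude above 10), noisy (more than
half the spectral power above 30 Hz), decorrelated (mean absolute
inter-channel correlation below 0.05). ODQ is the percentage of good
segments, 0–100.

Harmonization divides positive gaps by the scanner's maximum positive gap
and negative gaps by |minimum|, a sign-preserving two-sided min–max map to
[−1, 1]: zero stays zero, ranks are untouched, and group-difference signs
survive. Plain min–max was rejected because shifting zero destroys the
interpretation of positive vs negative gaps. Scanners with fewer than two
subjects or no spread raise an explicit error.

## Pipeline defaults and study sizes

The demo pipeline runs 120 subjects × 15 regions × 300 time points with a
reduced grid — small enough to execute in seconds while exercising every
stage. The replication studies report: estimator convergence at R = 5,
T = 50,000; sign checks at T = 20,000; permutation calibration over 500
null replicates (n = 50 per group, 1,000 iterations); age recovery and
bias transfer at R = 20, n = 400 (and 250 + 120) with 400 time points,
500 (250) augmented samples and a {1e−2} × {200, 400} grid; importance
recovery over 20 runs of 120 8-region graphs with 1,000 bootstrap
replicates; exposome recovery over 20 runs of n = 300 with 2×10-fold CV.
These sizes are the package's reference conditions, chosen to estimate
each rate with adequate precision on a single CPU.

## Known limitations

* The effective-age construction is additive; real diagnosis and region
  effects on connectivity are unlikely to be additive in years.
* The bias-transfer MDE underestimates the injected 5-year offset by the
  model's regression-dilution slope (observed MDE ≈ 1.5–4.5 years for a
  5-year offset), which is a property of any imperfect age regressor.
* Per-subject max-absolute Ω normalization discards the overall
  interaction magnitude; models learn only relative patterns.
* The GCN is full-batch and CPU-bound; cohorts beyond ~10⁴ subjects or
  ~200 regions would need mini-batching and a compiled backend.
* Exposome indicators enter as country-level constants; no within-country
  variation or multilevel structure is modelled.
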