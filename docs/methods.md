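# Methods

This note documents the models and procedures `strsa` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Experimental design model

The design generator reproduces a one-back block design: each block
presents every condition once in a shuffled order; a catch *event*
inserts two extra presentations of a randomly chosen condition
immediately after that condition's scheduled trial, so the one-back
repeat the participant must detect is present by construction and each
catch event adds exactly 2 trials. With the default parameters
(75 conditions, 39 of them social; 15 blocks; 4 catch events per block)
this yields 83 trials per block and 1245 in total. Catch trials are
flagged and excluded from every analysis, mirroring the treatment of
motor-response trials in real recordings.

## Synthetic EEG

The generator is geometry-level, not biophysical: no dipoles, forward
model, or volume conduction. A latent feature is a target RDM, an onset
latency (ms), and an SNR. The RDM is embedded as a point per condition
by classical (Torgerson) multidimensional scaling — double-center the
squared dissimilarities, eigendecompose, keep the top `dim` components
with nonnegative eigenvalues — normalized to unit RMS spread, rotated
into channel space by a seed-fixed random orthonormal basis, and scaled
by `snr × noise_sd`. Before the onset all condition means are
identical (nothing is decodable); the geometry ramps in linearly over
one analysis window (10 ms) to avoid step discontinuities interacting
with filtering in downstream contracts.

Noise is additive Gaussian with exponentially decaying channel
covariance `exp(−|i−j|/scale)` (default scale 5 channels) and AR(1)
temporal dependence (default coefficient 0.3, marginal SD 1 µV-scale
unit). The spatial correlation makes multivariate noise normalization
genuinely useful rather than a no-op; the AR structure gives window
statistics realistic autocorrelation. Everything derives from one
master seed via `SeedSequence.spawn`, so epoch sets are byte-identical
across runs.

What passing tests on this generator show: the pipeline's bookkeeping,
statistics, and recovery behaviour are correct when the generative
assumptions hold (stationary noise, sustained post-onset geometry,
label-independent artifacts). What they do not show: robustness to
real-EEG phenomena such as eye/muscle artifacts correlated with
conditions, drift, electrode pops, inter-subject latency jitter, or
non-stationary representational geometry.

## Preprocessing

Epochs are cut around trigger onsets corrected by per-event photodiode
offsets (display lag), covering −200…+1000 ms by default; the
per-channel mean over the prestimulus interval is subtracted. All
filters are 4th-order Butterworth applied forward-backward (zero
phase); the stated cutoffs (0.1 Hz high-pass, 100 Hz low-pass,
110–140 Hz artifact band) are treated as contracts tested by
attenuation, not by coefficient values. Muscle-artifact flagging
band-passes to 110–140 Hz, takes the Hilbert envelope magnitude,
z-scores per channel across the pooled trials × timepoints population,
and flags any trial containing a point above z = 15; whole trials are
flagged, never interpolated. Note the z-rule presumes artifacts are
rare relative to the pooled population — a burst occupying a large
fraction of a short recording inflates the pooled SD and can evade the
threshold. Median re-referencing subtracts the across-channel median
per sample (making the result invariant to any common offset), then a
100-Hz low-pass precedes integer-factor decimation (1000 → 500 Hz).
Manual channel/trial rejection and ICA-based eye-artifact removal are
interactive by nature and are only *consumed* here, as externally
supplied masks on `EpochSet`.

The order "baseline, then high-pass on epoched data" follows the
described acquisition chain; filtering epoched (rather than continuous)
data has edge effects, which is one reason the high-pass is optional in
`epoch_and_baseline`.

## ERP analysis

Condition ERPs are trial means; grand averages are unweighted subject
means restricted to channels present for every subject. The contrast
averages amplitudes into successive 100-ms slices, runs a paired t test
across subjects per channel × slice, and Bonferroni-corrects — over
channels × slices by default (the stricter reading; correction over
channels only is available). The displayed map is the t matrix z-scored
across all its cells; the z-scoring population is a display convention
(configurable), inference always uses the raw paired-t p values.

## Decoding

Fold splitting happens on source trials, stratified by condition,
*before* pseudo-trial averaging, so no source trial can leak across
folds through a shared pseudo-trial. The pseudo-trial group size
targets 6–8; with N trials per condition and 2 folds it resolves to
`min(8, N//2)` (15 trials → 7) and degrades with a log entry, never
silently, below 6.

Multivariate noise normalization estimates the within-condition
residual channel covariance of the *training-fold source trials*
(condition means removed per timepoint, covariance averaged over
timepoints), shrinks it toward its diagonal (default shrinkage 0.1),
and applies the inverse matrix square root to both folds. Source
trials, not pseudo-trials, feed the estimate because in the standard
regime each condition reduces to a single pseudo-trial per fold and
pseudo-trial residuals vanish.

The classifier is the libsvm linear SVM (scikit-learn `SVC`, C = 1, a
fixed regularization since none is stated for this class of analysis);
features are all channels at the samples of a 10-ms window, advancing
in 4-ms steps (6-ms overlap; at 500 Hz, 5 samples per window, 2-sample
step, timestamps at window centers). Single-sample native-resolution
windows are available via `window_ms=None`. When each class contributes
exactly one training pseudo-trial the soft-margin linear SVM boundary
is, by symmetry, the perpendicular bisector of the two training points
for every C > 0, so predictions coincide with the nearest-template
rule; `pairwise_decode` uses that closed form as a vectorized fast path
(the equivalence is unit-tested against `SVC` directly) and falls back
to libsvm otherwise. Accuracies are averaged over both fold roles and
over repetitions (default 10) with fresh random splits each repetition.

## RSA and fusion

Spearman correlation (average ranks for ties) between identically
vectorized upper triangles links neural to model RDMs per window;
constant vectors yield flagged NaN windows rather than errors. The
multiple-regression variant regresses the rank-transformed, z-scored
neural vector on all predictor vectors jointly, so a single-predictor
regression reduces exactly to the Spearman analysis; raw-value
regression is available by flag. The noise ceiling is the mean over
subjects of each subject's correlation with the leave-one-out group
mean RDM. fMRI ROI RDMs enter as 1 − Pearson correlation between
multivoxel patterns and are consumed as inputs; no fMRI preprocessing
or voxel selection happens here.

Onset latency defaults to the first window of the earliest significant
cluster. A `largest_cluster` read-off (first window of the significant
cluster with the greatest mass) exists because, when a dominant effect
is present, the earliest-cluster rule is fragile to isolated spurious
pre-onset clusters; the recovery studies use it. The Mann–Whitney U
comparison of latency samples uses the exact distribution for small
tieless samples and the normal approximation otherwise. Because the
sampling unit of such latency comparisons is a genuinely open choice,
`latency_difference_test` accepts any latency samples (per-subject
onsets or bootstrap replicates) without presuming one.

## Variance partitioning

All variables are standardized; R² is unadjusted ordinary least squares
(the decomposition identity requires unadjusted values). For three
predictors the seven subset fits give unique variances
`UV_i = R²_full − R²_without_i` and shared variances via the standard
commonality expansion (`SV₁₂ = R²₁₃ + R²₂₃ − R²₃ − R²₁₂₃` and
cyclically; `SV₁₂₃` as the inclusion–exclusion remainder). The
implementation checks nothing against these formulas at runtime, but
the test suite verifies symbolically generated random cases: the seven
components always sum to `R²₁₂₃` at machine precision, and R² is
monotone under subset inclusion. Negative shared components
(suppression) are legitimate; they are flagged, reported, and never
clipped. Two-predictor decomposition is supported with the analogous
three-subset formulas.

## Group statistics

The sign permutation test flips each subject's entire timecourse with
probability ½ per iteration (preserving within-subject
autocorrelation), always includes the identity as iteration 0 (so no
corrected p is ever exactly zero), and records each iteration's maximum
suprathreshold cluster sum. Two cluster-forming rules are provided,
since the primary threshold is a free parameter of this family of
tests:

* **percentile** (default): the statistic is the group mean and the
  threshold is the per-window (1 − p) quantile of its own sign-flip
  null. Fully nonparametric. Caveat: with a strong effect in the data
  the adaptive threshold absorbs it, deflating the max-cluster null, so
  small spurious clusters elsewhere can reach significance.
* **t**: the statistic is the one-sample t value and the threshold the
  parametric Student-t critical value (as in the common neuroimaging
  implementations). More robust for onset read-off when large effects
  coexist with noise.

Both modes control the family-wise error rate under the sign-symmetric
null; the suite measures ≈0.046 (percentile) and ≈0.053 (t) over
hundreds of simulated null group datasets against the nominal 0.05.

## Validation studies and problem sizes

`strsa.pipeline` packages the simulation studies the tests and the
acceptance script run. Sizes are desk-scale choices balancing power
against single-CPU runtime:

* **FWER**: 500 null datasets × 12 subjects × 100 windows, 1000
  permutations each.
* **Chance calibration**: 20 conditions × 10 channels, no injected
  geometry; grand-mean pairwise accuracy against the 95% binomial
  interval computed conservatively from pairs × folds × repetitions.
* **Onset recovery**: per seed, one dataset per injected onset
  (90/150/190 ms), 8 subjects, 16 conditions, 12 blocks, SNR 0.7,
  10 decoding repetitions, t-mode clustering; success = estimate within
  one 4-ms window step. Onsets are injected one per dataset because
  co-injected geometries saturate pairwise accuracy after the first
  onset (a ceiling of the decoder, not of onset estimation): once every
  pair decodes perfectly the RDM is constant and rank correlation is
  undefined.
* **VP recovery**: 20 seeds × 20 windows; three ROI RDMs mixed from one
  shared and three unique latent components, target loading on the
  unique components with coefficients 0.9/0.6/0.3 in the signal
  windows; success = recovered UV rank order matches.

The SNR of 0.7 deserves a note: pairwise decoding is *easy* at desk
scale (few channels, whitened noise, pseudo-trial averaging), so large
SNRs pin all accuracies at 1.0 and destroy the rank information RSA
needs, while very small SNRs delay statistical onset detection past the
one-window tolerance. 0.7 with 16 conditions and 8 subjects keeps most
pairs off the ceiling during the ramp, which is the regime where both
the onset and the geometry are recoverable.

## Known limitations

* Geometry-level simulation only; none of the spatial realism of
  forward-modelled EEG, and no eye/blink artifact model.
* The muscle-artifact z-rule assumes artifacts are rare in the pooled
  population (see above).
* Cluster-level inference grants no window-level localization
  guarantees; onset estimates inherit a detection delay that shrinks
  with power but is never exactly zero, and the percentile threshold
  mode weakens under strong signal (use t mode for onset work).
* Commonality components are estimates on rank-transformed data;
  their sampling variability is not propagated (no per-window
  confidence intervals).
* `vectorize_rdm`/RSA assume identical condition ordering across all
  RDMs; the containers carry condition ids but cross-RDM reordering is
  the caller's responsibility.
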