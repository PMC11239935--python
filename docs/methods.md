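# Methods

## Model

The object of study is a binary collection of multivariate time series
in which the two classes differ in the *heterogeneity of inter-channel
correlation* and in how that heterogeneity evolves. The pipeline has
four stages: multiscale coarse-graining, windowed eigen-entropy,
signature construction, and a repeated-split classification protocol.

### Correlation-magnitude matrix and eigen-entropy

Each window is standardized per channel with the population convention
(divisor n). The correlation-magnitude matrix C\* is the Gram matrix of
the *absolute* standardized deviations divided by n. Its diagonal is
exactly 1 (the mean squared standardized deviation), it is symmetric
PSD with trace m, and it treats correlation and anti-correlation
identically. Eigen-entropy is the Shannon entropy of λ_i/m.

Two consequences worth keeping in mind when interpreting EE values:

- **The independent-channel limit is not log m.** For mutually
  independent Gaussian channels the off-diagonals of C\* converge to
  E|z_j|·E|z_k| = 2/π ≈ 0.637, not 0, because absolute deviations are
  positive quantities. EE of long independent Gaussian windows
  therefore converges to the entropy of the (2/π)-equicorrelated
  matrix (≈ 0.72 nats at m = 3), well below log m. The log m maximum
  is attained only by C\* = I, which real data essentially never
  produce. EE remains strictly decreasing in correlation strength,
  which is the property the signatures exploit.
- **Two-point windows always give EE = 0**: with n = 2 every absolute
  standardized column equals (1, 1), so C\* is the all-ones matrix.
  The first entry of every short-series EE profile is thus 0 by
  construction, which is why TSS₁ carries no information.

Numerical choices: natural logarithm (configurable via `log_base`);
symmetric eigensolver (`eigvalsh`); eigenvalues in [−1e−10·m, 0)
clipped to zero, more negative values raised as errors. A channel
whose in-window standard deviation is ≤ 1e−12 of its magnitude is
treated as degenerate — off-diagonal zeros, diagonal one — which
preserves PSD and trace m; the relative (not exact-zero) test is
needed because an affinely shifted constant column picks up an
O(machine-epsilon) standard deviation.

### Dense multiscale coarse-graining

Scale factors τ ∈ {0.5, 1.0, …, 5.0} with step α = 0.5 (both
configurable, `scales` / `alpha`). Integer τ uses plain block means of
the raw channel, emitting ⌊N/τ⌋ points; τ = 1 is the identity.
Fractional τ upsamples by zero insertion (1/α − 1 zeros between
samples, exact length (N−1)/α + 1), interpolates with a fourth-order
Butterworth low-pass applied forward-backward (zero phase), compensates
the zero-insertion amplitude loss by 1/α, and block-averages segments
of length Q = τ/α. τ = 0.5 is the fractional path with Q = 1, i.e. the
interpolated upsampled series itself.

Design choices where the procedure was open:

- **Filter cutoff** = α × Nyquist of the upsampled series — the
  classic anti-imaging choice for 1/α-fold interpolation; order,
  cutoff fraction and gain are configurable.
- **Zero-phase application** (`sosfiltfilt`) so coarse-grained samples
  stay aligned with the raw time axis; a single-pass filter would
  shift the changepoint location by the group delay.
- **DC handling**: the channel mean is removed before zero insertion
  and restored after filtering. A nonzero mean would otherwise become
  an edge-rippled filter response, and fractional-scale signatures
  would lose exact shift-equivariance (integer scales are exactly
  affine-equivariant by construction).
- **Length bookkeeping**: the upsampled length is the constructed
  (N−1)/α + 1; a trailing partial segment shorter than Q is dropped,
  mirroring the ⌊N/τ⌋ convention of the integer path.
- Scales whose coarse-grained output would be shorter than 4 points
  (or whose upsampled input is shorter than 13, the minimum for stable
  zero-phase filtering at order 4) are omitted per instance with a
  warning; extraction fails only if no scale survives.

### Signatures

The CMW sample size is SS = max(2, ⌊N/50⌋): about fifty windows per
series, growing by 2 when N < 100. When SS does not divide N a final
window of the full length N is appended so the schedule spans the whole
series; its divisor is its window index K. TSS_k = (EE_k − EE_1)/k for
k = 2 … K; TSS₁ ≡ 0 is dropped. SS is recomputed from each
coarse-grained length, so every scale contributes a comparable number
of features (509 for n = 400, m = 4 on the default grid). Unequal-length
collections must be padded first (`pad_to_length` repeats each
channel's final value); the gait-style pipeline block-averages
(window 10) before padding.

### Evaluation protocol

Per split seed (0–29): stratified 80:20 split → min-max scaling fit on
the training rows only, no clipping of out-of-range test values →
recursive feature elimination (linear-kernel SVM, C = 1, one feature
per step, keep ⌈p/2⌉ by default) → per classifier, exhaustive grid
search with stratified shuffled 5-fold CV (fold shuffling seeded by the
split seed) refit on recall → test recall and AUC. AUC is the
tie-corrected rank statistic; classifiers without probabilities use
their decision margin. Best classifier = highest mean recall, ties
broken by mean AUC. Welch's unequal-variance two-sided t-test compares
per-seed metric samples between methods. The full bank reproduces the
standard grids (SVM kernels/C/degree; RF estimators/criterion; KNN
neighbors/weights; NB var_smoothing; LR solvers/C with the default l2
penalty; XGB at its single default point); `reduced_classifier_bank`
(linear SVM, LR, NB with trimmed grids) is used for simulation studies
where the signal is linear by construction.

### Baselines

- **DTWD-1NN**: one warping path shared by all channels; per-step cost
  is the squared Euclidean distance across channels (absolute-sum
  available via `cost="abs"`); the square root of the accumulated
  optimum is returned; no warping window. Ties in nearest-neighbour
  distance go to the lowest training index. The ROC score is the
  margin d(nearest negative) − d(nearest positive), an artifact of
  this package so the hard 1-NN classifier can appear in AUC
  comparisons.
- **MMSPE**: integer scales 1–5, embedding 3, lag 1; ordinal patterns
  with positional tie-breaks, counts pooled across channels before the
  entropy (per-channel averaging available via `aggregation="mean"`);
  one entropy value per scale.

## Synthetic data

The generator emulates the method's premise — classes that differ in
correlation dynamics — as zero-mean Gaussian channels with
equicorrelated covariance: the control class holds ρ_base throughout,
the case class switches to ρ_shift at a changepoint. Defaults: 40
instances per class, n = 400 time points, m = 4 channels, ρ 0.1 → 0.8
at the midpoint, no added noise. Equicorrelation keeps positive
definiteness checkable in closed form (ρ > −1/(m−1)). One master seed
spawns one substream per instance, so enlarging a collection never
perturbs earlier instances. The null variant sets ρ_shift = ρ_base and
shuffles balanced labels.

What the generator does **not** emulate: autocorrelated or oscillatory
channel dynamics, heavy tails, artifacts, nonstationary variance, or
unequal series lengths. Passing the protocol tests therefore shows that
the pipeline detects correlation-structure shifts under clean Gaussian
conditions, not that it matches any particular clinical benchmark.

A note on effect sizes: the variance of TSS_k is dominated by the
sampling noise of EE_1, whose window holds only SS points. The class
gap in TSS_final at τ = 1 is ≈ 1.5 pooled SDs at n = 400 and exceeds
3 pooled SDs from n ≈ 2000–3000 upward; the separation test uses
n = 3000 for that reason, while the protocol-level checks (which pool
hundreds of features and 30 splits) already reach ≥ 0.9 mean recall at
n = 400.

## Problem sizes

The repeated-split studies use 40 + 40 instances of 400 × 4 series on
the default ten-scale grid with the reduced classifier bank — chosen so
that a full strong-plus-null comparison, including the DTWD distance
matrix, completes in about a minute on one CPU while leaving the
protocol (30 seeds, 5-fold grid search, RFE over ~500 features) intact.

## Known limitations

- Binary protocol only; multiclass would need one-vs-rest handling.
- The `.ts` reader covers the common UEA dialect (no timestamps,
  no sparse format).
- EE profiles on very short windows are noisy; series shorter than ~50
  points rely on the SS = 2 schedule and inherit first-window noise.
- The DTWD baseline is exact dynamic programming without lower-bound
  pruning; distance matrices scale quadratically in collection size.
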