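# Methods

## Signal model and preprocessing

Input recordings follow the DEAP layout: per subject, 40 trials × 40
channels × 8064 samples at 128 Hz, of which the first 32 channels are EEG
(10–20 montage Fp1 … O2); each trial carries 1–9 ratings of valence,
arousal, dominance and liking. Preprocessing is: optional polyphase
resampling to 128 Hz, a zero-phase band-pass to 4–45 Hz (order-4
Butterworth, two passes via `sosfiltfilt`; zero phase avoids latency
distortion of the time-domain features), and common-average
re-referencing (idempotent; per-sample channel mean exactly zero).
Ocular-artifact removal is not implemented: the reader assumes
preprocessed-release data from which artifacts were already removed.

Ratings are discretized per axis as [1,4) → −1, [4,7) → 0, [7,9] → +1 —
the continuous extension of the integer bins 1–3 / 4–6 / 7–9 — and the
two axes combined into five classes (happy (+1,+1), anger (+1,−1), sad
(−1,−1), relax (−1,+1), neutral if either axis is 0). The anger/relax
quadrant placement is kept verbatim from the labelling convention this
package reproduces even though it transposes the conventional circumplex;
`map_levels_to_emotion(..., circumplex=True)` swaps them.

## Tunable-Q wavelet transform

The TQWT is an oversampled two-channel filter bank iterated on its
low-pass branch. From the quality factor Q ≥ 1 and redundancy r > 1 the
per-stage scaling factors are h = 2/(Q+1) and l = 1 − h/r, with l + h > 1
(oversampling). Stage equivalent responses: the depth-J low-pass is
∏ H0(ω/l^m), supported on |ω| ≤ l^J π; sub-band j's response is
H1(ω/l^(j−1)) ∏ H0(ω/l^m), supported on [(1−h) l^(j−1) π, l^(j−1) π].

The bank is realized directly in the DFT domain. A stage acting on an
even-length-N spectrum produces even sub-band lengths N0 = 2·round(lN/2)
and N1 = 2·round(hN/2); the positive-frequency bins split into P =
(N−N1)/2 pure low-pass bins, T = (N0+N1−N)/2 − 1 transition bins, and S =
(N−N0)/2 pure high-pass bins. Transition gains use the
two-vanishing-moment Daubechies function θ(ω) = ½(1+cos ω)√(2−cos ω)
sampled at v_k = kπ/(T+1), paired with its reflection θ(π−ω); the pair is
exactly power complementary (θ(ω)² + θ(π−ω)² = 1). Sub-band spectra are
scaled by √(N_sub/N), which makes the transform a Parseval frame: energy
is conserved exactly and synthesis is the conjugate-transpose flow graph.
Numerically, both perfect reconstruction and energy conservation hold to
better than 1e−8 relative error (tested across Q ∈ 1..5, J ∈ 1..6 on
8064-sample signals); the residual is FFT round-off.

Odd-length inputs are zero-padded by one trailing sample (recorded,
stripped on reconstruction). `max_stages` iterates the length recursion
and requires every stage to satisfy N0 ≥ 4, N1 ≥ 4, T ≥ 0; decomposition
past that depth raises. The default setting Q=3, r=3, J=4 yields five
sub-bands; the total coefficient count N·(h(1+l+…+l^(J−1)) + l^J) is
bounded by r·N and approaches it as J grows.

## Features

Five scalars per (sub-band, channel) cell:

- **SampEn** (m = 2, u = 0.2·std of the *sub-band* sequence): −ln(A/B)
  with B (A) the number of unordered template pairs i ≠ j among the N−m
  templates whose m- ((m+1)-)length embeddings lie within Chebyshev
  distance u. Production counting uses KD-tree range queries; the O(N²)
  enumeration is kept in the test suite as an independent oracle.
  Conventions: constant signal → 0 (warned); A = 0 → +inf (warned,
  imputed downstream); B = 0 → degenerate-signal error.
- **2dif**: the signed mean of lag-2 differences, (1/(N−2)) Σ (x(n+2) −
  x(n)); it telescopes to (x(N)+x(N−1)−x(2)−x(1))/(N−2). The signed form
  is deliberate (much of the literature uses the mean absolute
  difference, available as `absolute=True`).
- **2ndif**: 2dif divided by the standard deviation (scale-invariant).
- **HM / HC**: Hjorth mobility √(var(Δx)/var(x)) and complexity
  HM(Δx)/HM(x), with Δ the first difference and no sampling-rate scaling
  (the standard discrete convention; units cancel in HC).

All standard deviations/variances use divisor N (population), chosen once
for consistency between the normalized difference and the Hjorth ratios;
at sub-band lengths of thousands of samples the distinction is
immaterial. Cells whose feature is undefined on a flat sub-band are
imputed to 0 and counted in the log rather than aborting a subject.

A per-subject, per-feature-type matrix at the reference dimensions is 40
trials × 160 columns (5 sub-bands × 32 channels, sub-band-major). Three
fusion layouts feed selection/classification: per-subject (40 × 160),
per-sub-band over subjects (1280 × 32 for a 32-subject cohort), and fully
fused (1280 × 160).

## Feature selection (BGWO)

Positions are binary masks over feature columns. Each iteration decays
the control scalar a linearly from 2 to 0 over T iterations. For each
wolf and each of the three best-so-far leaders (alpha, beta, delta), the
continuous grey-wolf step is computed on the 0/1 coordinates — A =
2a·rand − a, C = 2·rand, D = |C·leader − position|, candidate = leader −
A·D, all per dimension with independent draws — then squashed through
S(a) = 1/(1 + e^(−10(a−0.5))) and stochastically binarized into a donor
bit-vector. The new bit is 1 iff S((Y1+Y2+Y3)/3) ≥ r0 with r0 uniform per
bit. Empty masks are repaired by switching one random bit on. Leaders
update by strict improvement (first-evaluated wins ties), so the
best-so-far fitness trace is monotone non-increasing, and the whole run
is a pure function of the seed.

The wrapper objective is w·(stratified k-fold SVM error on the selected
columns) + (1−w)·(fraction selected), with w = 0.99 and k = 6 by default;
evaluations are memoized per mask. Defaults pack_size = 8, T = 70 are
desk-scale conventions of the binary-metaheuristic literature; all of
pack size, iterations, w, folds and kernel parameters are configurable.

## Classification and evaluation

RBF SVM (C = 1, bandwidth scaled to feature variance, i.e. sklearn's
`gamma="scale"`), with z-score standardization fitted inside each
training fold. Folds are stratified, shuffled, and seeded; classes with
fewer members than folds trigger a warning and a best-effort round-robin
stratification that never empties a training class (as long as each class
has ≥ 2 members). Per-fold confusion matrices are pooled; accuracy =
100·trace/total; sensitivity and specificity are macro averages of the
one-vs-rest per-class rates (zero-support classes excluded with a
warning); kappa = (Acc/100 − 1/k)/(1 − 1/k). This uniform-chance kappa is
*not* Cohen's marginal-product kappa: the chance term is fixed at 1/k so
that accuracies of problems with different class counts normalize onto
one scale. Chance accuracy maps to kappa 0 for every k.

## Synthetic cohorts

Each generated trial is unit-variance 1/f noise (frequency-domain
synthesis, randomized phases, default exponent 1.0) plus four
band-limited noise components (theta 4–8, alpha 8–13, beta 13–30, gamma
30–45 Hz) at base amplitude 0.6 relative to the background, each scaled
by 1 + effect_size·s where s ∈ {−1, 0, +1} comes from a fixed class
template (happy: beta+gamma up; anger: beta up, alpha down; sad: theta
up; relax: alpha up; neutral: baseline). Channel gains vary uniformly in
0.8–1.2 and the result is scaled to a ~10 µV amplitude. Ratings are
emitted at the level-bin centers (2/5/8), so class recovery through the
label mapping is exact by construction.

These cohorts emulate only the class-conditioned spectral structure and
the container shapes of real recordings. They have no spatial source
structure, no cross-channel correlation beyond shared class templates, no
non-stationarity, and no artifacts — so passing tests demonstrate that
the pipeline recovers planted spectral class structure, not that it
attains any particular accuracy on real EEG.

The planted Gaussian fixture for selector tests draws per-class mean
shifts for the informative columns once from N(0, effect²) and leaves
noise columns standard normal; at effect 3 the classes are separable to
>90% CV accuracy from the informative columns alone.

## Problem sizes and numerical choices

Defaults reproduce the reference cohort dimensions (40 trials × 32
channels × 63 s at 128 Hz; effect size 0.5; uniform class distribution).
Statistical end-to-end tests run on reduced cohorts — 8-second trials
and 8–16 channels, 1–2 subjects — sizes chosen so the planted effect is
still recovered with a wide margin while the suite stays desk-scale;
selector-recovery tests use pack 5 and T = 10 on the 1280 × 32 planted
fixture. Perfect-reconstruction and energy tolerances are 1e−8 relative
(double precision with FFT headroom); kappa reproduction is checked to
±0.005 (2-dp rounding of published values, plus a 1e−9 float-
representation epsilon). Degenerate inputs follow the conventions above
(constant-signal SampEn 0, imputation of undefined cells, empty-mask
repair); ties in the parameter sweep resolve to smaller J then smaller Q.

## Known limitations

- The synthetic generator is a fixture, not a physiological model;
  accuracies on it say nothing quantitative about DEAP or other real
  datasets.
- The BGWO objective (w, folds, kernel) is a convention: the selector's
  printed retention ranges on real data depend on it and are treated as
  descriptive, not contractual.
- Per-subject runs with 40 trials and five imbalanced classes cannot be
  cleanly 6-fold stratified; the best-effort fallback warns and proceeds.
- `resample` only downsamples (the pipeline never upsamples).
- Sensitivity/specificity macro-averaging over pooled confusion matrices
  is one of several reasonable multiclass generalizations; per-fold
  values are also reported for transparency.
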