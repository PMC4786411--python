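# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer should know about.

## Signal chain

**Recording model.** Raw voltage is channels × samples at a few kHz,
organized in contiguous 16-channel amplifier banks (the last bank may be
short). All event times are seconds on the recording clock; trial-aligned
data place t = 0 at acoustic onset and report latencies in ms.

**Notch.** Second-order IIR notches (Q = 30) at 60/120/180 Hz, applied
forward–backward so the chain stays zero-phase.

**Channel rejection.** Welch log-periodograms (1 s windows). Each
channel's deviation is the Euclidean distance to the mean log-periodogram
of the *other* channels; a channel is rejected when its deviation exceeds
the cross-channel mean by more than 2 cross-channel SDs. The threshold
applies to centered deviations: raw distances are positive even for
perfectly typical channels, so thresholding them directly would reject
everything whenever no grossly deviant channel inflates the spread. The
rule assumes deviant channels are a minority; configurations in which half
the array carries strong narrowband power can push clean channels over
the threshold (see Limitations).

**Banked common-average reference.** Within each contiguous bank the mean
over non-rejected channels is subtracted from every channel (rejected
channels are referenced but do not contribute). Bank-shared noise cancels
exactly; a response present on k of the bank's 16 channels loses only the
k/16-scaled bank mean of itself.

**High gamma.** Eight Gaussian frequency-domain bandpass filters with
log-spaced centers in 70–150 Hz. The stated bandwidth growth is
"semi-logarithmic", which under-determines the law; here σᵢ = c·√fᵢ with c
fixed so the eight full-widths-at-half-maximum tile the band end to end —
monotone, sub-logarithmic growth with full coverage. Each filter's
analytic amplitude comes from zeroing negative frequencies (Hilbert
transform); the eight amplitudes are averaged and polyphase-resampled to
100 Hz (the native rate is not an integer multiple of 100, so decimation
would not apply). Z-scoring uses the mean/SD of declared baseline rest
intervals per channel (pre-stimulus windows by default); the statistics
are stored so the transform is invertible.

## Statistics

**Adjusted Rand index.** Pair counts a, b, c, d classify every item pair
by same/different cluster membership under the two partitions;
RI = (a+d)/C(n,2) and RI_adj = [C(n,2)(a+d) − E]/[C(n,2)² − E] with
E = (a+b)(a+c) + (c+d)(b+d). The pair-count form is algebraically equal to
the contingency-table form; the test suite verifies the identity to 1e-12
against an independent implementation. Degenerate case: when both
partitions are trivial (all together or all apart) the denominator
vanishes and the index is defined as 1. For the fixed 8-syllable gold
standards, RI_adj(place, manner) = −2/11 ≈ −0.18, which is the floor the
pipeline reports when data organize perfectly by the *other* scheme; a
perfect ΔRI_adj is therefore 1 + 2/11 ≈ 1.18, not 1.

**Silhouette.** s(i) = (b(i) − a(i))/max{a(i), b(i)} on a precomputed
distance matrix; singleton clusters score 0 (convention; the formula is
undefined there). Note that a forced k-means split of an unstructured 2-D
Gaussian cloud scores ≈ 0.35 — moderate silhouettes alone do not imply
structure; the spatial stage therefore gates k-selection behind the dip
decision.

**Hartigan dip.** The dip is the sup-norm distance from the empirical CDF
to the nearest unimodal CDF. The implementation evaluates the definition
exactly: for each mode placement (at a data value, where an atom is
allowed, or inside a gap), a convex-then-concave CDF exists within ±d of
the empirical CDF iff the greatest convex minorant of the per-point upper
band clears the lower band on the rising side (symmetrically with the
least concave majorant on the falling side); the dip is half the minimum
worst violation over placements, computed in O(n²) with incremental
convex hulls. Anchors: n equally spaced distinct values → 1/(2n); half
mass at each of two points → 1/4. The test suite cross-checks against an
independent LP-feasibility + binary-search oracle. P-values are bootstrap:
the dip of N(0,1)-size-matched uniform samples (the least favorable
unimodal null), 2000 replicates by default, cached per sample size.
Viewer-level testing in the spatial stage applies no multiple-comparisons
correction (one significant viewer declares clustering), matching the
source procedure; a Bonferroni switch exists.

**Bootstrap t-test.** The test statistic is Welch's t. The null resamples
both groups with replacement from the mean-centered pooled sample
(n_boot = 2000 default) and p = (1 + #{t* ≥ t})/(n_boot + 1). Sidedness
defaults to one-sided (activation) with a parameter. Calibration is
verified: type-I error at α = 0.01 lies in [0.005, 0.02] over 2000
simulations. Degenerate alpha ≥ 1 in site selection flags every testable
site explicitly, since the +1-corrected p-value can equal exactly 1.

**Onset latency.** Per post-onset sample, one-tailed rank-sum of the
across-trial values against the pooled 500 ms pre-stimulus baseline at
p < 0.001; the onset is the first significant sample, with no correction
across samples (faithful to the source procedure). Two consequences are
quantified in the tests: (i) on pure noise the chance of *some* false
onset is ≈ n_samples × 0.001 per electrode (≈ 0.14 for a 1.5 s axis), so
"no onset" is the typical but not near-certain null outcome; (ii) the
estimate carries a constant detection delay — the crossing happens where
the rising response clears ≈ 0.4 SD, ~10 ms for a fast (100–150 ms)
raised-cosine rise at SNR 5. Cross-region latency comparisons subtract
this delay implicitly since it is common to both regions.

**Cross-correlation.** Trials are mean-subtracted within the analysis
window ([−0.5, 1] s), per-trial lagged products are scaled by 1/(M − |τ|)
(the unbiased normalization; expected value is lag-independent for
stationary noise) and by the trial's two SDs to make values
correlation-like, then averaged across trials; lags span ±0.75 s. Sign
convention: the printed summation convention and its verbal gloss
conflict under index algebra; the verbal convention is adopted — **a
negative peak lag means the first argument leads** — and the lag axis is
defined to enforce it. The asymmetry index sums only positive correlogram
values on each side of lag 0 (lag 0 belongs to neither side) and is
undefined (None) when there is no positive mass. The analytic ±1 anchors
are computed with `demean=False` on nonnegative pulse pairs: demeaning
compactly supported pulses creates a tiny spurious positive mass at
opposite-extreme lags (product of the two negative baselines), which
would make the anchor ±(1−ε). The three-way lead/coactive/lag
classification thresholds the index at ±0.25 (configurable; the source
threshold is unstated).

**ΔRI trajectory.** Sliding 100 ms windows, 10 ms step by default (the
evoked kernel at 100 Hz is well resolved). The permutation null
randomizes the token labeling of the k-means clustering (1000 relabelings
by default); p is one-sided toward acoustic organization,
Benjamini–Hochberg corrected across windows at q = 0.05. Under no planted
organization the p-values are verified uniform (KS) and the FDR mask
near-empty. RI_adj error bars come from trial-bootstrap resamples ×
k-means restarts (100 by default); the resampling unit is a documented
choice.

**PSI.** Pairwise two-sided rank-sum tests over all n(n−1)/2 phoneme
pairs at p < 0.01, Bonferroni-corrected by default (FDR switchable);
PSI(p) counts the phonemes significantly different from p. The pairwise
test is symmetric, so significant-pair endpoints always sum to an even
number. Response scalar: mean z in [0, 150] ms after phoneme onset
(phoneme-scale window; the source is silent). Phonemes need > 30
occurrences and ≥ 5 trials.

**STRF.** The auditory front end is a bank of log-spaced constant-Q
gammatone filters (60 channels, 180–7000 Hz), cube-root compression, a
first difference across the spectral axis (lateral inhibition) half-wave
rectified, lowpass envelope, 100 Hz frames. Estimation solves the
ridge-penalized least-squares reverse-correlation problem on the lagged
stimulus design (columns and response centered; the design carries no
intercept, and centering makes cross-validated r exactly invariant to
affine response rescaling). The sparseness hyperparameter s zeroes the
fraction s of weights smallest in magnitude and refits the survivors once
(the source names but does not define its sparseness mechanism).
Hyperparameters are chosen by grid search — λ log-spaced over six decades
scaled to the stimulus energy, s ∈ {0, 0.25, 0.5, 0.75} — maximizing mean
held-out prediction correlation over 10 contiguous-block folds
(contiguous, because temporal autocorrelation would leak across shuffled
folds). The source maximizes a mutual-information criterion whose
estimator it does not specify; correlation is the quantity it reports and
thresholds, so correlation is the default and a 16-equal-occupancy-bin,
bias-corrected MI estimator is selectable. The final H and r are means
over the 10 per-fold fits. Significance: circular shifts of the response
by ≥ n_delays frames, p = fraction of null r ≥ observed; sites are
"predictable" at r ≥ 0.10 and p < 0.01. Delay span default 30 frames
(300 ms), covering observed evoked latencies.

## Synthetic data

Every generator is a pure function of (parameters, seed), and the
GroundTruth object suffices to compute the ideal noise-free output of
every downstream stage.

* **Raw recordings**: per-channel 1/f (pink) background — chosen so the
  periodogram rejection rule faces a realistic spectral shape — plus
  shared 60/120/180 Hz sinusoids, Gaussian noise shared within each
  16-channel bank, and event-locked bursts on designated channels. The
  burst carrier is band-limited (70–150 Hz) Gaussian noise: spectrally
  realistic (a tonal carrier would put a spike in the periodogram and
  trip the rejection rule) and its analytic amplitude tracks the planted
  raised-cosine envelope to r ≈ 0.98 under the 8-filter average. Burst
  amplitude is `burst_snr` × the channel's in-band background SD.
  Default configurations keep burst duty cycle near 10% and responsive
  channels a minority-per-bank subset.
* **Evoked datasets**: each electrode gets a raised-cosine temporal
  kernel (onset from a per-region latency map, default STG 100 ms before
  vSMC; duration 400 ms) whose per-token gain depends only on the token's
  feature group relative to the electrode's assigned group
  (weights 1.0/0.55/0.2), so token means cluster exactly by feature group
  in the noise-free limit; `mode='none'` removes token dependence. Trial
  noise is i.i.d. Gaussian (SD 0.5 z by default, chosen so 12 trials give
  clean but not trivial recovery).
* **STRF data**: modulation-limited stimulus (Gaussian noise smoothed
  over time and frequency — non-white, so reverse correlation must
  normalize by the stimulus autocorrelation), response = causal
  convolution with a smooth excitatory/inhibitory ground-truth filter
  plus noise.
* **Phoneme trials**: Normal(mean, 1) per phoneme over a fixed 33-label
  inventory, means set by a selectivity profile.
* **Electrode positions**: isotropic Gaussian scatter around planted
  centers in an abstract 2-D cortical plane (all spatial analyses in
  scope use pairwise distances and the signed distances to the central
  sulcus / Sylvian fissure, so no 3-D surface is modeled).

What passing tests show — and what they do not: the generators share the
analyses' own structural assumptions (linear STRF, Gaussian trial noise,
smooth unimodal kernels, exact feature-group gains). Recovery on this
data validates the implementations, window logic, sign conventions, and
calibration of the statistics; it does not certify performance on real
cortical data, where responses are non-Gaussian, nonstationary,
correlated across trials and electrodes, and only approximately linear in
the stimulus.

## Numerical choices and degenerate inputs

Seeds: every stochastic routine takes a seed; the pipeline derives
per-stage substreams from one master seed, so identical config + seed
reproduces every output bit for bit. Exact ties in peak latency resolve
to the earliest sample with a flag. Coincident electrode positions make
every viewer distance equal; the dip is then degenerate and the
configuration reports "not clustered". Zero-variance rows (tokens,
baselines, pooled bootstrap samples) raise typed errors rather than
propagating NaNs. k-means uses k-means++ with 50 seeded restarts (10 in
inner loops) — restarts stabilize the RI_adj statistics built on top.
MDS is SMACOF initialized from the classical-scaling solution;
correlation distances are generally non-Euclidean, so eigendecomposition
alone may not embed them, but it is the right starting point and makes
exactly-Euclidean cases converge to machine-precision stress.

## Problem sizes

Default test and demo scales are desk-sized by design: 32-channel, ~50 s
recordings at 1200 Hz; 30-electrode evoked datasets with 12 trials per
syllable; 10 000-frame STRF fits with 20 delays × 16 frequencies; 2000
simulations for calibration checks. These sizes give stable statistics
for every claim the tests make while keeping the full suite fast; all are
config parameters, and clinical-scale values (3052 Hz sampling, 256
electrodes, 30-frame delay spans) run through the same code paths.

## Known limitations

* The 2-SD periodogram rule degrades when deviant channels are not a
  minority (bimodal channel populations), and flags ~2% of clean channels
  by construction.
* The onset-latency estimator's detection delay depends on response rise
  time and SNR; absolute onsets are biased late by design, and only
  cross-condition comparisons are unbiased.
* The cochlear front end is a compact functional approximation
  (gammatone + compression + lateral inhibition + envelope), not a fitted
  auditory-periphery model; channel count and frame rate are documented
  defaults, not sourced values.
* PSI with Bonferroni over 528 pairs is conservative; the FDR option
  trades specificity for sensitivity.
* The dip-means stage decides clustered-vs-not and selects k; it does not
  perform full iterative dip-means splitting.
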