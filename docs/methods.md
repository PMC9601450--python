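# Methods

## Problem and scope

`pnesent` re-implements, as a tested and reusable pipeline, an entropy-based
analysis of interictal scalp EEG and single-lead ECG for differentiating
psychogenic non-epileptic seizures (PNES) from epilepsy: six entropy
estimators per channel per frequency band, imbalance-aware cross-validated
classification, and grouped permutation band importance. The clinical
recordings such analyses are run on cannot be redistributed, so the package
ships a synthetic-cohort generator and every claim the test suite makes is a
*property* of the method — oracle equivalence, analytic limits, recovery of
planted structure — not a reproduction of clinical results.

## Preprocessing chain

Raw recordings (20 common 10–20 electrodes + ECG± leads, 256/512/1024 Hz)
pass through:

1. **Resampling** to 256 Hz (`scipy.signal.resample_poly`, which applies its
   own anti-aliasing filter) and selection of the common electrode set.
2. **Broad-band EEG filter**, 0.5–40 Hz linear-phase FIR (Hamming window),
   applied as a single forward pass with exact integer group-delay
   compensation on reflection-padded data — equivalent to zero-phase for a
   symmetric FIR. Transition bandwidth is `max(0.25·f_low, 1.0 Hz)`. The
   1 Hz floor is deliberate: a 0.125 Hz transition at the 0.5 Hz edge would
   need ≈6800 taps, longer than one 10-s epoch (2560 samples at 256 Hz), and
   the per-band filters must be applicable to single epochs. The resulting
   ≈845-tap Hamming design still gives ≥53 dB stop-band attenuation.
3. **ECG derivation**: (ECG+) − (ECG−), 6th-order Bessel IIR band-pass
   0.25–40 Hz, then a 2nd-order 0.05 Hz high-pass for baseline wander. The
   filter family and cutoffs are the replicated convention; the order is a
   free choice, and 6 is the lowest at which the Bessel's slow roll-off
   still yields >20 dB steady-state suppression of mains-range tones while
   keeping QRS-band droop under 10 %. Both IIR stages run forward–backward
   with ~10 s padding (the 0.25/0.05 Hz poles ring for seconds); this
   sacrifices the Bessel's linear phase in exchange for zero phase, keeping
   the ECG time-aligned with the zero-phase EEG bands. The same derived ECG
   accompanies every EEG band.
4. **Epoching** into non-overlapping 10-s windows (N = 2560), trailing
   partial data dropped.
5. **Artifact rejection** by amplitude criteria with a reason log: flat
   epochs (every EEG channel peak-to-peak < 1 µV — peak-to-peak is assumed
   where "amplitude" is ambiguous, and configurable), noisy epochs (any EEG
   channel peak-to-peak > 300 µV by default; a deliberately simple
   stand-in for consensus-threshold rejectors such as AutoReject, whose
   Bayesian-optimised thresholds are out of scope), and flat-ECG epochs
   (automating what would clinically be a visual check).
6. **Baseline correction**: per subject and channel, the mean over all of
   that subject's retained epochs is subtracted.
7. **Band decomposition** into broad (0.5–40), delta (0.5–4), theta (4–8),
   alpha (8–13), beta (13–30) and gamma (30–40 Hz); broad is the identity
   pass-through. Mains-noise removal is intentionally absent.

## Entropy estimators

All six are implemented from scratch (`pnesent.entropy`) and verified
against independent oracles in the test suite.

* **ApEn(m, r)** — Chebyshev distance over length-m templates,
  self-matches *included*, Φ^m = mean ln C_i, natural log. The production
  path builds running element-wise-max distance matrices
  (D_{m+1}[i,j] = max(D_m[i,j], |x_{i+m}−x_{j+m}|)), costing O(mN²) without
  materialising embedded vectors; the test oracle uses explicit embeddings
  and `scipy.spatial.distance.cdist`.
* **SampEn(m, r)** — self-matches excluded, B and A counted over the N−m
  templates that have an (m+1)-length continuation, both normalised by
  (N−m−1); returns −ln(A/B). If A or B is zero the value is undefined and a
  NaN sentinel is returned; downstream feature assembly excludes and logs
  such epochs rather than capping. For both statistics r = r_sd·SD(x),
  computed per epoch per channel; a zero-variance series returns 0 with a
  warning (a flat channel carries no irregularity; the flat-epoch rejector
  normally removes these upstream).
* **Spectral entropy** — Welch PSD (1-s Hamming segments, 50 % overlap; all
  bins up to fs/2), normalised to a probability vector, Shannon entropy
  divided by ln Ω, so white noise → 1 and a line spectrum → 0.
* **SVD entropy** — delay embedding with dimension 10, delay 2 (the Hankel
  dimensions are otherwise a free choice and are exposed as parameters);
  p_l = σ_l²/Σσ², entropy −Σp log₂ p / log₂ L. A single log base is used
  for both the sum and the normaliser so the maximum is exactly 1 (printed
  definitions of this estimator sometimes mix bases; the normalised-to-[0,1]
  convention is adopted).
* **Rényi entropy** (α = 2) — equal-width amplitude histogram over the
  epoch's observed range, 100 bins by default, then
  (1/(1−α))·log₂ Σp^α. The histogram rule is the main replication degree of
  freedom of this estimator and the bin count is deliberately a parameter.
  Note the equal-width-over-range rule makes the value invariant to
  amplitude scaling; class contrast reaches it through distribution *shape*
  (e.g. the arcsine-like density of a strong oscillation vs the Gaussian
  density of noise).
* **Wavelet entropy** — Morlet CWT (PyWavelets) at 10 log-spaced scales
  covering 0.5–40 Hz; level energies are mean squared coefficients over the
  window (default: the whole epoch, one value per epoch per channel);
  Shannon entropy (nats) of relative level energies, in [0, ln J].

Feature assembly produces one value per (epoch, channel) — 21 columns per
band (20 EEG + ECG) — and concatenates band blocks column-wise with a
per-column band annotation used by the grouped importance.

## Parameter grid search

ApEn/SampEn parameters are chosen over m ∈ {1, 2} ×
r_sd ∈ {0.1, 0.15, 0.2, 0.25} on a ten-subject-per-class subset (uniform
draw without replacement under the run seed): features per cell → RBF-SVM →
5-fold CV → highest mean balanced accuracy wins; ties go to smaller m, then
smaller r_sd (cheaper, lower-variance estimator). The per-cell score
averages over all six bands by default; a single-band variant
(`bands=["broad"]`) is used wherever the full average is not needed,
because the Chebyshev distance stack shared across all eight grid cells is
still the dominant cost. When the search is skipped the defaults are
m = 2, r_sd = 0.2 (ApEn) and m = 1, r_sd = 0.15 (SampEn).

## Classification protocol

Stratified epoch-wise 10-fold CV (a subject's epochs may appear on both
sides of a fold — the protocol being replicated; a grouped subject-wise
mode is provided as the methodologically safer option). Per fold, strictly
train-only: z-scoring (added because RBF-SVM, kNN and PCA are
scale-sensitive; toggleable), SMOTE oversampling of the minority class to
parity (synthetic rows are convex combinations of a minority row and one of
its k = 5 nearest minority neighbours), PCA keeping the smallest component
count with ≥95 % explained variance, then one of:

* **SVM** — RBF kernel, γ = 1/(n_features × variance of the standardized,
  oversampled training matrix);
* **kNN** — k selected per fold by an inner 10-fold balanced-accuracy
  search over {2,…,10, 12, 15, 20}, Euclidean distance, uniform weights.
  The inner search issues one neighbour query at the largest k per inner
  fold and derives every smaller-k vote from prefixes of the same
  neighbour list — identical selections at a twelfth of the cost;
* **RF** — 100 trees; **GBM** — 100 stages, learning rate 0.1 (library
  defaults, pinned).

Metrics: precision, recall and balanced accuracy with PNES as the positive
class; zero-denominator folds are flagged NaN and excluded from unweighted
fold averaging.

## Band importance and exclusion

Grouped permutation importance of band b: reference balanced accuracy s on
the validation fold minus the mean score over K = 10 copies in which all of
b's columns are shuffled. Columns are re-permuted independently by default
(the stronger corruption); a shared-row-permutation mode exists, and tiny
validation sets can be scored exhaustively over all permutations (used by
the tests to pin the Monte-Carlo estimator to an enumeration oracle). The
band-exclusion experiment drops one band at a time (every band's ECG column
is always retained), reruns the full CV on the remainder, and reports the
all-bands model's fold-averaged importance next to each exclusion row.

## Synthetic cohort

The generator (`pnesent.synth`) emulates the statistical structure the
analysis assumes, not PNES physiology; every contrast parameter is
configuration. Defaults: 48 PNES-like / 29 epilepsy-like subjects (the
imbalance exercises the SMOTE path by default), 20 epochs per subject,
256 Hz, 10-s epochs, the 20 common electrodes plus ECG±.

Per epoch, each EEG channel is 1/f^β background noise (β = 1.0 both
classes by default; an optional class β shift and AR(1) component exist),
plus one amplitude-modulated oscillation per band (2, 6, 10, 20, 35 Hz;
base amplitude 5 µV against a 10 µV background), plus a shared 1/f source
mixed across channels through a fixed montage-determined profile. The class
contrast multiplies the oscillation amplitude in the configured informative
bands (default: theta, ratio 3.0 — a "strong" contrast chosen so the
planted effect is unambiguous at desk-scale cohort sizes; no distributional
description of the real interictal EEG exists to calibrate against, so this
magnitude is explicitly a calibration choice). ECG± carry ±half of a
Gaussian-bump QRS train whose RR intervals are mean 0.85 s with
class-specific jitter SD (15 ms vs 50 ms, echoing reports of reduced
interictal heart-rate complexity in functional seizures).

Two deliberate departures from a literal "one continuous recording":

* 1/f noise is normalised by its *analytic* (Parseval) SD, not the realised
  SD of the draw — realised-SD scaling couples every epoch cut from one
  recording and imprints a subject fingerprint that epoch-wise CV exploits
  even at zero contrast.
* Epochs are generated as independent segments, emulating rest epochs
  clipped at scattered times from a long monitoring session. Continuous 1/f
  background would make temporally adjacent epochs correlated, which
  epoch-wise CV also converts into spurious accuracy. With both choices a
  zero-contrast cohort classifies at chance, which is the null the tests
  rely on.

What the generator does **not** emulate: volume-conducted topographies from
a head model, eye-blink/EMG artifacts (only simple amplitude outliers for
exercising the rejector), non-stationary state changes (drowsiness),
epileptiform transients, or realistic ECG morphology beyond a QRS bump.
Passing tests therefore demonstrate that the pipeline recovers the kind of
band-specific complexity contrast it is designed to detect — not that any
particular accuracy is attainable on clinical data.

## Numerical choices and degenerate inputs

* Chebyshev distance ties (d = r) count as matches (≤ r), in both the
  production path and the oracles.
* SampEn A = 0 or B = 0 → NaN sentinel; feature assembly raises with the
  offending epoch/channel named (grid search excludes such epochs and
  logs).
* Rényi on a constant series → 0 (single occupied bin); spectral/SVD/
  wavelet entropy on an all-zero series → error (undefined spectrum).
* EDF output is plain 16-bit EDF (the continuous subset of EDF+) with 1-s
  records and per-channel physical ranges padded 1 % above the data
  extremes; quantization error is bounded by (phys_max−phys_min)/65535.
  Reading goes through MNE, which doubles as an independent format check.
* All randomness flows from integer seeds through `numpy.random.Generator`
  child streams; per-subject streams are keyed (seed, class, subject) so a
  subject's signal is independent of cohort size.

## Problem sizes used by the test and acceptance runs

Study-condition checks use a 10 + 10 subject cohort with 20 epochs per
subject (400 epochs, 126 features across six bands); the grid search runs
on ten subjects per class with one epoch each (its protocol subset size),
and module-level grid tests use six per class. These sizes make every
planted effect detectable while keeping a full run on one CPU at desk
scale; they are stated here because they are smaller than the ~10,000-epoch
clinical dataset the protocol is designed for, and the defaults
(`CohortConfig()`) mirror the full 48/29 cohort instead.

## Known limitations

* Epoch-wise CV inflates accuracy whenever same-subject epochs correlate;
  the generator removes such correlation by construction, but on real
  recordings the subject-wise mode is the honest evaluation.
* The Rényi histogram rule (equal-width, 100 bins, per-epoch range) is one
  of several defensible conventions and materially affects absolute values.
* The amplitude-criterion rejector is not a substitute for consensus-based
  artifact rejection on clinical data.
* The SVM γ rule ties γ to the post-SMOTE training variance; with
  z-scored features this is near 1/n_features, so the SVM's behaviour is
  largely governed by PCA dimensionality.
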