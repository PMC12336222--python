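# Methods

`bcgsleep` implements a complete non-contact sleep-staging chain for
ballistocardiogram (BCG) recordings: signal separation, beat and breath
detection, heart-rate-variability (HRV) and respiratory-rate-variability
(RRV) feature extraction, attention-gated iterative feature selection,
minority-class oversampling, an adaptive-base-class boosting classifier,
a population optimizer for hyperparameters, and the staging metrics.
Because clinical BCG datasets are rarely shareable, the package ships a
first-class simulator that provides exact ground truth for every stage of
the chain; all quantitative claims in the test suite are made against that
simulator or against published confusion-matrix arithmetic.

## Signal model and simulator

A BCG trace is modelled as a sum of three components:

* a heartbeat pulse train — a Gaussian-windowed cosine of ~0.12 s width
  whose central positive lobe is the J wave, flanked by the I/K troughs and
  small H/L lobes, centred at cumulative RR times;
* a respiratory baseline — a sinusoid at the stage's breathing rate
  (0.22–0.30 Hz across stages) that also amplitude-modulates the beats by
  ±20%;
* additive white Gaussian noise.

RR intervals are drawn per 30-s epoch from a stage profile: a mean and SD
plus two sinusoidal modulations, at ~0.1 Hz (sympathetic, "LF") and at the
respiratory rate (respiratory sinus arrhythmia, "HF").  The default
profiles follow the qualitative sleep-HRV literature — deep sleep N3 is
slow and regular with strong RSA (rr_mean 1.05 s, rr_sd 0.02 s), REM is
faster and more variable with LF dominance (0.85 s, 0.06 s), wake is
fastest (0.80 s, 0.05 s), N1/N2 intermediate.  No public quantitative
stage-conditional RR statistics exist for this device class, so the
profiles are stipulated, not estimated; they are chosen to make stages
learnable while remaining physiologically plausible.  Profiles with
`rr_mean − 3·rr_sd ≤ 0` are rejected because they could generate
non-positive intervals.

The default sampling rate is 100 Hz (configurable); BCG hardware varies
and nothing downstream depends on the exact rate beyond Nyquist coverage
of the 1–15 Hz heartbeat band.

Hypnograms are generated by apportioning stage quotas exactly to a target
distribution (largest-remainder rounding) and splitting each quota into
runs with geometric lengths of mean 10 epochs — equivalent to a 0.9
self-transition probability — which are then shuffled.  Compared to
sampling a Markov chain directly, this keeps realistic stage bouts while
pinning the empirical stage distribution to the target within one epoch
per stage; with free-running chains the per-stage share of a single night
fluctuates by several percentage points, which would make the night's
class balance itself a random variable.  The default target distribution
is the five-stage epoch distribution of a full-night BCG study (W 10.61%,
REM 21.40%, N1 4.33%, N2 43.27%, N3 20.39% of 10,201 epochs).

What the simulator does **not** model: body-movement artifacts, sensor
drift, inter-subject morphology differences, apnea-like breathing
irregularity, and stage-transition dynamics of real hypnograms beyond run
lengths.  Passing tests therefore demonstrate the correctness and internal
consistency of the chain under its stated signal model, not clinical
staging accuracy on real recordings.

### Planted feature tables

Selection and classification are additionally tested on feature tables
with known structure.  Each informative column carries one class-pair
contrast (the 10 unordered pairs of 5 stages), with means ±effect/2 for
the pair and unit within-class SD, so no informative column can substitute
for another; redundant columns are linear copies (slope magnitude
0.5–2, unit copy noise); noise columns are standard normal.  Labels
follow the study's class proportions.  This design was fixed once; the
pair-contrast structure is what makes "the selector must keep all
informative names" a well-posed requirement.

## Signal processing

* **Heart component.** Continuous wavelet transform with the Mexican-hat
  wavelet over 32 log-spaced scales with pseudo-frequencies 1–15 Hz.  The
  retained scale maximizes the sum of min-max-normalized coefficient
  energy and variance (each mapped to [0, 1] across the grid; ties break
  to the smaller scale).  On long recordings the scan runs on the leading
  5 minutes and the chosen single scale filters the full signal — the
  best scale is a property of beat morphology, not of the night.
* **J-peaks.** Local maxima with amplitude above the mean of the strictly
  positive samples, topographic prominence ≥ 0.3 signal SDs, and ≥ 0.4 s
  spacing.  Spacings above 1.4 s are reported as suspected missed beats
  rather than interpolated; downstream interval cleaning absorbs them.
* **Respiration.** Zero-phase (forward–backward) order-4 Butterworth
  low-pass at 0.5 Hz; breath peaks are local maxima with ≥ 2 s spacing.
  The bidirectional pass squares the magnitude response, giving gain 1/2
  at the cutoff.
* **Intervals.** First differences of peak times, assigned to the
  half-open 30-s epoch containing the earlier peak; epochs with fewer
  than two peaks yield an empty, flagged sequence.  Cleaning replaces
  intervals outside [0.3 m, 1.5 m] of the raw epoch mean m with m, in a
  single pass with m computed once — iterating the rule would shift the
  reference mean and is deliberately avoided.

## Feature bank (232 features)

Exactly 232 named features per epoch: 34 time-domain, 44
frequency-domain, 14 Poincaré, 14 heart-rate-asymmetry (JJ only),
2 sample-entropy, and 124 multi-scale window features.  The registry is
ordered and checksummed; any drift fails a test.

Definitions follow standard HRV practice: SDNN is the sample SD, RMSSD
the root-mean-square of successive differences, NNx/PNNx count successive
differences above x ms, TINN is the base width of the least-squares
triangular fit to the 1/128-s-bin interval histogram and HTI the total
count over the modal bin count.  Heart-rate statistics use instantaneous
60/JJ per interval.  Two names in the bank are not standard acronyms and
are implemented as documented choices: **RMSA** as the root-mean-square of
the interval amplitudes √mean(v²), and **SD2I** as the total along-line
SD recomputed from its directional parts √(SD2d²+SD2a²).

Spectra use a tachogram resampled at 4 Hz by cubic interpolation and a
Welch PSD (segments ≤ 256 samples).  Band edges default to Task-Force
conventions — ULF < 0.0033 Hz, VLF 0.0033–0.04, LF 0.04–0.15, MF
0.08–0.15, HF 0.15–0.40 — plus TLF ("total low frequency", 0–0.04) and
TF (0–0.40); the identical machinery runs on the breath-interval
tachogram.  A band is flagged missing when the window is shorter than one
cycle of its lower edge (so ULF/VLF are structurally missing at 30 s),
and peak-frequency/ratio/normalized features are flagged when the
underlying band power is numerically zero (< 1e-15) — the argmax of a
flat spectrum is noise, not a frequency.

Poincaré descriptors use SD1² = var(Δ)/2 and SD2² = 2 var − var(Δ)/2, so
SD1² + SD2² = 2 SDNN² holds identically.  The asymmetry family follows
the deceleration/acceleration decomposition of the Poincaré cloud:
signed distance to the identity line partitions points; contributions are
normalized so C1d+C1a = Cd+Ca = 1 exactly, and the Guzik index is the
percentage of line-distance contributed by decelerations.  Sample entropy
is the Richman–Moorman estimator with m = 2, r = 0.2 SD, Chebyshev
distance, self-matches excluded.

Multi-scale windows concatenate each epoch with the following 1, 3, 9 and
19 epochs (1-, 2-, 5-, 10-minute windows), truncated and flagged at the
recording end.  SDANN and SDNNI segment the window into minutes as
consecutive epoch pairs; windows shorter than 2 minutes flag both as
missing (a single minute has no between-minute SD).

Missing values are median-imputed per column at table assembly (0 when a
column is entirely missing, e.g. breath-interval sample entropy at 30 s,
where ~7 breaths cannot support an m = 2 template estimate); the
imputation mask is preserved alongside the table.

## Feature selection

A gating network learns per-feature weights jointly with a classification
head: input p → dense 128 (ReLU) → batch-norm → dropout 0.3 → dense 64
(ReLU) → batch-norm → dropout 0.3 → dense p with sigmoid = gates in
(0, 1); the gated standardized input feeds a linear softmax head trained
with cross-entropy (Adam, 50 epochs, batch 64, fixed seed).  The network
is a small, dependency-free numpy implementation with manual
backpropagation; reported weights are the mean gate over training rows
under full-set batch statistics without dropout.

The gated table is fit with a gradient-boosted tree ensemble (200 rounds,
depth 6, learning rate 0.1, column subsampling 0.5) and features are
ranked by **total-gain** importance normalized to sum 1.  Two numerical
choices matter here and were validated on the planted generator:
total gain rather than per-split average gain (average gain over-credits
rarely used noise columns — in the planted setting they would absorb
~69% of normalized importance), and column subsampling (without it,
greedy boosting funnels the whole credit of a correlated group into
whichever member is split first, which destabilizes the ranking across
seeds).

Selection keeps the minimal importance-sorted prefix whose cumulative
share reaches the weight ratio, then retrains both the network and the
ensemble on the survivors; defaults are 3 iterations at ratio 0.796.
"Share above a threshold" admits a per-feature reading as well; it is
available behind `per_feature_threshold=True`, with the cumulative prefix
as the default.  Selected sets are nested across iterations by
construction; an iteration that would empty the set keeps the top-1
feature and stops with a warning.

One property worth stating explicitly: multiplying a column by a positive
gate cannot change the split set of an exact greedy tree (splits are
order-based), so the gates influence the ranking only through degenerate
(zero) weights and through the joint training signal that the selection
loop exploits across iterations.  The tree regularization, not the gate
magnitudes, is what suppresses noise columns within one iteration.

## Class balancing

SMOTE: synthetic minority rows are X_i + λ(X_i^NN − X_i) with
λ ~ U(0, 1) and X_i^NN one of the k = 5 nearest same-class neighbours by
Euclidean distance on z-scored features.  Original rows are preserved
verbatim, all classes are raised to the majority count by default, and a
class with ≤ k rows is an error naming the class.  Balancing is applied
to training folds only; validation and test rows are never resampled.

## Fast-ABC Boost

Multi-class LogitBoost with a sum-to-zero score matrix F and
p = softmax(F).  With base class b fixed, the per-sample derivatives in
the direction of class k are

    g_i = (r_ib − p_ib) − (r_ik − p_ik)
    h_i = p_ib(1 − p_ib) + p_ik(1 − p_ik) + 2 p_ib p_ik,

and a 20-leaf regression tree (min leaf 5) is fit per non-base class with
second-order split gain and Newton leaf values −Σg/(Σh + 1e-12), scaled
by ν(K−1)/K; the base column absorbs the negated sum.  Split search is
delegated to a weighted-MSE tree on the ratio target −g/h with Hessian
sample weights, which reproduces the second-order gain ordering; leaf
values are recomputed exactly.  Trees are stored as plain arrays so a
trained model is self-contained JSON.

Base-class scheduling: classes are ranked by per-true-class mean
log-loss ("worst" = largest); warm-up iterations (w) use the running
worst class without search; afterwards the s worst classes are each tried
for one tentative iteration and the lowest-loss candidate is kept, once
every g+1 iterations, reusing the previous base in between.  With s = K,
g = 0, w = 0 this degenerates to the classic exhaustive adaptive-base
search, and the test suite verifies bit-identical base traces and
predictions against an independently coded exhaustive oracle.  Training
stops early when the loss improvement drops below 1e-10.  Default
hyperparameters are the published configuration (ν = 0.4546, M = 645,
s = 3, g = 19, w = 34).

## INFO optimizer

The weighted-mean-of-vectors metaheuristic used for hyperparameter
tuning, in three stages per generation: an updating rule built from
fitness-weighted means of difference vectors (cosine-damped weights with
exponentially scaled fitness gaps, a scale factor that decays as
2·exp(−4g/G), and a convergence-acceleration term toward the best), a
stochastic vector-combining stage mixing the two candidate moves with the
current position, and a probabilistic local search around the global
best / mean position.  Candidates are clipped to bounds, non-finite
objectives are rejected, integer parameters are rounded at evaluation,
greedy per-member replacement makes the best-so-far history monotone, and
an evaluation budget can cap the total cost.  The published description
of the algorithm is qualitative; the stage formulas here follow the
original weighted-mean-of-vectors design and are documented in-code.
Any minimizer with the same `optimize(space)` interface (e.g. random
search) can substitute in experiments.

## Evaluation

Class order is fixed to (N1, N2, N3, REM, W).  Per-class precision,
recall and F1 use one-vs-rest counts; overall metrics are the accuracy,
unweighted macro averages, and the multi-class Cohen kappa with
pe = Σ row_k·col_k / n².  The macro choice for the overall
precision/recall/F1 is a documented convention: the published per-class
values and accuracies are reproduced exactly from the printed matrices,
but the printed *overall* precision/recall/F1/kappa of those tables are
not jointly consistent with any single aggregation of the printed counts
(they presumably average over folds whose matrices were not published),
so only accuracy and per-class values are asserted.  Display rounding is
half-up to two decimals, matching the source tables.

The harness provides a stratified 8:2 split and stratified five-fold
cross-validation in which selection, SMOTE and classifier training all
run inside each training fold; reported metrics are across-fold means,
with the pooled confusion matrix also emitted.

## Problem sizes and defaults used by the shipped checks

The test suite and `scripts/acceptance.py` run the selector recovery at
n = 2000 with 230 columns (5 and 3 seeds respectively), the detection
benchmark on six 2-minute nights at 10 dB SNR, the equivalence check at
n = 500 for 10–12 boosting iterations, and the simulated-night
cross-validation on one 8-h night (960 epochs) with reduced boosting
(60 rounds, ν = 0.3, search every 10) — the published 645-round
configuration is the shipped default for real use, while the reduced
setting keeps the night benchmark proportionate to a synthetic,
perfectly-labelled task it solves comfortably.

## Known limitations

* The attention gates are informative in aggregate but weakly separated
  per feature; the iterative loop and tree regularization do most of the
  pruning (see the scale-invariance note above).
* Breath-derived 30-s features are sparse (6–8 intervals); several are
  structurally missing and imputed, which real-data users should keep in
  mind when interpreting BB-column importances.
* TINN/HTI at 30 s rest on ~30 intervals — the histogram is coarse and
  the triangular fit is correspondingly noisy.
* The simulator's stage separability is optimistic; simulated-night
  accuracies near 1.0 say nothing about clinical performance.
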