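# Methods

This note documents the models and procedures `roarbout` implements, the
choices made where the design was genuinely open, and what the synthetic
corpus does and does not establish about field data.

## F0 extraction

A lion call's fundamental frequency lies between roughly 30 and 375 Hz.
Extraction proceeds in two steps on a mono clip:

**Bandpass.** Default is a 4th-order Butterworth bandpass applied
forward–backward (`sosfiltfilt`), i.e. zero phase and ~48 dB/octave
effective rolloff; an alternative `fft_hann` mode masks an STFT computed
with a 2048-point Hann window at 68% overlap and inverts it by
overlap-add. Both attenuate by well over 40 dB one octave outside the
band; contours record which mode produced them. The Butterworth default
was chosen because autocorrelation pitch estimation benefits from a
phase-linear passband; the FFT mask is retained for comparability with
overlap-add toolchains.

**Windowed autocorrelation.** Frames of 128 samples (8 ms at 16 kHz)
advance by half a window. A frame yields an estimate only if its peak
absolute amplitude reaches the clip's 99th amplitude percentile (the
"top 1%" gate); gated frames are dropped rather than interpolated —
downstream HMMs do not require uniform frame spacing. Per retained
frame, the normalized cross-correlation r(l) between the frame and the
signal shifted by lag l is evaluated for l in
[round(rate/f_high), round(rate/f_low)] (27…533 samples at the default
band), using signal beyond the frame's end so that lags longer than the
window remain measurable. F0 = rate / l*.

*Peak selection.* For periodic signals every integer multiple of the
true period scores within noise of the global maximum, so taking the
argmax would fall to a subharmonic about half the time. l* is therefore
the **shortest-lag local maximum within `peak_tolerance` (default 0.02)
of the global maximum**; exact float ties across a plateau resolve to
the longer lag (the lower frequency). The tolerance sits ~2 standard
errors above the correlation noise floor at 20 dB SNR with 128-sample
support.

*Precision.* The estimator is quantized to integer lags; one lag step
corresponds to rate/(l(l−1)) Hz. The median estimate on rendered
harmonic stacks at 20 dB SNR is within one step across 40–350 Hz.
Frame-level precision is physics-limited at the low end: near 60–80 Hz
the correlation peak's curvature (2πf/rate)²/2 falls below the
correlation noise at this SNR and window, so individual frames scatter
over ±2–3 lags (still <1 Hz). Tests assert a median within one step
everywhere, ≥90% of frames within two steps, and ≥90% within one step
above 100 Hz.

## Two-state Gaussian HMMs

Each call type's (or each lion's) F0 dynamics are modelled by a hidden
Markov chain with two states, initial distribution π, transition matrix
A, and per-state Gaussian emissions N(μ_k, σ²_k) in Hz. Two states
capture the coarse temporal structure that distinguishes the call types:
an arched roar visits a low flank state and a peak state with sticky
transitions; a flat moan effectively occupies one regime; a grunt pulse
switches quickly.

* **Likelihood** — exact forward algorithm with per-frame scaling (and a
  per-frame max-subtraction on the emission densities), numerically safe
  to at least 10⁵ frames. Verified to 1e−10 against exhaustive
  enumeration over all 2^T paths for T ≤ 8, and against an independent
  library implementation.
* **Fitting** — Baum–Welch EM over multiple independent sequences,
  vectorized across sequences (padded + masked). Convergence when the
  relative log-likelihood change is ≤ 1e−6, cap 100 iterations.
  Emission variances are floored at 1 Hz² to prevent collapse onto
  repeated values.
* **Restarts** — each restart draws means uniformly from the pooled
  data's 5th–95th percentile range, sets variances to the pooled
  variance, and draws π and the rows of A from Dirichlet(5,5); the
  restart with the highest final log-likelihood wins. 1000 restarts
  reproduce the full field protocol; the desk default is 5 (the
  likelihood surface for these well-separated 2-state problems is
  benign, and in practice 3–5 restarts find the same optimum).

## Leave-one-out protocols

**Call types.** Classes are first balanced by downsampling without
replacement to the smallest class. Each call is held out once; an HMM
per class is trained on the remaining calls of that class and the call
is assigned to the argmax log-likelihood class (ties, probability zero
for continuous data, break by alphabetical class order and are logged).
The whole procedure repeats `n_repeats` times with fresh
initialisations; confusion counts are averaged over repeats (a
majority-vote aggregation is available). Only the held-out call's own
class model changes between folds, so the other class models are fitted
once per repeat.

**Individuals.** The unit of cross-validation is the bout, which keeps
temporally autocorrelated roars of one bout on one side of the split. A
bout's score under a lion's HMM is the sum of its FTR contours'
log-likelihoods (calls treated as independent); a concatenation mode is
provided as an option. Lions with fewer than two bouts after roar
selection cannot be cross-validated and are dropped with a warning.

**Warm-started folds.** By default the held-out fold's model is
EM-refined from the corresponding full-class parameters rather than
refitted from fresh restarts: removing one unit from a class barely
moves the optimum, EM still maximises the training-only likelihood, and
the refit converges in a few iterations. `exact_loo=True` restores full
random-restart refits; on separable data the two agree exactly (tested).

## Metrics

Performance is computed from the true×predicted confusion matrix (counts
may be fractional after repeat-averaging). Per class, one-vs-rest
TP/FP/TN/FN feed the four formulas: accuracy (TP+TN)/(TP+TN+FP+FN),
recall TP/(TP+FN), precision TP/(TP+FP), F1 = 2PR/(P+R). Micro
averaging pools the four counts over classes before applying the
formulas; macro averaging is the unweighted mean of per-class values.
Two conventions are made explicit because they matter for multiclass
problems: (1) the TN-inclusive accuracy above exceeds plain
fraction-correct for k > 2 (for uniform random 4-class prediction it is
0.625 while fraction-correct is 0.25), so reports always print both;
(2) a class never predicted gets precision 0 (logged), rather than NaN.

## K-means call typing

Duration and maximum frequency are standardized per dataset (mean-centred,
divided by the sample SD with n−1 denominator — never pooled across
study sites, whose feature distributions differ) and clustered by
k-means (Lloyd iterations, best inertia of `n_init=10` seeded starts).
Two mappings from anonymous clusters to call types are used, and they
are deliberately distinct:

* **evaluation** (labels available): the agreement-maximising one-to-one
  assignment via the Hungarian algorithm on the cluster×label
  contingency table;
* **application** (no labels, k=3 after moan removal): rank centroids by
  unstandardized duration — longest = FTR, middle = IR, shortest =
  grunt. This codifies the "pick the long, high cluster" visual rule so
  the FTR selection needs no expert in the loop.

The pipeline refuses k=3 while labeled moans are still present: moan
removal is the analysis's one manual step, and silently clustering moans
into three roar classes would corrupt the FTR selection.

## Synthetic corpus

The generator emulates the statistical structure the analysis assumes,
with controllable ground truth. It is a parametric stand-in — its
templates are not fitted to any real recordings, and no default is an
estimate of a real population's parameters.

* **Grammar** — bouts are moans → FTRs → IRs → grunts with per-type
  count ranges (1–3, 2–5, 2–5, 4–10) and positive inter-call gaps, so
  IRs always follow FTRs and precede grunts.
* **Features** — per-call duration and max frequency are Gaussian per
  type; defaults (duration s, max freq Hz): moan (1.2, 110), FTR
  (1.0, 320), IR (0.5, 210), grunt (0.15, 120). Moans get deliberately
  large scatter (SD 0.45 s, 45 Hz) so they straddle the roars in
  duration while sitting low in frequency — the qualitative geometry
  that makes moan removal necessary. A `separation` knob moves the type
  means toward/away from their grand mean in units of a (0.117 s,
  30 Hz) reference scatter; 3 (the default) reproduces the default
  layout, 0 collapses all types onto identical means.
* **Contours** — piecewise-linear templates in log-F0 sampled every 4 ms
  (the extractor's hop): roars rise to the call's max frequency over
  ~25% of the call and fall to ~60% of peak; moans are quasi-flat at
  ~50% of their nominal max frequency with a slow wobble; grunts are
  brief symmetric pulses. Gaussian frame jitter of 4 Hz is added.
* **Individual signatures** — each lion scales its peak F0
  (multiplicative spread of 20% across lions by default), its arch rise
  fraction (0.7–1.3×, interleaved so lions adjacent in pitch differ in
  shape) and its call durations (±5%). Within-lion call-to-call scatter
  is kept below the between-lion spread, which is the premise that makes
  FTRs individually identifiable at all.
* **Audio** — a contour can be rendered as a harmonic stack (amplitude
  1/k on harmonic k) plus white noise at a chosen SNR, for end-to-end
  tests of the extractor.
* **Seeding** — bout (i, j) is generated from
  `SeedSequence(seed, spawn_key=(i, j))`, so any subset of a corpus
  regenerates bit-identically.

**What passing tests show — and don't.** On this corpus the pipeline
recovers planted structure: ≥95% k=3 clustering accuracy and ≥90%
leave-one-out HMM call-type accuracy at 3-SD class separation, moans
hurting the k=4 run, and macro F1 > 0.9 for individual identification at
a ≥15–20% planted peak spread. These are parameter-recovery results
under Gaussian features, clean grammar, and no chorus overlap, call
truncation, propagation loss or recorder noise floor; they validate the
implementation, not the field difficulty of the task. Field performance
depends on real inter-individual variation, annotation quality and
recording conditions that the generator does not model.

## Problem sizes and defaults

Desk-scale defaults keep every experiment interactive: 5 EM restarts, 10
repeats of the LOO protocols (the full field protocol's 1000×1000 is
reachable by flags), corpora of 5 lions × 10 bouts (~700–850 calls), 40
calls per class for balanced call-type runs. The acceptance script uses
3 restarts, 3 repeats (call types) and 2 repeats (individuals) at these
corpus sizes.

## Known limitations

* The F0 estimator has no octave-cost continuity tracking across frames;
  isolated octave errors survive in low-SNR frames (the amplitude gate
  removes most).
* Two HMM states are fixed by design; no model-order selection is
  offered.
* The duration-rank heuristic assumes the k=3 clusters genuinely contain
  an FTR-like longest cluster; on corpora without FTRs it will still
  name one cluster "full_throated_roar" (a warning is logged).
* Bout grammar is deterministic in stage order; real bouts occasionally
  interleave or truncate stages, which the generator does not simulate.
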