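# Methods

This note documents the models, estimators and design choices behind
`prvarr`, including the places where the underlying procedure is
under-determined and a concrete choice had to be made.

## Signal model and denoising

The observed waveform is modelled as a train of pulse waves plus three
additive disturbances: mains-frequency AC interference, slow baseline
drift (< 0.5 Hz) and broadband EMG-like noise (> ~70 Hz). Both filters
are designed around integer arithmetic so the recursion is exact and
implementable in fixed point.

**Notch.** `F1(z) = z^(-N(R-P)/2) - [(1 - z^-R)/(Q(1 - z^-P))]^N` is an
all-pass branch minus a comb band-pass. Since `R = PQ`, the ratio
`(1 - z^-R)/(1 - z^-P)` is the polynomial `1 + z^-P + ... + z^-(R-P)`,
so the filter is exactly FIR (length `N(R-P) + 1`, symmetric, hence
exactly linear-phase) even though it is evaluated as a rational
recursion. Its magnitude vanishes at 0 Hz and every multiple of
`f1 = fs/P`: the same structure removes drift (0 Hz tooth) and mains
harmonics. The frequency response is evaluated in the factored closed
form `H1(w) = e^{-jwN(R-P)/2} (1 - [sin(wR/2)/(Q sin(wP/2))]^N)` with the
removable singularities at multiples of `fs/P` filled by their limits
(`±1` by l'Hôpital, sign depending on the harmonic index and parity of
`Q`). `Q` must be a power of two (divisions become bit shifts); the
default design is `N = 2`, `Q = 64` at 250 Hz.

**Low-pass.** `F2(z) = [(1 - z^-C)/(C(1 - z^-1))]^N` is an `N`-fold
cascade of a length-`C` moving average, run as the first-order recursion
`y(n) = y(n-1) + (x(n) - x(n-C))/C` applied `N` times. DC gain is
exactly 1; the first null sits at `f2 = fs/C`.

**Cascade and start-up.** `preprocess` applies notch then low-pass
(order is immaterial for LTI filters; this order is fixed for
reproducibility), then advances the output by the combined group delay
`N(R-P)/2 + N(C-1)/2` (315 + 3 = 318 samples for the defaults) so beat
positions align with the raw record. Filter states start at zero; the
first `settle - delay` output samples (318 for the defaults, ~1.3 s)
are flagged as transient on the record and excluded from beat
detection. Records shorter than the combined transient trigger a
warning.

A consequence worth knowing: the 0 Hz tooth removes not only drift but
any rate-episode-induced shift of the local mean level (a tachycardia
run raises the short-term average pressure level). Passband fidelity
(correlation > 0.99 with the raw signal after delay compensation) holds
for steady pulse trains; records with embedded episodes read lower for
this legitimate reason.

## Pulse-peak detection

Systolic peaks are detected on the preprocessed waveform in six steps:

1. band-limit to 0.5–10 Hz (order-2 Butterworth, zero-phase) — the
   pulse fundamental and first harmonics of any plausible rate;
2. collect local-maximum candidates spaced at least half the refractory
   period (the band-passed positions of closely spaced pulses shift
   toward each other; the true refractory is enforced later);
3. gate by sliding band energy (0.3 s window, ≥ 2% of the record
   maximum) and by an adaptive amplitude threshold
   (moving median + k·MAD over 2 s, k = 1);
4. keep candidates whose peak prominence is at least 20% of the largest
   candidate prominence within ±2 s — dicrotic bumps are never
   prominent next to their systolic peaks, while the reduced-amplitude
   beats of ventricular rhythms are;
5. snap each survivor to the local maximum of the (lightly smoothed,
   ~36 ms boxcar) filtered waveform and deduplicate within the 0.2 s
   refractory (300 bpm ceiling), keeping the taller peak;
6. secondary-wave rejection: drop a peak if a ≥ 2× taller peak precedes
   it within 0.34 s *unless* a comparable-size peak also follows within
   the same window — the signature distinguishing a dicrotic wave
   (follows one big systole, then nothing) from the crests of a genuine
   rapid low-amplitude oscillation such as ventricular flutter, which
   are preceded *and* followed by similar crests.

Step 4 was added after the median + MAD threshold alone proved unable to
reject dicrotic bumps in slow rhythms (their local maxima clear any
location-scale threshold that still admits reduced-amplitude VT beats);
step 6 handles the one case prominence cannot (a free-standing dicrotic
bump between widely spaced slow beats). Records carrying trusted beat
annotations can bypass detection (`use_annotations=True`), the
programmatic replacement for manual calibration of mis-detected peaks.

The detector is deterministic: identical input yields bit-identical
peak series.

## Beat series and segmentation

`PRV(i) = 60 fs / (Peaks(i+1) - Peaks(i))` bpm, `PPI(i)` the same
interval in ms (so `PRV·PPI = 60000` identically), `APM(i)` the
filtered-signal value at the leading peak. Segments are fixed-length
overlapping windows (default 16 beats, step 1); 8 beats is the hard
minimum on which all 19 features are defined. Windows inherit the
record's class label.

## The feature battery

Time-domain statistics use the sample (n−1) normalisation for Std, and
the same n−1 denominator for the RMS of successive differences. PNN40
and PNN70 are computed on successive-interval differences in
milliseconds (the thresholds are times), with the number of difference
pairs as denominator, and reported as fractions in [0, 1]. The
interquartile statistic is the *ratio* S75/S25 (quartiles by linear
interpolation): on a rate series it clusters near 1 and is
scale-invariant, which is the behaviour the downstream selection
expects; a quartile difference would simply duplicate Std.

**LF/HF.** The interval series is resampled at 4 Hz by linear
interpolation on the beat-time axis, and the spectrum estimated with a
Burg autoregressive model of order 16; LF = ∫ PSD over 0.04–0.15 Hz,
HF over 0.15–0.4 Hz. A segment must span at least 25 s (one LF cycle);
shorter segments — most 16-beat windows at normal rates — carry the
missing-value sentinel. Two known estimator limitations: linear
interpolation attenuates the upper band when the beat rate is low
(a standard HRV resampling caveat), and the AR band split is unreliable
on pure line spectra (real, noisy interval series are well behaved; the
tests regularise synthetic sinusoidal cases with broadband jitter).

**Poincaré.** `Sd1 = sqrt(Σ (S(i+1)−S(i))²/2 / (n−1))` and
`Sd2 = sqrt(Σ (S(i+1)+S(i)−2·Mean)²/2 / (n−1))` as printed in the
source formulas (note these are the dispersions perpendicular to and
along the identity line of the lag-1 return map; the conventional
short/long-axis naming is the reverse of the labels used here, which
follow the formulas). `Se = π·Sd1·Sd2`; the ratio is sentinel when
`Sd2 = 0` (constant or perfectly alternating series).

**Entropies.** Sample entropy uses embedding `m = 2`, Chebyshev
distance, self-matches excluded, both template lengths counted over the
same `n − m` start points; the tolerance is `r = 0.25 × Std(segment)` —
the fraction-of-Std reading of the bare "0.25", which is standard
practice and keeps the statistic scale-free (an absolute tolerance is
configurable). Zero matches at either length yield the sentinel, never
an infinity. CSampEn adds `ln(2r) − ln(mean)` on the same units as the
input series. Shannon entropy uses 16 equal-width bins over the segment
range, normalised by log2(16) to land in [0, 1] (both configurable);
the bin count is the smallest power of two that still resolves a
16-beat window without being mostly empty. Permutation entropy uses
order `m = 5` with natural logarithm (alphabet 5! = 120; ties broken by
position via a stable sort); order 5 matches the few-nats scale
expected of beat-rate series while remaining computable on short
windows.

**Missing values.** Degenerate features return a documented NaN
sentinel, produced only on the explicit degenerate branches. Learners
impute sentinels with training-split medians (features entirely missing
in training fall back to zero) — fitted on the training split only, so
no test information leaks.

## Feature selection

A bagged forest of 100 CART trees (`mtry = floor(sqrt(p))` = 4 features
tried per split) is fitted with explicit bootstrap handling so both
canonical importance scores are available: *mean decrease in accuracy*
(per tree, the drop in out-of-bag accuracy when one feature column is
permuted, averaged over trees) and *mean decrease in Gini* (total
weighted impurity decrease of all splits on the feature, averaged over
trees). Features are ranked by the mean of the two rank positions (ties
broken by the accuracy score) and the top k = 15 of 19 are kept. The
bagging is hand-rolled over library trees because the library forest
does not expose out-of-bag permutation importance.

## Classifiers

* **Decision tree** — CART, Gini criterion, grown to purity (no depth
  limit, minimum leaf 1); all hyperparameters exposed.
* **ELM** — input weights `IW ~ U[−1, 1]^(300×p)` and biases
  `B ~ U[0, 1]` drawn once from the seed; hidden layer
  `H = sin(X·IWᵀ + B)`; output weights `LW = pinv(H)·T` for one-hot
  targets `T`; prediction is the argmax over output columns. Features
  are z-scored on the training split first — a sinusoidal projection of
  raw features spanning four orders of magnitude aliases into noise.
  `LW` is checked in the tests against a direct least-squares solve.
* **BPNN** — two sigmoid hidden layers of 15 units, softmax output over
  the 5 classes, L-BFGS (quasi-Newton) training, at most 3000
  iterations, tolerance 1e−3; both hidden layers use the sigmoid (the
  activation of the first layer is under-determined in the source
  description; one choice is fixed and configurable). A zero-iteration
  budget returns an untrained random-initialisation network (chance
  baseline); non-convergence returns a usable model flagged
  `converged=False` with a warning.

Input width is always the number of selected features and the output
is the 5-class one-hot/argmax — the only reading under which the
printed layer sizes can consume the printed feature vector.

## Evaluation

Multi-class accuracy is `trace(Q)/M × 100` (the binary TP/TN form
generalised). Cohen's kappa uses observed agreement `p1 = trace(Q)/M`
and chance agreement `p2 = Σ_t Q_{t+} Q_{+t} / M²` with `M` the total
evaluated count and the sums over classes — the only normalisation
under which the statistic lands in [−1, 1]. The per-class variant is
implemented exactly as
`(P_tt − P_t+·P_+t)/(P_+t − P_t+·P_+t)`; the denominator is
asymmetric (column margin, not row margin), and that asymmetry is kept
as printed. Degenerate denominators (chance agreement 1; a class never
true and never predicted) return NaN.

The protocol is repeated uniform-random 80/20 hold-out over segments
(default 100 repetitions; 10 in the bundled acceptance run, which is
ample at these effect sizes), retraining from scratch each repetition,
reported as mean ± SD. Splitting is over segments because the feature
vectors are the sampling unit of the protocol; a group-wise mode
(`groups=` record ids) is available for subject-level generalisation
questions — expect lower numbers there, since segment-wise splits let
windows from one record appear on both sides.

## Synthetic data generator

The generator emulates the *observable structure* of the five rhythm
classes, not hemodynamics:

* **Background rhythm**: beat rate = base (70 bpm) + AR(1) modulation
  (coefficient 0.8, stationary SD 3 bpm), clipped to 45–95 bpm.
* **Episodes** (one per record, after a 6-beat lead-in): EB 8 beats at
  ~33 bpm (rates clipped below 38.8 so every beat is under the 40 bpm
  definition with margin); ET 18 beats at ~160 bpm (clipped above
  144.2); VT 10 beats at ~130 bpm with pulse amplitude halved; VF a 5 s
  raised-cosine oscillation at 4.5 Hz and 30% amplitude replacing the
  pulses, phase-locked so one crest falls on each annotated beat, fading
  in/out at troughs. Every generated record satisfies its defining
  inequality symbolically on the programmed interval sequence (tested).
* **Pulse shape**: systolic Gaussian (width 0.05 s) plus a dicrotic
  Gaussian (width 0.12 s) at 40% amplitude, offset 0.3·PPI capped at
  0.3 s — uncapped, slow rhythms would grow a free-standing late bump
  no physiological dicrotic wave shows. Per-beat amplitude jitter 5%;
  DC offset 80 (mmHg-like units with unit pulse amplitude).
* **Beat times** are quantised to the sampling grid (the resolution at
  which any detector can observe them), making the programmed interval
  sequence exactly renderable; annotations are snapped to the rendered
  local maxima.
* **Noise classes**: 50 Hz AC (amplitude 0.2), two drift sinusoids at
  0.05 and 0.1 Hz (amplitude 0.3 each — frequencies where the 0 Hz
  notch tooth still attenuates strongly), and high-passed white noise
  above 70 Hz (SD 0.1), all relative to unit pulse amplitude, with
  random phases per record.

Defaults were chosen once as representative of resting monitoring
conditions with visible but realistic contamination. What passing tests
on this generator do **not** show: robustness to motion artifacts,
sensor saturation, morphology pathologies (pulsus alternans, aortic
regurgitation waveforms), missed-beat runs, or mains frequency drift —
real validation needs recorded patient data.

A note on the VF default: the oscillation runs at 4.5 Hz rather than
the flutter-band midpoint 5 Hz because at 250 Hz sampling a 5 Hz crest
spacing (200 ms) sits exactly on the 300 bpm refractory floor, leaving
the detector zero margin; 4.5 Hz stays inside the 4–6 Hz flutter band
with a 10% margin.

## Numerical and testing choices

* Filter outputs are checked against two independent oracles: the FIR
  kernel obtained by exact polynomial long division, and a naive
  direct-form recursion written in the tests.
* All entropy/dispersion statistics are checked against brute-force
  enumeration oracles on hundreds of random short inputs (exact to
  1e−9 or better).
* The end-to-end check runs 2000 segments (400 per class): a scale at
  which the repeated-hold-out means are stable to well under a
  percentage point, while the whole suite stays fast.
* Round-trip accuracy through generator → filters → detector → PRV is
  bounded at two samples (8 ms at 250 Hz) per interval, the stated
  budget for downstream feature fidelity.
* Seeds flow through `numpy` `SeedSequence`/`default_rng` everywhere;
  identical seeds give identical datasets, splits, forests and reports
  (bit-identical for the deterministic classifiers).

## Known limitations

* The detector is tuned for resting-condition contamination; it has no
  motion-artifact stage.
* LF/HF is undefined (sentinel) on windows shorter than 25 s, i.e. on
  most short windows at normal rates — by construction, not by bug.
* Per-class kappa follows the printed asymmetric formula; it is not the
  symmetric per-class kappa found in some texts.
* The synthetic generator's five classes are far more separable than
  ICU data; headline accuracies on it say the pipeline is implemented
  correctly, not that the method achieves such numbers clinically.
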