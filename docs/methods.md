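# Methods

`connspeech` implements a fully automated analysis chain for connected
speech — reading passages and monologues — aimed at the timing,
articulation, phonation and respiration deficits of hypokinetic
dysarthria in Parkinson's disease (PD) and its prodromal stage (REM
sleep behaviour disorder, RBD). This note documents the models, the
numerical choices, and what the synthetic test bed does and does not
establish.

## Preprocessing

Recordings of any rate ≥ 8 kHz are decimated to 8 kHz (polyphase
resampling, anti-aliasing built in) and high-pass filtered at 130 Hz
with a 4th-order Chebyshev filter, removing mains hum and subsonic
pops while emphasizing voiced speech. Two choices the published
constants leave open are made explicit and configurable:

* **Filter family**: Chebyshev type I, 0.5 dB passband ripple
  (`hp_ripple_db`). Type I is the default reading of "Chebyshev
  filter"; the ripple value is recorded in the output metadata.
* **Phase**: applied forward–backward (zero phase). Segment boundaries
  feed duration features, so systematic group delay is unacceptable;
  the doubled effective order is accepted and documented.

## Frame parameterization

A 15 ms window advanced in 5 ms steps yields per frame:

* **PWR** = log₁₀ of the Hamming-weighted mean power,
* **R_x[k]**, the mean-removed, variance-normalized (biased)
  autocorrelation,
* **ACR** = log₁₀ of the sample variance of R_x — high for periodic
  frames. (The source equation as printed sums unsquared deviations,
  which is identically ~0; the accompanying text twice defines ACR as
  the *variance* of the normalized autocorrelation, which is what is
  implemented.)
* **ZCR** = log₁₀ of the sign-change rate of R_x with sign(0) = +1.
  Counting crossings on the autocorrelation rather than the raw signal
  suppresses the noise component of voiced consonants.
* **LFCC**: first 5 of 24 linear-frequency cepstral coefficients
  (half-overlapping triangular filters, 0–4000 Hz, log energies,
  DCT-II). Indexing is 1-based *including* the DCT order-0 term, so
  LFCC₁ tracks loudness.
* **MFCC**: 24 Mel-frequency coefficients, same indexing; MFCC₂
  measures the low-vs-high Mel-band energy balance and is gain
  invariant.

Log floors are ε = 10⁻¹⁰ (log base and floor are immaterial to
clustering; the floor avoids −∞ on silence). FFT size is the next
power of two ≥ the window length.

## Adaptive sequential segmentation

Classes are recognized class by class inside long recognition windows,
which makes every decision relative to the local speaker and noise
statistics (no absolute thresholds; doubling the input gain changes
total voiced duration by < 0.1 % in tests):

1. **Voiced** — GMM clustering of (PWR, ACR, ZCR) in 20 s windows / 6 s
   steps; the component with the highest mean PWR is voiced. Decisions
   smoothed by a 5th-order median filter, then voiced runs < 30 ms are
   dropped and voiceless runs < 20 ms refilled.
2. **Unvoiced** — frames in voiceless runs < 300 ms (excluding most
   respirations) clustered on LFCC₁..₅ in 60 s windows / 20 s steps.
   Runs < 5 ms, and runs farther than 30 ms from voiced speech, are
   rejected.
3. **Respiration** — residual runs > 200 ms clustered the same way;
   the loudest component is respiration. Runs < 40 ms are rejected,
   runs within 30 ms of voiced speech are reassigned to unvoiced
   speech (inspiration is bounded by silence), and gaps < 400 ms
   between respirations are merged.
4. **Pause** — the complement of voiced and unvoiced speech (pauses
   include respirations); runs < 30 ms are absorbed into the longer
   adjacent speech interval.

The number of mixture components per window (2 or 3) is chosen by the
Calinski–Harabasz index computed on the hard assignments of candidate
fits; EM uses k-means++ initialization with a fixed seed, full
covariances and an escalating ridge on degeneracy. Overlapping window
decisions are combined per frame by majority vote, ties resolved by the
earliest window. Windows shorter than one recognition window are
processed as a single window.

Three implementation decisions the published description leaves open:

* **Two-fraction reading for the unvoiced stage.** Each recognition
  step separates the pool into two fractions. When three components
  are selected in the unvoiced stage they typically capture fricatives,
  stop bursts and silence; labelling only the single loudest component
  as speech discards a whole consonant class, so every component except
  the quietest is taken as unvoiced speech. The respiration stage keeps
  the strict loudest-only rule.
* **Boundary-contaminated frames.** Frames within two steps of a
  voiced boundary still contain voiced energy inside their 15 ms window
  and would form a spurious loud cluster; they are excluded from the
  unvoiced-stage clustering (`edge_guard`).
* **Interval timing.** A frame's decision refers to its window center;
  run boundaries are placed midway between consecutive frame centers.
  Mapping decisions to frame start indices instead biases every
  boundary ~10 ms early — enough to push short stop-closure pauses
  outside their evaluation tolerance.

## The 12 features

Pauses longer than 2 s are saturated to 2 s before any feature is
computed. Interval *occurrence* is the mean of start and end time.
Undefined features (too few intervals of the needed kind) are NaN,
never zero.

| Feature | Definition | Units |
|---|---|---|
| RST | OLS slope of cumulative count of voiced+unvoiced+pause intervals vs occurrence time | 1/s |
| AST | (RST of second halftime − RST of first) / total duration; halftimes are [0, 0.625 T] and [0.375 T, T] (equal halves sharing 25 % of T) | 1/s² |
| DPI | median pause duration | ms |
| EST | Shannon entropy of the four interval-class counts | bits (≤ 2) |
| DUS | median duration of the smaller-mean component of a 2-mode GMM on unvoiced durations (stops are shorter than fricatives) | ms |
| DUF | 1000 · (mean fricative MFCC₂ of halftime 1 − halftime 2) / T; fricatives are the larger-mean duration mode per halftime | ‰ |
| DVI | mean voiced-interval duration | ms |
| GVI | count of the smaller-mean mode of pauses flanked by voiced speech on both sides and containing no respiration, per total time | 1/s |
| RSR | 60 / median spacing of respiration mid-times | breaths/min |
| PIR | median count of pause mid-times between consecutive respiration mid-times | count |
| RLR | median loudness (10·log₁₀ of the 120-point moving average of x² at 8 kHz) over respiration minus over speech samples | dB |
| LRE | mean latency from end of nearest preceding speech interval to respiration start | ms |

Mode assignments (DUS smaller mean = stops, DUF larger mean =
fricatives, GVI smaller mean = clear gaps) are the physiologically
natural readings and are config-overridable. DUF's normalization "per
total duration" uses the recording duration T, the same denominator as
AST.

## Evaluation

Detections are scored against reference labels with per-label
tolerance fields: ±d/4 around each boundary for a pause of duration d,
±d for respirations. Pairing is one-to-one, greedy by smallest summed
boundary distance (verified in tests to coincide with the exhaustive
optimal assignment on random configurations). Unpaired references are
FN, unpaired detections FP; efficiency is the F-score, also reported
stratified by a progressive minimum reference duration from 50 to
300 ms (references below threshold are dropped together with the
detections matched to them). With zero detections precision is
reported as 0 with a degenerate flag so cohort averages stay total.
Any callable `audio -> intervals` can be scored, so external baseline
detectors plug in without being bundled.

## Index test

Classification is quadratic discriminant analysis: one full-covariance
Gaussian per class fitted by maximum likelihood (the fixed point of EM
for a single Gaussian — numerically identical), priors = empirical
class frequencies, prediction by the Bayes rule with exact ties going
to the control class. Missing features are imputed with
training-pooled means, recomputed inside every cross-validation fold
so nothing leaks from the held-out subject. The feature subset is
chosen by greedy forward selection on leave-one-subject-out accuracy
(ties prefer smaller subsets, then lexicographic order); an exhaustive
mode over all subsets is available for ≤ 12 candidates and is used to
validate the search against brute force. The learned pattern is
transferred to a held-out cohort and scored against the motor
dichotomization UPDRS III* > 3 (score of exactly 3 is motor negative).

## Synthetic test bed

No recordings from the original cohorts are deposited, so the package
ships a generator whose class-conditional acoustics match the axes the
segmenter discriminates on: voiced speech is an impulse train at f0
(default 120 Hz) through ~500 and ~1500 Hz resonators (periodic, high
ACR, low ZCR); fricatives are noise high-passed above 2.5 kHz; stops
are a closure (background noise only, ground-truth labelled as pause,
consistent with the annotation rule that a pause before an explosive
consonant ends at its burst) followed by a broadband burst; pauses are
background noise (default −40 dB re voiced, a quiet room);
respirations are 500–2000 Hz band noise (−18 dB re voiced) placed only
inside pauses ≥ 300 ms with ≥ 100 ms margins. Interval durations are
lognormal (median, log-sd); the `pd_like` preset multiplies pause
medians ×1.5, stop durations ×1.4, voiced medians ×1.2 and lowers
respiration by 6 dB — the direction of the group effects the features
target. Cohorts contain two tasks per subject: a fixed-sequence
"reading" (default 20 s) and a random-sequence "monologue" with 25 %
longer pauses (default 25 s). These durations are deliberately shorter
than real task recordings (~30–90 s); they keep cohort-scale
experiments fast while leaving every recognition window code path
(single-window fallback included) exercised.

What passing on this bed shows: the clustering separates the classes
it was designed to separate, the rule cascade and tolerance-field
scoring are implemented correctly, features recover planted effects,
and the classifier transfers a real group difference. What it does not
show: performance on real dysarthric speech — the generator has no
coarticulation, no formant dynamics, no velar fricatives that mimic
breathing, no room reverberation, and its class transitions are
sharper than natural speech. Segmentation efficiencies near 1.0 here
are therefore an upper bound, not a field estimate.

## Known limitations

* The generator's presets are calibrated to the segmenter's duration
  gates, not to the statistics of any natural language.
* GVI's "clear gap" mode and the DUF halftime construction admit
  alternative readings; both are config-overridable and flagged for
  sensitivity analysis.
* The respiration stage assumes audible breaths exist; on recordings
  with none, residual noise can be promoted to respiration (the
  loudest residual cluster) unless it is silence-degenerate.
* No streaming mode; recordings are processed whole.
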