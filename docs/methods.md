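# Methods

`kittencall` re-implements, as a tested package, the acoustic-analysis
pipeline used to ask whether infant cat (kitten) isolation calls encode
*who* is calling (sender identity) and *how aroused* the caller is, and
whether different sets of acoustic parameters carry the two kinds of
information. Because no recordings of the original study design are
publicly available, the package pairs the analysis chain with a parametric
call synthesizer whose cohorts have known ground truth; every stage of the
pipeline is validated against that ground truth.

## 1. The synthetic call model

### Source–filter synthesis

Each call is rendered with a classical source–filter model:

* **Source.** A harmonic stack follows a rise–fall F0 contour. The contour
  has short plateaus at onset/offset (at MinF0) and at the peak (MaxF0);
  the rise and fall are power-law ramps `s(t)^gamma` whose exponent is
  solved per call so that the time-average of the contour equals the drawn
  MeanF0 *exactly* (a quadratic rise–fall cannot match an arbitrary
  (min, mean, max) triple — the published Low-condition triple sits at mean
  fraction 0.64 of the range, at the edge of what a quadratic permits).
  The contour is slope-limited with a 15 ms moving average so that only
  injected frequency jumps produce abrupt steps. Harmonic phases are
  coherent (pulse-like glottal excitation) and amplitudes fall at
  −6 dB/octave. Harmonics that would exceed 0.46 of the sample rate are
  muted sample-by-sample, so sweeping contours cannot alias.
* **Filter.** A cascade of second-order resonators at F1–F3 (drawn per
  call) plus a fixed fourth resonance at 16 kHz (bandwidth 3 kHz), which
  keeps the 0–20 kHz band realistic for the four formants a ~3.5 cm
  uniform-tube vocal tract supports below 20 kHz.
* **Envelope.** A raised-cosine hump peaking at the drawn relative peak
  position, resting on a floor of 0.15 of the peak so the onset/offset
  cross the 5 % segmentation criterion within a few milliseconds, with
  3 ms cosine edge ramps.
* **Noise.** A per-condition aperiodicity level (source noise, −30 dB for
  Low and −23 dB for High arousal, ±1.5 dB per call) plus a breathy
  onset/offset span (+6 dB noise over the harmonics for 0–20 ms in Low,
  10–40 ms in High). These two knobs realize the tonality contrast the
  per-condition targets state (voiced %, MaxHNR, consistency): tonality
  parameters are *measured* quantities that a synthesizer cannot set
  directly. Cohort files embed each call in Gaussian background noise at
  ~−26 dB relative to the call peak with 150 ms of padding, so the
  segmenter's amplitude criterion is genuinely exercised.

### Non-linear phenomena (NLP)

Injected per call with per-condition Bernoulli rates taken from the
published per-kitten prevalences (jump 20 %/10.6 %, chaos 38.9 %/28.9 %
for Low/High; subharmonics 0 %/18.3 % — absent from Low by design):

* **Frequency jump** — the contour is multiplied by a factor of 1.35–1.6
  (up or down) over a 12–30 % span of the call;
* **Subharmonic** — components at odd multiples of F0/2 are added at
  −13…−7 dB over a span covering roughly half the call;
* **Chaos** — formant-shaped noise at ~0 dB relative to the harmonics
  partially replaces the source over a 60–160 ms span, retaining a
  harmonic trace (as described for real chaotic segments).

### Cohort statistics

Per-call parameters are drawn as

    value = condition_target_mean + kitten_baseline_shift + within_noise,

truncated to physical bounds. The per-condition target means/SDs default
to the published Low/High condition tables for this species and age
(durations, inter-call intervals, F0 statistics, formant frequencies and
bandwidths, spectral peak, tonality). The (MinF0, MeanF0, MaxF0) triple is
drawn jointly (correlation 0.85) with rejection to guarantee ordering.
The kitten `baseline_shift` — the individual vocal signature — is drawn
once per kitten and reused identically in both conditions. With signature
ratio *r* (between-kitten / within-kitten SD; default 0.5) the split is
`sd_between = sd * r/sqrt(1+r^2)` and `sd_within = sd / sqrt(1+r^2)`, so
the total per-call SD always matches the published value. `r = 0`
switches signatures off for null simulations.

The default cohort mirrors the emulated study design exactly: 18 kittens
(9 male, 9 female, weights uniform in 246–370 g) in 6 litters, two arousal
conditions, 10 calls per kitten and condition except 3 and 5 Low-condition
calls for the last two kittens — 348 calls. One root seed drives
everything; per-call seeds are derived by stable hashing of (kitten,
condition, call index), so manifests are byte-identical across runs.

`sample_feature_table` draws the same cohort *at the distribution level*
(no audio), for statistical simulations where the measurement noise of
the audio chain is not the object of study.

### What the generator does not emulate

Perceptual realism of kitten voices; age development; amplitude
calibration (absolute SPL is unmodelled — the recording chain of the
emulated design was uncalibrated too); correlated parameter drift within a
session; reverberation and non-stationary background. Passing tests
therefore demonstrate that the *pipeline* measures what it claims on
signals with known truth — not that it would be noise-free on field
recordings.

## 2. Feature extraction (22 parameters)

* **Segmentation.** Calls are maximal runs of the 5 ms-smoothed rectified
  envelope above `background + 0.05 × (peak − background)` (background =
  10th envelope percentile), merging gaps < 40 ms and discarding runs
  < 30 ms. This is the deterministic stand-in for the manual
  oscillogram-based procedure with its 5 % amplitude criterion.
* **Time.** Duration (onset–offset), inter-call interval (next onset −
  this offset when calls share a recording; cohort pipelines take the
  manifest's ground-truth ICI since calls are stored one per file), and
  peaktime (onset to envelope maximum; stored in ms in the feature table,
  `time_params` also reports seconds — the source tables print 0.23/0.29,
  which we read as relative position in line with the documented
  ambiguity).
* **F0 (75–3000 Hz, 10 ms steps).** Normalised autocorrelation per 40 ms
  Hann frame (window ACF divided out), candidate local maxima scored with
  a small octave cost (+0.05 per octave toward higher candidates, enough
  to break the exact tie of a perfectly periodic signal without forcing
  harmonic locking), parabolic lag interpolation, voiced when the
  normalised peak exceeds 0.45, per-frame HNR = 10·log10(r/(1−r)).
  A repair pass then snaps frames locked onto an (almost exact) integer
  multiple/submultiple of the local median of high-HNR frames, and
  replaces frames > 1.9× the local median (resonance locking) with it —
  the automated analogue of the manual pitch-track checking the emulated
  protocol relied on. During strong subharmonics the tracker follows the
  doubled period; that is the physically correct reading and the
  subharmonic detector recognises it (below).
* **Source statistics.** Mean/SD over voiced frames with HNR ≥ 5 dB;
  Min/MaxF0 are the 2.5th/97.5th percentiles of those frames (robust
  extremes — one residual mistracked frame must not define the range).
  Voiced % counts all voiced frames; MaxHNR is the per-call maximum.
* **Formants (4 below 20 kHz, 10 ms steps).** Resample to 40 kHz,
  pre-emphasis above 50 Hz, 25 ms Gaussian frames, Burg LPC of order 8.
  Two passes: the standard pass provides F1; a second pass with extra
  +3.6 dB/oct tilt compensation provides F2–F4 (roots above 4.5 kHz).
  Rationale: with F0 > 1 kHz and a falling source spectrum, single-pass
  LPC parks upper poles on strong harmonics below the resonances (5–10 %
  low bias measured); flattening fixes F2–F4 but inflates F1, hence the
  split. Frames under 30 % of the loudest frame's RMS are excluded from
  per-call aggregates (their poles reflect the background). Bandwidths
  come from the pole radii.
* **Spectral peak** — arg-max of the whole-call power spectrum.
* **Cepstral peak.** Real cepstrum of the centred 10 ms window; because
  quefrencies up to 1/75 Hz ≈ 13.3 ms need at least two periods of
  context, the excerpt is padded with surrounding signal to 4× the window
  (clipped to the call). The log-spectrum is detrended before the inverse
  transform so the source tilt cannot mask the periodicity peak. Height
  (linear units) is the tonality parameter; the quefrency equals the
  fundamental period (10 ms at 100 Hz).
* **Consistency.** Mean over successive slice pairs of the maximum
  normalised cross-covariance between their power spectra (10 ms slices
  by default; the alternative 25 ms convention is a config switch).
* Missing values stay NaN (listwise exclusion downstream, logged counts);
  `extract_all` returns the calls × (22 + labels) table with the
  conventional column names.

## 3. Non-linear-phenomena detection

A reproducible stand-in for visual spectrogram classification; thresholds
were calibrated on ground-truthed injected fixtures and then frozen in
`NLPConfig` (sensitivity and specificity ≥ 0.8 per type on the default
cohort; measured 0.88–1.00).

* **Jumps.** |ΔF0|/F0 > 0.18 between stable anchor frames bridging up to
  4 frames (the frame straddling the step returns a spurious combination
  period), excluding near-octave ratios (indistinguishable from tracker
  octave errors) and a 50 ms onset/offset margin.
* **Subharmonics.** Per voiced high-HNR frame, energy in ±5 % bands at
  F0/2 or F0/3 exceeding 2 % of the F0 energy — or the halved/tripled-
  track criteria: odd multiples of the tracked F0 far weaker than even
  ones (< 0.25) betray a tracker locked onto F0/2; analogously for F0/3.
  Three consecutive frames required.
* **Chaos.** Spectral flatness per 25 ms frame *after subtracting the
  call's stationary noise floor* (per-bin 10th percentile across frames) —
  plain flatness cannot separate chaotic segments from background/breathy
  noise at any threshold; the corrected measure separates them by an
  order of magnitude (threshold 0.035, ≥ 3 frames, quiet frames and 45 ms
  edges excluded). A call that is unvoiced throughout is scored as one
  chaotic segment over its audible extent.
* `percent_agreement` scores two annotation sets per category exactly as
  two human raters would be compared; `nlp_condition_stats` gives
  per-kitten percentages and paired Wilcoxon tests between conditions.

## 4. Statistics

* **Fisher omnibus** gatekeeper: X = −2·Σ ln p ~ χ²(2k). Following the
  emulated analysis plan, no per-test correction is applied beneath the
  gate (a Holm option exists but is off by default).
* One-way fixed-effects ANOVA per parameter; dependent/independent t
  (pooled variance by default, Welch optional); Pearson; Wilcoxon
  signed-rank (Pratt zeros, exact small-sample null); exact binomial
  tails for classification-vs-chance.
* **PCA + DFA.** Correlation-matrix PCA, components with eigenvalue > 1
  retained, loadings flagged above |0.700|; an independent linear DFA
  (equal priors, pooled covariance, ties to the lowest class label)
  consumes the retained PC scores only. Resubstitution and leave-one-out
  accuracies, per-class exact binomial tests against 100/k % chance,
  DF–PC Pearson correlations, confusion matrix. The internal LDA is
  cross-checked against scikit-learn and has an O(d²) Sherman–Morrison
  leave-one-out path so permutation tests can afford cross-validation.
* **Identity analysis**: per condition — ANOVA battery + omnibus, PCA,
  k-kitten DFA, per-kitten binomial tests. **Arousal analysis**: per-kitten
  condition means, paired t per parameter with direction arrows at
  p ≤ 0.05, PCA of the mean rows, 2-class DFA, PC1/PC2 scatter data.
* **Permuted DFA.** Calls within a kitten are not independent, so p-values
  come from re-running the identical balanced DFA under block
  permutations: *crossed* (kitten × condition; equal calls per cell, test
  labels permuted across cells within each condition) and *nested*
  (kittens in litters; equal kittens per litter and calls per kitten,
  labels permuted across kitten-by-condition sub-blocks within each
  litter × condition stratum). The stratification keeps every permuted
  class's sub-block composition identical to an observed class — without
  it the null is conservative (permuted classes combining two
  same-condition blocks are artificially coherent; measured). Averaging
  over balanced selections (10 crossed / 100 nested by default)
  stabilises the statistic when litter sizes differ. p-values use the
  add-one rule, so min p = 1/(1+n_perm); type-I error measured at 0.04
  for both designs (α = 0.05, 200 null replicates). Note that with only
  two kittens per litter the nested permutation group collapses onto
  label bijections and the test becomes conservative by construction —
  three or more per group is the intended regime.
* **Pipeline order** (`run_study`): condition-order control → identity per
  condition + accuracy comparison + crossed/nested pDFA → sex and
  body-weight controls → arousal battery → NLP prevalence. CSV tables
  (rounded for reading), full-precision JSON summary, config copy, and a
  run log with per-stage exclusion counts.

## 5. Numerical and design choices

* Seeds: every public entry point takes one seed; internal streams derive
  from `SeedSequence` tuples, so outputs are bit-reproducible.
* Degenerate inputs: all-silent audio segments to an empty list; zero
  voiced frames, constant columns, single kittens, and missing conditions
  produce flagged missing records or named errors, never silent NaNs.
* PCA requires more rows than parameters (22); the arousal PCA therefore
  needs ≥ 12 kittens with both conditions.
* The DFA emits min(k−1, n_components) discriminant functions — a 2-class
  run has one DF, whatever the component count.
* Rounded report values (2 decimals, chance as integer %) are formatting
  only; JSON keeps full precision.

## 6. Performance envelope and known limitations

Validation sizes were chosen so the whole suite runs comfortably on one
CPU: the full 348-call audio cohort (synthesis + extraction + NLP) takes
~40 s; permutation calibrations use 200 replicates × 200 permutations at
a 12-kitten cohort; power checks use 200 permutations on the default
cohort.

Limitations worth knowing:

* Formant recovery is within ±5 % for typical calls but a few percent of
  random parameter draws are adversarial (F1 at or below MaxF0, a
  harmonic coinciding with a narrow formant); no frame-based LPC method
  resolves those, and per-call recovery is asserted distributionally
  (median ≲ 2.6 %, ≥ 75–90 % of calls within band depending on the
  parameter).
* On noisy cohort audio (−26 dB background) upper-formant means acquire a
  positive bias on calls with non-linear phenomena; condition *contrasts*
  and classification remain correct, absolute formant tables from noisy
  audio should be read with that in mind.
* Leave-one-out accuracy is pessimistically biased under the null at
  small n (its null distribution centres below chance); the permutation
  framework, not the raw LOO value, carries the inference.
* The cepstral-peak height is in linear cepstrum units; the emulated
  instrumentation reported instrument-specific volts, so only ordering
  (not scale) is comparable.
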