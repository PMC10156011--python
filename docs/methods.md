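# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `emovox`. Everything below is implemented and tested in
the package; no quantity is claimed that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic utterances

Recorded speech is out of scope; `emovox.voicegen` produces source-filter
stand-ins good enough for the two things the pipeline actually needs from
audio: trackable F0 contours and broadband spectra for shelving-filter
verification.

The glottal source is a band-limited harmonic pulse train (harmonics to
95% of Nyquist with 1/h amplitude roll-off) whose phase integrates a
per-sample F0 track: a piecewise-linear cents-offset contour around
`f0_base` (defaults 120 Hz male / 210 Hz female), plus mild multiplicative
jitter (0.1%, ≈1.7 cents s.d.). The source passes through a parallel bank
of second-order formant resonators (three typical adult vowel formants per
speaker sex), is gated by voiced segments with 10 ms raised-cosine edges,
amplitude-modulated at the syllable rate, given 3% shimmer, and
RMS-normalized to 0.05 full scale (headroom for the +9.5 dB/octave
shelving boost). Default duration 1.5 s, sample rate 22050 Hz.

Jitter was set so that the flat-F0 round-trip contract (≥95% of voiced
frames within ±5 cents of target) is a property of the whole
generator-plus-estimator chain: at 0.1% the *true* instantaneous F0 stays
within that band, so the contract tests the estimator rather than the
generator's own randomness.

The sentence inventory is metadata: 4 sentences × {normal, jabberwocky,
shuffled, reversed} × 2 speaker sexes per main language (32 base items
each), plus 4 × 2 normal-only items for the unfamiliar-language control.
Synthetic audio carries no semantics or syntax, so the jabberwocky and
shuffled conditions differ from normal **only in metadata**; the reversed
condition is genuinely time-reversed audio. Passing tests therefore show
that the pipeline handles the design correctly, not that degradation
manipulations have acoustic consequences here.

## Voice transformations

All three pitch effects are realized as one time-varying resampling warp.
Given a per-sample offset contour c(t) in cents, the output reads the
input at φ(t) with φ′(t) = 2^(c(t)/1200), multiplying the instantaneous
frequency by exactly the desired ratio. Consequences, by design:

- no formant preservation (the spectral envelope scales with the warp) —
  the transformations are specified by their F0 contract, which the tests
  verify by contour re-estimation;
- output length equals input length; content timing shifts by the
  integrated ratio error, ≈3% for a 50-cent shift (well within the 1%
  duration contract on the container, since length is preserved exactly);
- read positions past the input's end (possible for upward shifts) yield
  silence — utterance tails, not onsets, absorb the loss.

Composition order in `apply_transform` is pitch shift → vibrato →
inflection → filter; the pitch stages are additive in cents and are merged
into a single warp (one interpolation pass), which is mathematically
identical to sequential warping for these contours and halves the
interpolation error. An all-empty spec is a bit-exact passthrough.

Specific effects:

- **Vibrato** — sinusoidal cents offset with peak deviation `depth_cents`.
  Rate jitter (default fraction 0.30 of the rate, configurable) is a
  smooth zero-mean perturbation of the instantaneous rate, renormalized so
  the time-averaged rate equals the nominal rate; jitter widens the
  modulation spectrum without moving its center. The *afraid preset* uses
  no jitter: the preset parameter table specifies only rate (8.5 Hz) and
  depth (30 cents), and a jitter-free preset keeps the contour-spectrum
  contract (8.5 ± 0.5 Hz) deterministic.
- **Inflection** — the onset excursion's exact analytic shape is not
  pinned down by its published description ("overshoots … then decays"),
  so the package uses a piecewise-cosine: from `min_cents` at t = 0 up to
  `max_cents` at half the window, decaying to 0 at `duration_ms`. The
  testable contract is extrema attainment (±15 cents) and identity after
  the window.
- **Shelf filter** — a linear-phase FIR designed by frequency sampling
  (513-point grid, 1025 taps): unit gain to the cutoff, then
  ±slope·log2(f/cutoff) dB above it. A frequency-sampled FIR hits the
  stated dB/octave slope directly (measured within ±0.1 dB/octave on
  white noise) and leaves the passband flat within 1 dB; the published
  description constrains the slope, not the filter topology. Group delay
  is compensated, so filtering is time-aligned and length-preserving.
- **Pitch step** — zero offset before the onset, a 10 ms raised-cosine
  transition, then a constant positive offset to the end.

## F0 estimation

`estimate_f0` is a frame-based autocorrelation tracker in the spirit of
Boersma's windowed-autocorrelation method: each frame is Hann-windowed,
its autocorrelation divided by the window's own autocorrelation (removing
both the linear lag taper and the phase-dependent edge bias), and the
period taken from a parabolically interpolated peak. Among near-maximal
local maxima (≥0.9 of the best) the shortest lag wins, guarding against
octave-down errors. Frames are voiced when the normalized peak exceeds
0.6 and frame RMS exceeds 1e-4; both thresholds are parameters.

Defaults: search band 75–500 Hz, 10 ms hop, window 3/fmin (≥3 periods of
the lowest trackable F0). For fast modulations (vibrato at 8.5 Hz) the
window is the limiting low-pass on the recovered contour: a 40 ms window
attenuates an 8.5 Hz modulation by ≈18%, so vibrato verification uses a
higher `fmin` (shorter window) and a 5 ms hop. Accuracy on clean synthetic
signals is ≈0.1 cents (pure tones) and well under 1 cent on the package's
vowels — an order of magnitude tighter than the ±3 cents the verification
contracts require.

## Adaptive staircase

Levitt's transformed up-down rule: level up one step after any error,
down one step after two consecutive correct responses; a single correct
leaves the level unchanged and does not affect the movement direction.
Asymptotically the rule targets the level with p(correct) = √0.5 ≈ 0.707.
Defaults follow the calibration design the package reproduces: start 200
cents, initial step 40 cents, step halved after every two *cumulative*
reversals (2, 4, 6, …) down to a 5-cent floor, stop at 12 reversals,
threshold = mean of the last six reversal levels. The reversal level
recorded is the level at the turning trial (the local extremum), and
halving is applied before the next move. Levels are floored at 1 cent and
have no ceiling (calibrated human thresholds range up to ≈257 cents).

Degenerate observers are diagnosed: a near-ceiling observer pins the
track at the floor where no further reversals can occur — after 30
consecutive floor trials the run terminates with the floor as its
threshold and a `StaircaseDivergenceWarning`; a near-chance observer
drifts upward and usually *does* terminate (direction changes are common
in an upward drift), so divergence is flagged when the threshold estimate
reaches the starting level, with a 1000-trial cap as the backstop.

**Finite-run bias.** With fixed nonzero steps and only twelve reversals,
the equal-step one-up/two-down procedure converges slightly above its
asymptotic 70.7% target; the bias grows as the final step size becomes
large relative to the psychometric spread, and for shallow observers
(≈1.6 probit units/octave) reaches 4–6 percentage points. The default
simulated observer is steep (4.5 probit units/octave — appropriate for
detection of suprathreshold pitch steps in speech), for which the bias is
≈1 point. This is a property of the procedure, reproduced faithfully, not
an implementation artifact; the staircase-convergence check carries a ±2
point tolerance around 70.7% accordingly.

## Simulated listeners

The listeners are explicitly synthetic scaffolding: the source study
reports no generative model of its participants, so these observers claim
no cognitive fidelity. Their role is to make the pipeline testable end to
end with the language-familiarity effect reduced to a single
interpretable parameter per task.

**2IFC observer.** p(correct) = 0.5 + (0.5 − λ/2)·Φ(s·log2(L_eff/θ) + z₀),
with threshold θ = 80 cents (the native 70.7% point; z₀ anchors that),
slope s = 4.5 probit units/octave, lapse λ = 0.02. Foreign-language
stimuli are processed at an effective level L/g with familiarity gain
g = 1.2; a `familiarity` scalar in [0, 1] interpolates the gain away.

**Categorization observer.** Each response category has a cue template
derived deterministically from its transformation preset — (pitch offset,
vibrato depth, inflection span = max − min, signed shelf slope) — and
responses are sampled from softmax(−β·d²) over the four templates, with
Euclidean distance in a cue space normalized by scales (50, 30, 200, 10)
that bring the four dimensions to comparable units. β is
`precision_native` = 0.25 for native speech and `precision_foreign` =
0.17 for foreign speech. Optional per-condition multipliers can shrink
precision for degraded speech (default 1.0: the package makes no
mechanistic claim about degradation).

Defaults were chosen by the calibration sweep in
`scripts/calibrate_observers.py`, run once and frozen: native-language
mean unbiased hit rate over the three emotion categories ≈ 0.34 and
foreign ≈ 0.25 (a gap of the magnitude reported for human in-group
advantages), native detection accuracy ≈ 0.72 at the calibrated level
versus ≈ 0.56 foreign, Group × Language interaction power ≈ 1.0 at the
study's cohort sizes, and empirical type-I rate ≈ 0.043 with the gap
switched off. Cohort simulators add lognormal individual differences
(s.d. 0.25 log units) on each participant's sensitivity parameter.

Because simulated listeners lack the many extra noise sources of human
cohorts (attention, criterion drift, strategy changes), simulated
interaction effect sizes — especially in the detection task — come out
larger than the human-scale F values; the package treats the presence and
calibration of the interaction, not its magnitude, as the reproducible
quantity.

## Experimental designs

*Categorization*: each base item is paired with its happy, sad, and
afraid transformations (96 pairs per main language, 24 for the control
language) and, by default, one neutral (identical) pair per base item.
The published trial count names only the manipulated pairs while the
results table includes neutral rows; the neutral-pair count is therefore
configurable (`include_neutral`). Trials are shuffled per seed; the first
interval is always the untransformed recording; the inter-stimulus
interval (0.7–1.3 s) is carried as metadata only, since simulated
observers have no temporal dynamics.

*Detection*: per participant, one staircase per speaker sex on
native-language normal sentences; the two thresholds become the fixed
step magnitudes for 3 blocks × 64 trials (every untransformed main-
language recording once per block), with per-trial step onsets uniform in
400–600 ms and balanced-random target intervals.

*Analysis*: per-participant confusion matrices per design cell → Wagner's
H_b, H_u, p_c; H_u tested against p_c by paired t (Bonferroni across the
12-comparison family); the LFE tested by a 2 × 2 mixed ANOVA (language
within, group between) on the 3-emotion mean H_u (categorization) or
accuracy (detection). Sums of squares are the classical weighted-means
decomposition, which for this design (one between factor, one within
factor, one observation per cell) coincides across ANOVA types and is
verified against both a brute-force decomposition and
`pingouin.mixed_anova`, including unbalanced groups. Proportions are
analyzed untransformed. Partial η² = SS_effect/(SS_effect + SS_error)
with each effect's own error term; it is invariant under affine rescaling
of the response.

The proportion index pi = H_b(k−1)/(1 + H_b(k−2)) maps chance (1/k) to
0.5 and perfect decoding to 1 for any k. Group-mean rows compute
pi(mean H_b), matching the convention of the reference report; note that
recomputing pi from hit rates already rounded to one decimal can differ
from a printed value by one unit in the last digit.

## Problem sizes and determinism

The repeated-cohort checks (power and type-I calibration) use the
closed-form cohort simulators — one multinomial per participant × language
× category cell, mathematically identical to trial-by-trial sampling —
at 100 runs for power and 1000 runs for the null rejection rate;
staircase convergence uses 200 simulated runs. Every stochastic component
draws from a `numpy` Generator seeded explicitly; the pipeline spawns
named substreams per stage from the master seed and records SHA-256
checksums of all artifacts in its manifest, so a rerun with the same
config and seed reproduces deterministic stages byte-for-byte.

## Known limitations

- Synthetic utterances are vowel-like carriers, not speech: no
  consonants, no aspiration noise, no microprosody; degradation
  conditions (other than reversal) are metadata-only.
- Pitch warping trades formant fidelity for exact F0 control; perceptual
  naturalness is not modeled and not claimed.
- The observers encode the LFE by construction; simulations demonstrate
  that the pipeline *detects* a familiarity gap when present and stays at
  the nominal false-positive rate when absent — they cannot, and do not,
  constitute evidence about human listeners.
- The staircase's finite-run bias (above) means converged levels track
  the 70.7% target only to within ≈1–2 points for realistic observers.
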