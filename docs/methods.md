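# Methods

## Study design being modeled

A two-arm randomized pre/post design: participants write either about
prosocial experiences (positive arm, dummy coded 1) or antisocial
experiences (negative arm, 0). Around the writing task they complete a
14-measure self-report panel, three cognitive tasks (recognition memory
for 16 positive/negative/neutral words each, situation construal of 6
images × 10 rated items, a 9-word word find), and — for a physiological
subcohort — EEG and wristband recording throughout, with stimulus-locked
analysis of word presentations, construal items, and questionnaire items.

## Synthetic cohort

Pre-intervention scores are multivariate standard normal with correlation
`R = (1−c)I + c·ssᵀ`, `c = 0.3`, `s` the keying sign vector (−1 for
negative affect and negative social emotions). This is the positive
semi-definite realization of an exchangeable structure in which same-keyed
measures correlate at +0.3 and opposite-keyed at −0.3 — a stand-in, not an
estimate; real inter-measure correlations for these instruments are not
published alongside the design, and `SimConfig.measure_correlation`
accepts any PSD matrix.

Post scores are `post = r·pre + δ_arm + √(1−r²)·e`, with test–retest
reliability `r = 0.8` (a typical state-measure value) and `e` drawn from
the same correlation structure. Both sessions are therefore unit variance,
so the configured per-arm mean change `δ_arm` *is* the standardized mean
change, and it survives the pooled z-scoring used downstream up to
O(δ²) ≈ 0.001. The default `δ_arm` table is the study calibration built
into `SELF_REPORT_EFFECTS` (e.g., gratitude −0.162 SD in the negative arm,
elevation +0.166 SD in the positive arm); change-score SD under these
defaults is √(2(1−r)) ≈ 0.63.

Cognitive logs are generated from latent per-participant task parameters
(d′ ≈ 1.35 and criterion ≈ 0 per valence for recognition; valence- and
polarity-dependent rating means for construal; exponential latent search
times for the word find) with zero condition effects by default, matching
the design's null cognitive findings; `cognitive_effects` injects per-arm
shifts in latent-SD units. Fixed per-valence hit/false-alarm probabilities
can replace the latent model for calibration tests.

Raw EEG is 1/f background (5 µV RMS) + a shared 10 Hz alpha source with
posterior-dominant gains (O 1.0, P 0.7, C 0.3, F 0.15) + frontal eyeblink
transients (100 µV, 400 ms raised cosine, Poisson arrivals) + injected
artifact bursts (600 µV, 1 s, 5 Hz under a Hann window) hitting a random
quarter of the channels — channel-specific so that average re-referencing
cannot cancel them, and placed unambiguously relative to the 400/40 µV
rejection rules. The sync channel carries one rectangular pulse per event
with edges on the event-onset sample. RR intervals are baseline 800 ms +
LF (0.1 Hz) and HF (0.25 Hz) sinusoids (25 ms depths) + white noise, with
beat times accumulated from the intervals; tonic conductance drifts
slowly, phasic conductance superposes exponentially decaying responses at
Poisson times, temperature is a bounded random walk.

What the generator does **not** emulate: realistic pulse-waveform
morphology, movement artifacts in the wristband channels, non-stationary
alpha, volume-conduction-realistic topographies, or learning effects
inside a session. Passing tests therefore demonstrate that the analysis
chain is correct and calibrated under its stated assumptions — not that it
would recover effects from arbitrary real recordings.

## Processing decisions

* **Bands**: delta 1–4, theta 4–7, alpha 8–15, beta 16–31 Hz; delta is
  used only for artifact envelopes, the other three for features.
* **Filters**: 4th-order Butterworth applied forward–backward (zero
  phase); the 0.1–60 Hz band-pass upper edge is clipped just below
  Nyquist at 128 Hz.
* **Blink removal**: spatial FastICA (fixed random state); a component is
  removed if its mean absolute mixing weight on frontal channels exceeds
  1.2× the all-channel mean *and* more than half its power lies below
  4 Hz. Removal precedes the average re-reference so the cleaned data have
  an exactly zero channel mean; decomposition failure falls back to a
  logged pass-through.
* **Artifact mask**: per channel, a 0.3 s sliding window is marked if any
  sample exceeds 400 µV absolute, window peak-to-peak exceeds 400 µV, or
  any band's Hilbert envelope exceeds 40 µV; the mask is the union over
  rules and bands. Event windows with more than 50% masked samples are
  dropped from feature averaging (an explicit choice; the design gives no
  rule for the interaction of masks with event windows).
* **Montage**: 12 channels (F7 F8 Fz C3 Cz C4 P3 P4 P7 P8 Pz Oz), the set
  consumed by the four channel groups; asymmetry pairs default to F7–F8,
  P3–P4, P7–P8. Both are configurable.
* **Hurst exponent**: rescaled-range over dyadic block sizes with the
  Anis–Lloyd small-sample bias correction (0.5 + corrected log-log slope),
  clipped to [0, 1]. On 1 s windows this is a coarse descriptor; the
  white-noise expectation 0.5 is recovered to ±0.1 after event averaging.
* **`hjorth_fd`** is the Hjorth complexity parameter (mobility of the
  derivative over mobility of the signal), used as a fractal-dimension-like
  descriptor; `petrosian_fd` is the standard sign-change formula.
* **EEG PCA** is fitted across participants on the per-task 24-column
  table (columns standardized, full SVD, deterministic sign convention);
  per-subject fitting is the other reading of the design and is not
  implemented as a mode because cross-subject scores are what the
  classifier consumes.
* **HRV windows**: spectral HRV cannot be estimated from ~1 s stimulus
  windows (the 0.04 Hz band edge alone requires tens of seconds), so the
  HF/LF "signal value" at time *t* is the Welch band power (Hann, 50%
  overlap, segments ≤ 64 s) of the RR series in a symmetric 64 s window
  centred on *t*; per-event mean and peak-to-peak are taken over the
  in-event grid times. This windowing is a necessary invention and the
  main deviation from the event-amplitude treatment of the other signals.
* **Tonic/phasic stand-in**: when only raw conductance is available, tonic
  = running median (8 s), phasic = residual (tonic + phasic reconstructs
  the input exactly); device-provided decompositions pass through.
* **Change scores**: z-scoring pools mean/SD over all participants and
  both sessions (the design does not state the normalization statistics;
  pooling keeps pre and post on one scale so the difference is a genuine
  standardized change). The intercept of the change regression equals the
  negative-arm mean change by construction of the dummy coding; a reading
  of the intercept as a positive-arm quantity is inconsistent with that
  model and is not implemented.
* **d′ edge rule**: the "set to 1/(2N)" correction is applied to the
  hit/false-alarm *rate* before the probit (the standard correction, and
  the only reading consistent with the paired 1 − 1/(2N) rule); a literal
  mode that sets d′ itself to the boundary value is selectable.
* **Word-find partial completion**: unspecified by the design; strict mode
  errors listing missing words, lenient mode yields NaN for affected
  valence groups with a `complete` flag.

## Cross-validation

The scheme is exactly: stratified 80/20 outer split; the training set
split into thirds, each third validating once; the grid value with the
best mean inner-validation accuracy selected (ties to the strongest
regularization); refit on the full training set; scored on the test set;
20 repeats with fresh splits; mean ± SE (SD/√20) reported. Grid values are
penalty strengths λ (linear models use C = 1/λ; a grid value of 0 means
"no regularization" and applies to linear models only). Random forests
and AdaBoost-SVM have no L1 penalty; their native complexity controls
(tree depth ≈ 3/√λ; boosting stages ≈ 10/λ with the base linear SVM at
C = 1) are searched over the analogous grid — a faithful-intent mapping,
not a literal one. Features are standardized inside each training fold.
Group PCA (wide groups → 5 components) is fitted inside each training
fold by default (`pca_mode="fold"`, leak-free); `"global"` fits once on
the full sample, reproducing the simpler published procedure.

A family that cannot be fit (degenerate split, solver failure) is reported
with an explicit failure reason rather than omitted.

### Chance intervals

The 20 repeats resample the *same* participants, so test decisions are
strongly correlated across repeats and the number of independent binomial
units is the cohort size, not repeats × test-set size. Chance bands in the
tests are therefore 0.5 ± 2.576·√(0.25/n) with n = participants — e.g.
(0.409, 0.591) at n = 200. Empirically the pure-noise mean test accuracy
ranges over roughly 0.46–0.57 across generator seeds, confirming that the
naive decision-count interval would be anti-conservative.

## Problem sizes

The test suite and acceptance script run everything at sizes a laptop
handles in seconds: cohorts of 12–245, physiological timelines of 9–48
memory words (the full session timeline is the default for the library),
200 simulation replicates for sign recovery, 1000 for type-I calibration,
and 20 CV repeats as in the scheme above. The end-to-end pipeline demo
uses 16 participants with 2 recorded physiological participants; all
sizes are configurable from `SimConfig`/`RunConfig`.

## Known limitations

* The calibrated decoding accuracy (~0.59–0.65 at n = 245) depends on the
  assumed measure correlation and test–retest reliability; the published
  analogue of this analysis reported 74%, which is not a reproduction
  target because the real covariance structure is unknown.
* ICA blink removal on 12 channels can absorb some alpha variance along
  with blinks; the criterion is deliberately conservative.
* The Hurst and fractal descriptors on 128-sample windows are noisy; they
  are retained because the feature set, not any single descriptor, is the
  analysis unit.
* AdaBoost with a linear-SVM base can terminate early on degenerate inner
  folds; this surfaces as a logged failure, never a silent omission.
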