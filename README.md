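# affectpipe

Pipeline for evaluating whether a brief positive- vs. negative-activity
writing intervention (e.g., gratitude/kindness recall vs. ingratitude/
unkindness recall) leaves detectable traces in self-report, cognition, and
physiology. It is aimed at well-being researchers who want to test
"objective" outcome measures — recognition-memory signal detection,
situation construal, attentional word search, EEG band features, and
wristband autonomic signals — against the traditional self-report panel,
on data they can fully control.

Because raw recordings from such studies are rarely public, the package
ships a first-class synthetic-cohort generator with known ground truth:
every downstream stage (scoring, artifact rejection, feature extraction,
statistics, classification) is testable end to end without any download,
and condition effects of any size can be injected into any feature group.

## What it computes

**Cognitive scoring.** Recognition memory is scored per word valence with
equal-variance signal detection theory: with hit rate *H* and false-alarm
rate *F*, *d′ = z(H) − z(F)* and *C = −(z(H) + z(F))/2*, where *z* is the
probit; extreme rates are corrected to 1/(2*N*) and 1 − 1/(2*N*).
Construal ratings *r* ∈ 1..7 map to (*r* − 4)/3 with negative-polarity
items sign-flipped; the word-find task yields average find order (grand
mean 5 over nine words) and average find time per valence.

**Physiological features.** EEG (12 channels, 128 Hz) is band-passed
0.1–60 Hz, ICA-cleaned of eyeblinks, average re-referenced, and masked by
three artifact rules in 0.3 s sliding windows (|x| > 400 µV, peak-to-peak
> 400 µV, band-envelope > 40 µV). Stimulus-locked windows yield
theta/alpha/beta RMS, Hurst exponent, Petrosian FD and a Hjorth complexity
descriptor per channel group (F/C/P/O: 6 × 4 = 24 variables, PCA-reduced
to 5), plus left–right alpha asymmetry. Wristband streams yield HF
(0.15–0.4 Hz) and LF (0.04–0.15 Hz) heart-rate-variability power of the
spline-interpolated RR series, tonic/phasic skin conductance, and skin
temperature, summarized per event as mean amplitude and peak-to-peak.

**Statistics and decoding.** Measures are pooled z-scored and differenced
(post − pre); each change score is regressed on the intervention dummy
(positive = 1) with Bonferroni familywise control (α = 0.05/18 = 0.0028
cognitive, 0.05/14 = 0.0036 self-report). Intervention condition is then
decoded from each feature group via nested cross-validation: stratified
80/20 split, inner thirds for selecting the L1 penalty from a grid
(10⁻³…10), refit and test, repeated 20×, for logistic regression, linear
SVM, AdaBoost-SVM and random forests, with feature groups added
hierarchically on top of the self-report baseline.

## Worked example

```python
from affectpipe import synthetic as syn, stats, ml

cohort = syn.generate_cohort(syn.SimConfig(n_participants=245, seed=2))
changes = stats.compute_change_table(cohort)
res = stats.run_change_regressions(changes, family="self_report")
print(res.sort_values("intervention_p").head(4).round(4))

cv = ml.nested_cv_classify(changes.drop(columns="condition"),
                           changes["condition"], ml.CVConfig(seed=2))
fr = cv.families["logistic_l1"]
print(f"test accuracy {fr.test_mean:.2f} +/- {fr.test_se:.2f}")
```

prints

```
                 measure  intercept  intervention_coef  intervention_p  significant
Negative Social Emotions     0.3497            -0.4494          0.0000         True
         Positive Affect    -0.1782             0.3360          0.0000         True
               Elevation    -0.0491             0.2445          0.0012         True
               Gratitude    -0.1934             0.2503          0.0023         True

test accuracy 0.64 +/- 0.01
```

The intercept is the negative-arm mean change (negative social emotions
rise by ~0.35 SD after writing about unkindness), the intervention
coefficient the between-arm difference, and 0.64 the mean held-out
accuracy of the L1 logistic classifier over 20 repeated splits — above
chance, as expected when the generator's default standardized effects are
in play.

The full chain runs as one command:

```bash
affectpipe run-all --out runs/demo --seed 1
```

which simulates the cohort and recordings, scores and extracts features,
writes tidy regression and classification tables, and records a manifest
of seeds, hashes, and stage outputs (reruns with unchanged config are
no-ops).

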