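# Methods

## Synthetic motor-imagery EEG

The generator produces the statistical structure a variance-feature
decoder relies on, nothing more. Per run it draws:

- **Background**: independent per-channel Gaussian noise with a
  1/f^`noise_exponent` spectrum (`noise_exponent` = 1, SD 2 µV).
- **Rhythms**: one mu (8–12 Hz) and one beta (18–26 Hz) band-limited
  Gaussian source per hemisphere (SD 3 µV and 1.5 µV), projecting with
  weight 1 onto C3 (left hemisphere) or C4 (right hemisphere) and 0.5
  onto their immediate montage neighbours. The fixed, sparse spread
  keeps the ground-truth discriminative direction known, so CSP's
  recovery can be verified.
- **ERD**: within each trial the source contralateral to the cued hand
  is multiplied by an envelope that is 1 outside the imagery window
  (2–8 s) and `sqrt(1 − erd_depth)` inside, with 0.25 s half-cosine
  ramps, so the *variance* attenuation is exactly `1 − erd_depth`.
  Default `erd_depth` = 0.6, a deep but realistic desynchronization;
  at that depth the decoder saturates near ceiling on clean synthetic
  data, which is deliberately cleaner than recorded EEG.
- **Nuisances** (off by default): a common 50 Hz sinusoid of amplitude
  `line_amp`, and `artifact_rate` × 80 trials that receive a 0.5 s
  amplitude step of 10 × channel SD on two random channels.

Trials are 9 s at 256 Hz (the rate is a package choice typical of the
hardware class — it is not documented for the original recordings),
80 per run, balanced 40/40 left/right in seeded random order. Identical
config + seed gives bit-identical output.

What the generator does **not** emulate: volume conduction from a head
model, eye/EMG artifact morphology, non-stationary rhythm amplitude
drift, inter-subject variability in electrode placement. Tests passing
on this generator therefore validate the *pipeline arithmetic and its
calibration* (chance level under exchangeable classes, monotone effect
recovery), not clinical-grade decoding performance.

## Conditioning chain

Filters are 4th-order Butterworth band-passes applied forward–backward
(`sosfiltfilt`, zero phase); the notch is an IIR notch at 50 Hz with
Q = 35, giving ≥ 30 dB rejection at 50 Hz and < 3 dB at ±5 Hz. Epochs
start at the trial cue and span 8 s.

Artifact rejection is package-defined (no published procedure exists
for this protocol): per channel, the per-trial *sustained amplitude*
(95th percentile of |x|) is scored against the median and scaled MAD of
that channel's values across trials; any channel score above
`z_threshold` = 5 drops the trial. The 95th percentile was chosen over
the raw peak because the maximum of ~2000 samples has a Gumbel-type
tail whose clean-trial scores overlap z = 5, while the upper quantile
is stable across clean trials yet driven to the artifact level by any
burst longer than a few percent of the epoch. Rejection runs on
**broadband** epochs, before the 8–30 Hz filter removes the
low-frequency energy that makes amplitude artifacts visible. At least
two trials per class are always retained (rejection relaxes with a
warning otherwise).

## CSP

Class covariances are per-trial covariances normalized by their trace
and averaged (robust to inter-trial amplitude drift). The generalized
eigenproblem `C_L w = λ (C_L + C_R) w` is solved after adding a
diagonal loading of 1e−8 × trace/16 to the composite (configurable);
the 2 + 2 eigenvectors from the ends of the descending spectrum form
the filter bank. Each filter is scaled so its largest-magnitude
coefficient is positive, making results reproducible across
eigensolvers. Eigenvalues are clipped to [0, 1].

## Features, LDA, cross-validation

At each timepoint t in {1.5, 2.0, …, 8.0} s the variance of each
virtual channel over [t − 1.5 s, t] (trailing window; clipped at the
epoch start) is floored at 1e−12, divided by the sum over the four
channels, and log-transformed — so `exp(features)` sums to 1 per
(trial, timepoint).

One LDA is trained on the pooled (trial × timepoint) samples with
equal priors and pooled within-class covariance (diagonal loading
1e−9 × mean diagonal); a per-timepoint variant is available
(`per_timepoint=True`) for sensitivity checks. Ties at the decision
boundary go to the first class (left).

Accuracy uses stratified k-fold (default 10) cross-validation at the
**trial** level; all timepoints of a trial stay in one fold. By
default the whole chain — CSP included — is refit on each fold's
training trials. This matters: with the spatial filters fitted once on
the full run, held-out trials have already shaped the filters, and the
measured null accuracy (no ERD simulated) sits near 65 % instead of
50 %. Refitting per fold restores chance-level behaviour under the
null, which is the calibration property the test suite enforces; the
cheaper fixed-CSP variant remains available
(`refit_csp_per_fold=False`) for comparison with analyses that fix the
filter bank. Per-class accuracy at each timepoint is the fraction of
held-out trials of that class classified correctly, averaged over
folds; the per-class summary is the max or mean over the 14
timepoints.

## Game and protocol

A trial's boolean event stream (one event per feature timepoint, from
the online classifier; all-true during calibration, whose feedback is
always positive) saves the cheese iff it contains ≥ 5 consecutive
true events; a suffix variant (`rule="suffix"`, the last five events
must be true) is provided because the narrative ties the save to the
moment the arm lowers. Scoring is independent of the score-panel mode.

The protocol runs two independent sessions of Calibration → Training 1
→ Training 2 (80 trials each). Online feedback uses the calibration
classifier in T1 and a classifier refit on the pooled C + T1 trials in
T2; session 2 never reuses session-1 classifiers. Offline, every run
is scored by cross-validation on its own trials, and the five reported
cells (C-S1, T1_S1, T2_S1, T1_S2, T2_S2) are laid out per class and
summary mode. Per-run `erd_offsets` can inject condition effects; the
default (none) encodes the null hypothesis that feedback mode does not
change the imagery signal. Which cells enter the ANOVA is
configuration (`StudyResult.anova_matrix(cells=...)`), since a
protocol analysis may legitimately exclude calibration runs.

## Statistics

Shapiro–Wilk, Mann–Whitney U (exact p when n_x·n_y ≤ 400 and there
are no ties, asymptotic with tie correction otherwise), the pooled
two-sample t and Pearson correlation delegate to scipy.stats behind
the module surface.

The one-way within-subject ANOVA decomposes
SS_total = SS_subjects + SS_condition + SS_error with
F = MS_condition / MS_error on (k−1, (n−1)(k−1)) df, after listwise
deletion of subjects with missing cells (the number dropped is
recorded). Sphericity corrections scale both df by ε: Greenhouse–
Geisser from the eigenvalues of the double-centered condition
covariance, Huynh–Feldt in the classical 1976 form
`(n(k−1)ε_GG − 2) / ((k−1)(n−1−(k−1)ε_GG))` capped at 1, and the lower
bound 1/(k−1). Note the corrected p-values are only ordered
(p_LB ≥ p_GG ≥ p) when F is clearly above 1; for F < 1 the ordering
reverses — a property of the F distribution, not an implementation
artifact. Mauchly's statistic uses the two-term asymptotic expansion
of its null distribution (the ezANOVA convention), which is noticeably
more accurate than the one-term chi-square at small n; with k = 2,
sphericity holds trivially (p = 1). If the contrast covariance is
singular (tiny cohorts), the ANOVA still runs and the Mauchly fields
are NaN.

Degenerate input — every subject constant across conditions — yields
F = 0, p = 1 by convention rather than 0/0.

## Questionnaire

The headline score is the unweighted mean of the eight per-question
means, reported to two decimals with half-up rounding; group rows also
report the sample SD across subjects' individual mean scores (absent
for single-subject strata). The two aggregations (question-level and
subject-level) coincide on complete tables; they can differ under
missingness, which is why both are exposed. The synthetic response
generator draws integer scores from a distribution concentrated on 4–5
(cohort mean ≈ 4.2), matching the satisfied-cohort regime the scoring
is exercised in.

## Problem sizes and numerical choices

Test fixtures use 20–40 trials at 128 Hz where the property under test
is size-independent; calibration suites (chance-level behaviour,
effect recovery, ANOVA p-uniformity) use the protocol's native sizes
(80 trials, 256 Hz, 20 seeds; 1000 replicates for the ANOVA). All
randomness is seeded; simulation is bit-reproducible, and
cross-validation splits are deterministic given the seed.

## Known limitations

- The synthetic ERD is stationary within the imagery window; real
  desynchronization waxes and wanes, so real timepoint curves are less
  flat than simulated ones.
- The "enhanced" Training-2 classifier is implemented as a refit on
  pooled calibration + Training-1 trials; the commercial system's
  exact update rule is not public.
- Artifact rejection is a substituted, explicitly package-defined
  rule; results on recorded data with other artifact morphologies
  (drift, EMG) would need its quantile/threshold revisited.
- Accuracies on the clean generator saturate near 100 % at deep ERD;
  comparisons with recorded-EEG accuracy levels are out of scope.
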