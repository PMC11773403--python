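# Methods

`corticomark` implements an analytical-validation workflow for a
two-component cortical biomarker of pain sensitivity — sensorimotor peak
alpha frequency (PAF) from resting EEG, and corticomotor excitability
(CME) change from TMS motor mapping — evaluated against pain-trajectory
classes derived from longitudinal diaries under a strict locked-model
discipline. Because no participant-level data are public, the package
ships a synthetic-cohort generator that reproduces the *statistical
structure* of the study design; every empirical number the package reports
is computed from such cohorts at run time.

## Synthetic cohorts

Each participant carries a latent pain-sensitivity class (high/low,
default prevalence 0.5) that drives three coupled observables:

* **PAF.** The participant's true alpha frequency is drawn from a
  class-conditional normal: mean 9.5 Hz (high) vs 10.5 Hz (low), SD
  0.5 Hz, truncated to the 8–12 Hz band. The 1 Hz gap encodes the
  direction "slower alpha → higher pain sensitivity"; the magnitude is a
  package choice, since class-conditional distributions are not published.
* **CME change.** Depressor probability is 0.75 given high class and 0.25
  given low. Depressors scale their day-5 motor-map surface by a factor
  drawn from U(0.45, 0.8), facilitators from U(1.2, 1.8); day 2 carries
  60 % of the day-5 log-modulation, making the planted direction persist
  across sessions.
* **Diaries.** The summed (chewing + yawning, 0–20) pain score follows a
  class-specific quadratic in day plus a participant random intercept and
  Gaussian noise, rounded and clipped. Defaults place the high class near
  8/20 at the first-week peak and the low class near 2/20, with residual
  SD 1.5 and between-subject SD 1.0–1.2 — pain that develops over days
  and resolves within the month. Entries go missing completely at random
  (default 5 % of timepoints), both activities of a timepoint together.

EEG is simulated as channel-independent 1/f^1 background plus a single
bursty narrowband alpha source (band-pass-filtered noise, ~1 Hz bandwidth,
multiplied by a slow waxing-and-waning envelope) mixed through a gain
vector that peaks over the left sensorimotor electrodes and decays with
scalp distance. The envelope matters twice: real alpha waxes and wanes,
and the resulting leptokurtosis is what lets ICA isolate the source — a
stationary Gaussian narrowband source is not identifiable by ICA at all.
`alpha_amplitude_snr` (default 20) is the alpha-to-background band-power
ratio at a full-gain channel; 0 yields an alpha-free recording. The
generator does **not** attempt biophysical realism: no forward head model,
no ocular/muscle artifacts, no occipital alpha competitor, no
non-stationarity beyond the envelope. Passing tests therefore show that
the estimators recover planted structure under realistic spectra and
topographies — not that they survive every artifact of laboratory EEG.

Covariates (sex, pain-catastrophizing totals) are drawn independent of
class by default, matching the finding that covariates did not improve
the model; `covariate_class_coupling` can induce dependence.

Determinism: all randomness descends from one seed through
`numpy.random.SeedSequence` spawns, one substream per participant and
session, so cohorts are bit-reproducible and participant *i* is unaffected
by draws for participant *j*. EEG recordings are regenerated lazily from
stored per-session seeds — a materialized 150 × 3-session × 63-channel
cohort would not fit in memory.

## PAF estimation

Spectra are Welch periodograms (4 s Hann segments, 50 % overlap, 0.25 Hz
resolution) after minimal preprocessing (de-mean, 1–40 Hz zero-phase
band-pass). The component pathway unmixes the recording with seeded
FastICA (up to 15 components) and selects the component with a *clear
alpha peak* and a sensorimotor-looking topography: qualifying components
need a local 8–12 Hz maximum whose prominence exceeds **2.5× the median
windowed power**; candidates are ranked by peak prominence and by cosine
similarity between the absolute topography and a Gaussian template over
the central electrodes, best summed rank winning (ties to the more
prominent peak). The prominence criterion is deliberately relative to the
local power level: background components have near-flat alpha windows, so
a threshold expressed as a fraction of the windowed power *range* passes
essentially any sampling wiggle, while measured margins for the level-
relative ratio are <1.8 for noise components and >5 for genuine alpha even
at SNR 2.

Two estimators operate inside a configurable window (8–12 default, 9–11
variant): `peak` (highest local maximum, QC-flagged absent when none) and
`cog`, the spectral center of gravity Σf·P(f)/ΣP(f) over window bins. CoG
is the default — robust to plateau peaks — and both are invariant to
overall spectral scaling. The sensor-ROI pathway averages the spectra of a
configurable central electrode set (default C3/C1/Cz/FC3/FC1/CP3/CP1) and
applies the same estimators. Note the CoG carries a small bias toward the
window center from the 1/f background under the peak (≈0.1 Hz at the
band edges at default SNR), which is inside the 0.2 Hz recovery tolerance;
aperiodic/periodic decomposition is deliberately out of scope.

## CME metrics

MEP amplitude is peak-to-peak within a 5–50 ms post-stimulus window
(configurable; the underlying study defers trial handling to an automated
supplementary method). Maps average trials per 1 cm grid site; a site is
*active* when its mean amplitude is ≥10 % of the map maximum — a
conventional motor-mapping rule, pluggable, since "active site" has no
published definition here. Map volume sums active-site amplitudes; map
area counts them. The facilitator/depressor classification compares day 5
to day 0: a strict increase is facilitation; Δ = 0 falls to the depressor
(risk) class, a measure-zero tie in practice.

## Trajectory labelling

The label model is a two-class growth mixture: class-specific quadratic
mean trajectory over fractional days (10 am at the day mark, 7 pm at
+0.375), participant random intercept b ~ N(0, τ²), homoscedastic
residuals. The within-participant marginal covariance is compound
symmetric (σ²I + τ²11ᵀ), which the EM uses in closed form, including for
participants with missing timepoints. The fit runs from 50 starts
(k-means responsibilities first, then random assignments), each a
multicycle ECM iteration: E-step responsibilities; class polynomials by
responsibility-weighted least squares on the raw outcomes (exactly the
marginal GLS maximizer, because the intercept column spans the
compound-symmetry direction); random-intercept posterior refreshed; then
closed-form σ², τ², and mixing-weight updates. The naive joint update that
regresses on intercept-adjusted outcomes stalls on a β/random-intercept
aliasing ridge when residual noise is small, which is why the ECM form is
used. Convergence is declared when the log-likelihood gain falls below
1e-6 relative to its magnitude (an absolute 1e-6 is unreachable on flat
variance-component ridges); monotonicity holds to 1e-8 and is asserted in
the tests. Class labels are anchored by mean-trajectory integral, "high"
being the larger.

Training labels follow the extreme-rank rule: sort by posterior P(high),
label the top and bottom `n_extreme` (default 40 of 100), leave the middle
unlabelled; the posteriors at the two boundary ranks become the locked
thresholds (inclusive comparisons, so boundary participants satisfy their
own rule; rank ties break by enrollment order). Labelling a test set
requires the rule to be explicitly locked and typically labels a strict
subset. Diary gaps are linearly interpolated inside the observed range and
extended by nearest value at the edges, or left missing in the
non-imputed variant; participants with fewer than two observations are
excluded from interpolation with a warning.

## Classification and locking

Features are PAF (Hz) and the binary CME class (facilitator = 1); high
pain sensitivity is the positive class, so the planted effects appear as
negative logistic coefficients for both features. Continuous features are
z-scored with training-set constants that are frozen into the locked
model. The labelled training set (80) splits into a held-out validation
16 and an internal 64 (four stratified folds of 16); five families —
logistic regression, SVM (RBF), single-hidden-layer perceptron, random
forest, gradient boosting — are tuned by grid search over deliberately
small published grids on the internal folds and compared by validation
AUC. Ties go to the family earliest in that (fewest-parameters-first)
order. The winner is refit on all 80 labelled rows; its parameters,
standardisation constants and probability threshold (Youden's J on the
training ROC — the threshold must exist before the test stage, and "J" is
the standard reading of an unexplained "optimal threshold") are hashed
(SHA-256) and locked. Prediction refuses to run on an unlocked or
modified model.

The blinded test stage receives shuffled truth plus the recorded
permutation; per-participant scores are computed without aligned truth
and the permutation is inverted only at scoring. AUC uses the midrank
Mann–Whitney formula (ties count ½) with a stratified percentile
bootstrap 95 % CI (2000 resamples, seeded); bands follow the 0.7/0.8/0.9
acceptable/excellent/outstanding convention. For a locked logistic model
the decision boundary inverts to one raw-Hz PAF cutoff per CME class (two
parallel boundaries); covariate-augmented variants select features by
univariate p-value (two-sample t for continuous, Fisher exact for binary,
threshold 0.05) before an identical fit/lock/predict cycle, falling back
to the biomarkers with a warning if nothing survives.

## Reliability

ICC is the two-way random-effects, absolute-agreement, single-measure
form computed from two-way ANOVA mean squares with the conventional
F-based confidence bounds (cross-checked against pingouin's ICC(A,1) in
the tests); bands use the usual <0.5 / 0.75 / 0.9 conventions. Session
agreement of the binary CME class uses Cohen's kappa plus raw agreement.

## Problem sizes and numerical choices

The repeated-seed experiments (end-to-end signal, null calibration,
robustness grid) run the full pipeline on 150-participant cohorts with a
reduced EEG profile — 16 channels, 60 s, 125 Hz, day-0 session, chosen so
that a 25-seed battery completes in minutes while preserving every
pipeline stage; planted-PAF recovery is verified separately at the full
63-channel, 5-minute, 250 Hz profile. The robustness grid caches spectra,
ICA decompositions and growth-mixture fits across cells that share the
relevant options. Variance floors of 1e-8 guard the EM against exact
degeneracy; all-zero maps, single-class score sets, unlocked rules and
missing sessions raise informative errors rather than guessing.

## Known limitations

Synthetic EEG omits artifacts and competing alpha sources, so component
selection faces an easier field than laboratory data. The growth-mixture
family is fixed (quadratic, random intercept only, two classes); model
order selection and random slopes are out of scope. Raw-Hz cutoffs are
only defined for the logistic family. Reported AUCs describe synthetic
cohorts with configured effect sizes — they validate the machinery and
its calibration (null cohorts score at chance), not any clinical claim.
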