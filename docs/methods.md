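# Methods

`eegattn` reimplements, end to end, a single-trial EEG analysis that asks
whether the cortical response to an *attended target* differs measurably
from the response to an *ignored distractor* when the two stimuli appear in
opposite visual hemifields during covert spatial attention. The chain is:
epoch preprocessing → eight per-epoch/per-channel features → stepwise
discriminant channel selection → a mixed repeated-measures ANOVA gate →
a three-classifier comparison under two cross-validation schemes. This note
records the model behind each stage, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## Session and data model

A session contains four trial datasets: A (attend left, target left),
B (attend left, distractor right), C (attend right, distractor left),
D (attend right, target right). Task condition 1 compares A vs B, condition
2 compares C vs D; A and D are the target class, B and C the distractor
class. Each dataset contributes 90 trials. EEG is 29 scalp channels of the
10-20 system at 512 Hz; epochs span −200 … +600 ms around stimulus onset.
With floor-based millisecond→sample conversion and half-open windows this
is 102 + 307 = 409 samples per epoch at 512 Hz (the floor convention is
ours; the equally defensible alternative is 410). Stimuli last 117 ms and
successive onsets are separated by that duration plus a 225–1000 ms
inter-stimulus interval, so consecutive onsets are 342–1117 ms apart —
*closer than the epoch length*, a property the synthetic generator
reproduces deliberately.

## Synthetic generator

The generator's task is to make every downstream stage testable with known
ground truth, not to imitate raw EEG waveforms. Each channel is a sum of

* five independent **band-limited Gaussian noise** processes (delta
  0.5–4 Hz, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz), with
  baseline RMS amplitudes 12/4/6/6/2 µV — the oscillatory content;
* **1/f background** (exponent 1, flattened below 1 Hz, 4 µV RMS, zero DC)
  plus a 1 µV white floor.

Class effects are planted as **band-power envelope modulation**: while
trial *i*'s stimulus is the active one (from its onset to the next onset),
the band envelopes on a set of informative central-parietal channels (CP1,
CP2, PZ, P3, P4) are scaled so that the target/distractor band-power ratio
at channel *c* equals `ratio ** w_c`. Defaults: delta ratio 2.5 (targets
stronger), beta ratio 0.5 (distractors stronger), channel weights CP1 1.0,
CP2 0.35, PZ 0.85, P3 0.25, P4 0.7. Three design points deserve emphasis:

1. **Why envelope-modulated noise rather than coherent bursts.** Any
   design that shares a waveform or a trial-common amplitude factor across
   channels correlates the per-trial feature values between channels; the
   stepwise selection then (correctly, but unhelpfully) recruits
   *uninformative* channels as nuisance covariates, and planted-channel
   recovery collapses. Independent band-noise carriers per channel keep
   channels statistically independent, so selection behaves the way the
   channel-recovery tests require. Modulation of ongoing band power is also
   the standard event-related desynchronization/synchronization picture of
   attention effects.

2. **Why the weights are unequal.** The statistical gate downstream tests
   the *channel × class interaction* on the three selected channels. If
   every informative channel carried the same effect, that interaction
   would be identically zero and the gate could never fire. The weight
   spread is chosen so that a genuine interaction survives top-3 selection
   while all five informative channels still dominate the 24 null channels.
   The magnitudes (2.5, 0.5, and the weights) are free parameters of the
   emulation — the source analyses report directions only — and were fixed
   once from a design power sweep targeting: top-3 delta channels inside
   the planted set in ≳90 % of sessions, and borderline interaction
   p-values of the order the original analyses report (0.01–0.09).

3. **One session model for both outputs.** `generate_recording` returns
   the continuous timeline with event markers; `generate_epochset` returns
   the −200…+600 ms windows cut around the same onsets of the same signal.
   Epoching a generated recording with `epoch_signal` therefore reproduces
   the generated epochs *exactly*, and the within-epoch envelope edges
   (the previous trial's class before onset, the next trial's after its
   onset) are identical in both paths. Trials are scheduled in
   same-dataset mini-blocks (default 10), echoing the block design of such
   recordings; this makes the neighbouring-envelope contamination mostly
   class-matched, so realized effect ratios stay within a few percent of
   the configured ones (the realized CP1 delta ratio is tested to be
   within 15 % of the configured value).

An optional linear amplitude drift (default 0) scales the band envelopes
across the session to make the time-separated cross-validation scheme
distinguishable from the random one.

What the generator does **not** model: ERP wave shapes (P300 etc.), eye
movements/EOG, artifacts, volume-conduction correlation between channels,
between-subject variability (a loop over seeds stands in for subjects).
Consequently, passing tests show the *pipeline machinery* is correct and
well calibrated, not that real EEG supports any particular accuracy.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass 0.1–45 Hz in
second-order sections, then common-average re-reference over scalp
channels (labels starting with "EOG" are excluded from the average and
untouched), then epoching with the half-open window above. Zero-phase
filtering is a choice — the source text does not say causal vs zero-phase —
made because the analysis is offline and phase distortion of epochs is
undesirable; it doubles the effective order, which the stopband test
accounts for. No baseline correction is applied. Events too close to the
recording edge are dropped with a warning carrying the count.
Blind-source-separation artifact removal is out of scope; users with
cleaned data can enter the chain at `epoch_signal` or the epochs-table
format. Continuous EEG can be read from EDF via MNE; EDF *writing* is not
provided (the plain-text epochs table is the package's interchange
format).

## Features

Per epoch and channel (conventions chosen once, stated here because the
source formulas leave them open):

* **Hjorth mobility** `std(dX/dt)/std(X)`; derivative = first difference
  × fs, std with n−1 denominator. With fs scaling the sinusoid limit is
  the angular frequency (rad/s).
* **Hjorth complexity** `std(d²X/dt²)·std(X)/std(dX/dt)²` =
  mobility(dX/dt)/mobility(X); dimensionless, minimum ≈ 1 for a sinusoid.
  (The typeset source formula is garbled; this is the standard form
  consistent with "spread of the spectrum".)
* **Average frequency**: zero crossings per second; a sample exactly at
  zero inherits the previous nonzero sign so a touch is never counted
  twice. Crossings are not halved into cycles/s.
* **LZ76 complexity**: binarize at the median (default; mean available),
  parse with the Lempel–Ziv 1976 exhaustive-history rule, report phrase
  count divided by n. The parser binary-searches the longest reproducible
  extension (reproducibility is monotone in length); tests pin it to an
  independent exhaustive-substring reference and to hand parses. The
  common `c·log₂n/n` normalization is available behind a flag.
* **Periodogram**: raw squared DFT magnitude folded to one side, no
  taper, normalized so the one-sided powers sum to `n·Σx²`. Band power is
  the sum over the half-open band `[lo, hi)`, which partitions the axis
  exactly. Median power frequency and spectral edge frequency are the
  smallest grid frequencies at which the cumulative power (DC bin
  excluded — after 0.1 Hz high-pass and average reference the DC term is
  numerical residue) reaches 50 % and 95 %; an absolute 1e−9 relative
  slack keeps exact ties at the lower bin.

`build_feature_matrix` evaluates one feature over all (trial, channel)
pairs into the observations × channels matrix C_d (180 × 29 per condition)
with rows in acquisition order; failures are re-raised naming the trial
and channel.

## Channel selection

Two-group MANOVA Wilks' lambda `det(W)/det(T)` (pooled within-group over
total scatter), minimized greedily: at each step the candidate channel
whose addition minimizes lambda is entered, stopping after a fixed count
(3, matching the analysis design) rather than an F-threshold — the source
fixes the number selected, not a significance criterion. Exact ties break
by montage order; candidates that make the scatter singular are skipped
with a warning. The partial F-to-enter
`((N−g−p)/(g−1))·(λ_p/λ_{p+1} − 1)` is recorded per step. Lambda is
invariant to per-channel affine maps, and the trace is non-increasing —
both property-tested.

## Repeated-measures ANOVA

The design inferred from the reported degree-of-freedom arithmetic is a
split plot: within factor = the 3 selected channel-feature values, between
factor = class, N = 180 observations → interaction df (3−1)(2−1) = 2 and
error df (180−2)(3−1) = 356. The interaction F is MS_interaction over
MS_within-error. Sphericity corrections deflate both dfs:
Greenhouse–Geisser ε from the double-centered pooled within-group
covariance (`tr(S̃)²/((k−1)tr(S̃²))`), Huynh–Feldt
`min(1, (N_w(k−1)ε_gg − 2)/((k−1)(N_w−1−(k−1)ε_gg)))` with N_w = N−g, and
the lower bound 1/(k−1). All three corrected p-values are emitted; the
formatted report (`F(2,356) = …, p = …`) quotes the lower-bound correction
by default, the one the source analyses quote. The implementation is
cross-checked against pingouin's mixed ANOVA in the tests, never backed by
it. Identical measures across levels raise a degenerate-covariance error
(relative threshold against total scatter, so float dust does not mask
degeneracy). At k = 2 all ε equal 1 and the interaction F equals the
squared two-sample t on difference scores — tested numerically.

**A calibration caveat that users should know.** The pipeline tests the
interaction on the *same observations used to select the channels*. Under
a null generator the fixed-channel test is well calibrated (type-I error
≈ 5 % at α = 0.05, p-values uniform — both tested), but the post-selection
test is strongly anticonservative: selection maximizes class separation
over 29 channels, and the spuriously selected effects have random signs,
which manufactures interaction. This circularity is inherent to the
select-then-test design being reimplemented; it is characterized by a
dedicated test rather than patched. The cross-validated classification
metrics, whose channel selection and normalization are re-fit inside every
training fold, remain at chance under the null (tested over 20 seeds) and
are the leakage-free readout.

## Classification and cross-validation

Features are z-scored with means/SDs estimated on the training fold only;
channel selection likewise runs inside each training fold. Three
classifiers, each emitting a continuous target score in [0, 1]
(hard labels at 0.5; the ROC sweeps all thresholds):

* **MLP**: one tanh hidden layer of 10 units, single output, trained with
  scikit-learn's L-BFGS solver under a fixed iteration budget (500).
  The original description specifies Levenberg–Marquardt; L-BFGS is the
  closest second-order batch method available in scikit-learn and the
  substitution is deliberate and documented here. Deterministic given the
  seed. Score = output probability.
* **KNN**: k = 5 (odd, to avoid vote ties; the source leaves k ambiguous),
  Euclidean metric, exhaustive search, distance-weighted vote; score =
  weighted target-vote fraction (a duplicated training point wins
  outright).
* **SVM**: RBF kernel, C = 1, γ = 1/n_features (neither is given in the
  source), libsvm's SMO-type solver; score = decision value through a
  logistic link.

Fold schemes (default k = 10, stratified): **random_kfold** is a seeded
stratified random partition; **time_separated_kfold** sends the trial of
within-class time rank r to fold r mod k, so each test fold spans the
whole session and temporally adjacent trials land in different folds —
the guard against slow session drift. On drift-free synthetic data the two
schemes agree to within 5 accuracy points (paired over seeds), and under a
planted linear drift the time-separated estimate is not optimistic —
both tested.

Evaluation: sensitivity TP/(TP+FN) with target positive, specificity
TN/(TN+FP), accuracy; per-fold values aggregated as mean ± sd and maximum;
one pooled ROC/AUC per (feature, classifier) from concatenated
out-of-fold scores, with trapezoid AUC (equal to the normalized
Mann–Whitney U — tested on random score vectors). Whether "maximum" is
taken over folds or seeds is labelled explicitly in the report; the
aggregate table reports the fold maximum.

## Pipeline and formats

`run_condition` chains the stages for one condition and carries into
classification only the features whose corrected interaction p falls
strictly below α (default 0.1 with the lower-bound correction, matching
the source's reporting threshold; a Bonferroni flag divides α by the
number of features, off by default because the source applies no
multiplicity correction). Outputs are delimited tables (selection, rANOVA,
evaluation, ROC points) plus a JSON manifest of config, seeds and library
versions; identical config and seed give byte-identical tables. The
epochs-table format is line-oriented plain text with `repr(float)` values,
so a write→read→write round trip is byte-identical. The CLI (`eegattn`)
is a thin click layer over these functions.

## Problem sizes used in the shipped checks

The test-suite and `scripts/acceptance.py` run at the study's native
per-condition size (180 trials × 29 channels × 409 samples); seed sweeps
use 10–20 sessions, the null calibration uses 1000 replicates of the
180 × 3 design, and parser/oracle comparisons use hundreds of short random
inputs. These sizes were chosen so every check completes comfortably on a
single CPU.

## Known limitations

* Real EEG's inter-channel correlation (volume conduction) is absent; with
  it, stepwise selection would legitimately mix informative and reference
  channels, and planted-channel recovery rates would not transfer.
* The single synthetic "subject" per seed makes seed loops a stand-in for
  the 13-subject population average; no claim of equivalence to true
  between-subject variability is made.
* The post-selection rANOVA gate is anticonservative by construction (see
  above); its p-values should be read as descriptive, as in the original
  analysis.
* Accuracies obtained on synthetic data depend directly on the planted
  effect magnitudes, which are free parameters; they demonstrate pipeline
  correctness, not attainable real-data performance.
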