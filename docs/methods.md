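# Methods

This package implements a complete single-trial ERP analysis for a
color-oddball attention paradigm — from continuous multichannel EEG to
cross-task and cross-participant target-versus-distractor classification —
together with a synthetic cohort generator that stands in for real
recordings. This note documents the models, the tunable parameters, the
numerical choices, and what the synthetic data can and cannot show.

## The paradigm being modelled

Squares in five colors flash one by one (500 ms on, 500 ms blank; 1000 ms
stimulus-onset asynchrony) in a 5x5 grid. Each task repetition presents
47-50 stimuli; one color, drawn uniformly at random per repetition, is the
target. Because colors are equiprobable, targets make up roughly one fifth
of the stimuli; color assignments are rejection-sampled until the target
count lies in 8-13, reproducing the printed range. Participants perform
one of three tasks per repetition: **C** — silently count targets; **A** —
add ten per target and one per distractor; **M** — memorize target
positions. Each task runs 20 times per participant.

Attended targets evoke a late positive ERP component (P300-like), maximal
over centroparietal midline sites around 300-600 ms. The analysis asks
whether a classifier trained to detect this response in one task transfers
to the others.

## Synthetic cohort generator

The forward model is additive and deliberately simple — the simplest
structure that reproduces the class structure the classifier exploits:

- **Shared early visual component** for every stimulus (Gaussian time
  course, peak 120 ms, SD 30 ms, 3 uV, occipital topography centered at
  Oz). It carries no class information; its purpose is to make "evoked
  activity" and "discriminative activity" distinct.
- **Late positivity** with Gaussian time course (peak 450 ms, SD 80 ms)
  and a fixed spatial pattern (unit-peak Gaussian on the scalp centered at
  Pz, spatial SD 0.06 m; electrode positions from the standard 10-05
  montage). Targets receive 5 uV. Condition defaults encode the
  qualitative task contrasts: distractors receive 0.5 uV in C and M but
  2.5 uV in A (every stimulus requires arithmetic there), and the
  per-epoch latency jitter SD is 30 ms in C versus 60 ms in A and M
  (memory encoding more variable in time). All of this is configurable.
- **Background activity**: spatially correlated 1/f noise (10 uV RMS per
  channel; squared-exponential inter-channel correlation with 0.05 m
  length scale), amplitude-modulated 10 Hz occipital alpha (4 uV), common
  50 Hz line noise (1.5 uV), sub-0.5 Hz per-channel drift (5 uV), and an
  independent 8 uV RMS 1/f floor on the EOG channel.
- **Blinks**: Poisson events at 5/min; Gaussian transients (SD 100 ms) of
  150-300 uV on the EOG, leaking into frontal scalp channels with a
  Gaussian spatial profile (40% at Fpz). They exist to exercise the
  200 uV EOG / 100 uV EEG rejection rule.
- **Between-participant variability**: per-subject log-normal amplitude
  scale (SD 0.2), latency shift (SD 25 ms), and per-channel log-normal
  topography gain (SD 0.3). These are properties of the subject, shared
  across that subject's three conditions — which is what makes
  across-participant transfer harder than within-participant transfer.

The montage emulates a 64-electrode cap: 62 scalp electrodes, one
electrode on the right mastoid, one EOG electrode below the left eye,
recorded against a left-mastoid reference (also carried as a channel so
linked-mastoid re-referencing is explicit). Feature extraction uses the
62 scalp channels.

With these defaults the peak single-feature effect size is a class-mean
difference of ~4.5 uV against ~10 uV of per-feature noise — a per-trial
d' around 0.45 at the best channel/time, which is the regime in which
single-trial ERP classification genuinely operates: individual features
are weak and only the multivariate pipeline with several hundred epochs
reaches solid AUCs. A full-scale simulated participant-condition yields
~810 epochs (~165 targets, ~648 distractors after the first-8 discard),
matching the study's bookkeeping, and within-condition cross-validated
AUCs around 0.7.

**Seeding.** A master seed plus a structured spawn key (stream id,
participant, condition) drives every random draw through numpy's
`SeedSequence`, so the whole cohort is bit-reproducible and any single
recording can be regenerated in isolation.

**What the generator does not emulate**: real head-volume conduction (no
dipole/leadfield model — topographies are phenomenological Gaussians),
saccades and other non-blink artifacts, non-stationary noise, overlapping
responses beyond the 1000 ms stimulus spacing, reaction-time structure in
the behavioral answers, and any dependence of the EEG on grid position.
Passing tests therefore show that the *pipeline* behaves correctly on data
with the assumed statistical structure; they are not evidence about any
particular real dataset.

## Preprocessing

Re-reference to linked mastoids; band-pass 0.5-40 Hz with a Butterworth
filter applied forward-backward (zero phase). The filter order is 5 per
band edge: the forward-backward squared response of that design attenuates
50 Hz line noise by ~21 dB while leaving a 10 Hz passband tone untouched
to within 1% — a 4th-order design would only reach ~17 dB after both
passes, which we considered too permissive next to a 50 Hz line component.

Epochs span the half-open window [-100, +900) ms around stimulus onset
(0-based sample indexing, onset at sample 100 at 1000 Hz; this convention
is stated once here and used everywhere). The first eight markers of every
repetition are discarded. Baseline correction subtracts the per-channel
mean over [-100, 0) ms.

Artifact rejection is a max-min (peak-to-peak) criterion on the
post-stimulus interval: 100 uV on any scalp channel or 200 uV on the EOG
rejects the epoch. Rejection only fills a boolean mask; classification
deliberately uses *all* epochs (the multivariate classifier can project
artifacts out, and an online system would have no choice), while grand
averages and discriminability maps use the artifact-free subset. The EOG
is thresholded on its own referenced signal (it is excluded from the
linked-mastoid subtraction).

Features: the 100-800 ms window per scalp channel, downsampled to 20 Hz —
15 values per channel, concatenated channel-major into a 930-dimensional
vector (62 x 15). Two downsampling conventions are supported because
"15 time points at 20 Hz" admits both readings: the default averages 15
consecutive equal-width bins spanning [100, 800] ms (robust interval
means; bin centers are reported as the time points), and a `pick` variant
takes the samples at exactly 100, 150, ..., 800 ms.

## Classification

With n ≈ 810 epochs and D = 930 features the empirical covariance is
ill-conditioned, so LDA uses an analytically shrunk estimate

    Sigma_hat = (1 - gamma) S + gamma * nu * I,    nu = tr(S) / D,

where S is the pooled covariance of class-wise centered epochs (each class
centered by its own mean — standard ERP-LDA practice) and gamma is the
closed-form optimal intensity: the summed estimated sampling variances of
the entries of S divided by the squared Frobenius distance between S and
nu*I, clipped to [0, 1]. The weight vector is w = Sigma_hat^{-1}
(mu_target - mu_distractor); the bias centers the threshold between the
projected class means (AUC, being rank-based, ignores it).

Two numerical notes. First, undersampled fits (n < D) are solved in the
dual n x n space via the Woodbury identity — algebraically identical to
the D x D solve (verified in tests to machine precision) and an order of
magnitude faster at cohort scale. Second, the closed form degenerates at
exactly n = 2 centered observations: both rows are +-v, every per-sample
second moment equals S, and the estimated sampling variance — hence
gamma — is exactly 0. This is a property of the estimator (sklearn's
Ledoit-Wolf reference behaves identically) and is documented rather than
patched.

Evaluation follows the study design:

- **AUC** (rank-based, midrank ties) as the performance measure; 0.5 is
  chance.
- **Within-participant**: stratified seeded 10-fold cross-validation on
  the diagonal of the 3x3 condition matrix; full-train/full-test on the
  off-diagonal (train on all epochs of one condition, test on all of
  another). Diagonal and off-diagonal cells are therefore not directly
  comparable.
- **Across-participant**: leave-one-participant-out, all nine condition
  combinations.
- **Learning curve**: conditions merged; for each held-out participant and
  each n, training subjects are drawn at random from the remainder
  (default 20 redraws per cell; reduced-scale analyses use fewer) and the
  AUC is averaged; 68% bootstrap CIs over participants.
- **Population tests**: one-sided Wilcoxon signed-rank against AUC 0.5 per
  cell (the direction "above chance" is given), Bonferroni-multiplied by
  the nine train/test combinations and capped at 1. scipy's exact null
  distribution is used automatically at these sample sizes.

## Discriminability maps

Per channel and time point, the point-biserial correlation r between
single-epoch voltage and the 0/1 class label, reported as signed
r^2 = sign(r) * r^2. Zero-variance cells yield 0 with a warning.
Participant maps are averaged via the Fisher z-transform: r is recovered
from the signed square (the transform is defined for correlations, not for
squared ones — applying atanh to signed r^2 is the other reading of an
ambiguous convention; we use r and expose the choice), z = atanh(r) is
averaged, tanh back, re-squared with sign. |r| is clipped to 1 - 1e-10
before atanh. No significance threshold is applied anywhere in the maps:
the full spatio-temporal pattern is kept, including sub-threshold
structure that only the multivariate classifier can exploit. Grand
averages are two-stage means (epochs to participant, participants to
grand) with equal participant weights. Scalp-map figures average 50 ms
windows centered at 100, 200, ..., 800 ms.

The bootstrap CI resamples participants with replacement and reports the
percentile interval of the resampled means; the default 68% level
corresponds to +-1 SD of the mean in the Gaussian case.

## Behavioral compliance

Scoring: C — number of targets; A — 10 per target plus 1 per distractor
(so A = 9 * targets + sequence length, an identity the tests assert); M —
the set of target grid positions. Distances are |correct - entered| for C
and A. For M the accuracy is the unordered position-set overlap divided by
the number of true targets (order sensitivity is not modelled; the
denominator is switchable to the number of entered positions).

The compliance test compares observed accuracy against a randomization
null with one-sided Mann-Whitney U tests (midranks; scipy's automatic
exact/asymptotic switch): for C and A, observed distances versus distances
under 1000 random re-pairings of correct and entered numbers (observed
smaller); for M, observed accuracies versus accuracies with the targets
moved to uniformly random grid cells without replacement (observed
greater). With fewer than ~50 shuffles the null is flagged as unreliable
in the log.

## Problem sizes in tests and the acceptance script

The generator's defaults are the study design: 13 participants, 3
conditions, 20 repetitions of 47-50 stimuli at 1000 Hz. A full-scale
cohort is ~40 minutes of signal per participant-condition, so the test
suite and the acceptance script run the same pipeline at reduced scale,
chosen per quantity:

- epoch bookkeeping and sequence-constraint checks use the full printed
  design (they are sequence-level and cheap);
- the chance-level calibration uses 13 null participants x 3 seeded
  cohorts with 5 repetitions of 20-24 stimuli each;
- the cohort-level reproduction of the study's findings uses 13
  participants x 3 conditions with 12 repetitions of 40-44 stimuli
  (~410 epochs per participant-condition, about half the study's count),
  which is the smallest scale at which all nine transfer cells are
  reliably separable from chance at the population level.

## Known limitations

- Phenomenological topographies mean re-referencing interacts with the
  signal only weakly (the injected pattern nearly vanishes at the
  mastoids); with real data the reference choice matters more.
- The noise model shares its smooth spatial structure with the signal, so
  the classifier cannot exploit a noise-only spatial subspace as strongly
  as on real EEG; synthetic AUCs are accordingly conservative at matched
  epoch counts.
- Behavioral answers are conditionally independent across repetitions
  given the error rate; no learning, fatigue or strategy effects.
- The EDF reader is available for real data, but recordings are written
  only to the documented HDF5 layout (plus BrainVision-style .vmrk marker
  sidecars).
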