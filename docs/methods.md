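# Methods

This note documents the models, conventions and design choices behind
`ovinesense`: what the pipeline computes, what the synthetic flock
generator does and does not emulate, and where genuinely open design
decisions were resolved.

## Signal model and preprocessing

Input is a 16 Hz ear-tag stream: tri-axial acceleration in g and
tri-axial angular rate in °/s, with a ground-truth annotation stream of
behaviour bouts (walking / standing / lying, from an ethogram in which
walking requires ≥ 2 s of four-beat forward motion) and a 0–6 locomotion
score per sheep-day. Scores ≥ 2 define the lame class; 0–1 the sound
class.

Each modality is reduced to its Euclidean magnitude and then
first-differenced per contiguous recording, `d[i] = m[i+1] − m[i]`. The
difference is per sample, *not* divided by Δt, so the differenced
accelerometer stays in g and the gyroscope in °/s. Differencing removes
any static component (gravity, mounting orientation) exactly — a
constant offset contributes nothing to the difference — which the test
suite asserts as an invariant.

Windows are 7 s (112 differenced samples) with 50 % overlap (stride 56).
Windowing is indexed on the differenced stream, so every window carries
a full 112 differenced samples; the alternative (windowing the raw
stream and differencing inside each window, 111 samples) loses one
sample per window edge and was rejected. A window takes the activity
covering the strict majority (> 50 %) of its samples; windows without a
majority label (ties, mostly-unannotated spans) are dropped. Lameness is
a per-recording label. Windows whose *source magnitude* is identically
zero across their span — a dead or disconnected sensor, impossible for a
live accelerometer which always sees gravity — are removed.

## Feature characteristics

Sixteen characteristics per modality, 32 per window:

| domain | features |
|---|---|
| time | mean, SD, min, max, skewness, kurtosis, interquartile range, median, zero crossings, signal area SA |
| frequency | spectral entropy SE, dominant frequency, spectral area SpA, 2nd and 3rd harmonic frequencies, harmonic ratio HR |

Conventions, fixed and documented because several are genuinely open:

- **Moments.** Population (biased) estimators; kurtosis is excess
  kurtosis; a zero-variance window takes skewness = kurtosis = 0.
  Quantiles use linear interpolation; "interquantile range" is read as
  the interquartile range Q3 − Q1.
- **Median.** The characteristic set's prose enumeration yields 15
  features per modality while every published count (and this package's
  vector contract) is 16/32; the set is completed with the median, the
  standard location statistic missing from the enumerated list.
- **Zero crossings.** Counted after subtracting the window mean; exact
  zeros carry the previous nonzero sign; leading zeros carry no sign.
- **Signal area.** SA = Σ|x| / f_s. The differenced magnitude is nearly
  zero-mean, so the literal signed sum would be ≈ 0 for every window and
  carry no intensity information; the absolute value preserves the
  feature's evident intent. The signed reading is available via
  `FeatureConfig(signal_area_absolute=False)`.
- **Spectrum.** One-sided periodogram from the plain DFT — no taper, no
  detrend (differencing already removed the static level). For a 112-
  sample window at 16 Hz: Δf = 1/7 Hz, 57 bins spanning 0–8 Hz. An
  all-zero window is flagged degenerate and all spectral features default
  to 0.
- **Spectral entropy.** Natural log over the normalised one-sided PSD;
  0 ≤ SE ≤ ln N; amplitude-scale invariant.
- **Dominant / harmonic frequencies.** The three distinct highest-power
  bins excluding DC (the DC of a differenced signal is residual drift,
  not rhythm), descending, power ties broken toward the lower frequency.
- **Spectral area.** SpA = 2 Δf Σ_{n≥1} S(f_n): one-sided doubling,
  DC excluded; ≈ the window's variance for broadband signals.
- **Harmonic ratio.** Even- over odd-*indexed* DFT bin amplitudes (DC
  excluded), the literal index reading of HR = Σf_2i / Σf_2i+1; the
  alternative (even vs odd integer multiples of the dominant-frequency
  bin) is available via `FeatureConfig(harmonic_ratio_bins=False)`.
  Denominator zero ⇒ HR = 0.

Every spectral feature is verified against an explicit O(n²) DFT oracle
to 1e-8 relative in the test suite.

## Feature selection

ReliefF, exhaustive deterministic variant: every instance is evaluated,
k = 10 nearest hits and misses in min-max-normalised feature space, L1
distance, neighbour ties broken toward the lower instance index. The
exhaustive variant removes subsampling noise and is cheap at this scale
(≤ a few thousand windows per activity); a seeded subsampling mode
exists for larger tables. Weights lie in [−1, 1]; constant features
score exactly 0; weights are invariant to affine rescaling of any single
feature. Rankings are computed separately within each activity.

## Classification

Five algorithms with fixed hyperparameters: random forest (250 trees,
min leaf 1, √p features per split), one-hidden-layer MLP (100 ReLU
units, learning rate 1e-4, adam, early stop on training-loss plateau,
≤ 300 epochs), RBF-kernel SVM (library-default C and γ, recorded in the
run manifest), AdaBoost (100 depth-1 trees, learning rate 1), and 5-NN
(Euclidean, no normalisation). No class rebalancing.

Evaluation is 10-fold cross-validation stratified on the lameness class
only. Because windows overlap by 50 % and folds are drawn at window
level, train and test folds contain windows from the same sheep — and
even half-overlapping neighbour windows. This **sheep-level leakage is
reproduced deliberately**: it is part of the benchmark protocol this
package re-implements. A leakage-free mode (`grouped_kfold`, a
class-balanced grouped k-fold that never splits a sheep across folds) is
provided as the honest variant.

The distinction matters quantitatively. On synthetic flocks with the
lameness effect switched *off*, the leaky window-level protocol still
reaches ≈ 0.55–0.60 accuracy — overlapping windows place near-duplicate
feature rows with identical labels on both sides of the split — whereas
grouped folds sit at chance. The package's distribution-level checks
(null indistinguishability, effect-size recovery) therefore use grouped
folds, which measure the injected signal rather than the protocol
artifact; the label-permutation calibration, which destroys the
neighbour-label structure, uses the faithful stratified protocol and
sits in [0.45, 0.55] for all five algorithms.

One fold assignment is drawn per experiment and reused across the
feature-count sweep, so sweep curves reflect the feature set rather than
fold noise.

The two-phase path trains a phase-1 activity classifier (same 32
features, random-forest spec) and one lameness model per activity; a
window is routed to the lameness model matching its predicted activity.
With ground-truth activity supplied, routing reduces to the
within-activity prediction by construction.

## Sheep-level statistics

Per sheep: the fraction of out-of-fold windows predicted lame, within an
activity. Group comparison:

- Δσ = (μ_lame − σ_lame) − (μ_nonlame + σ_nonlame), with σ the *sample*
  SD (ddof = 1; a singleton group takes σ = 0). Δσ > 0 iff the 1-SD
  intervals do not overlap.
- Mann–Whitney U, two-sided (one-sidedness of the published comparison
  is unstated; two-sided is the conservative choice): exact distribution
  for combined n ≤ 20 without ties, normal approximation with tie
  correction otherwise; two identical constant groups give p = 1.
- Decision threshold (μ_lame + μ_nonlame)/2; a sheep is declared lame
  iff its ratio is *strictly* above it. Sheep-level accuracy is reported
  in percent at 2 decimals (e.g. 16/18 → 88.89 %).

## Synthetic flock generator

The generator emulates the behavioural differences that the field
literature reports between lame and sound sheep, with a single
`effect_size` scaling every perturbation (default flock: 13 lame sheep
with scores in {2, 3}, 10 sound with scores in {0, 1} — the observed
field range — 16 Hz, 1800 s recordings).

- **Bout schedule.** Alternating-renewal quota scheduler: the activity
  with the largest time deficit relative to the sheep's activity budget
  (default 32 / 37 / 31 % walking/standing/lying, the windowed share of
  the reference deployment) starts next; bout lengths uniform per
  activity (8–30 s walking, 20–80 s standing, 30–90 s lying). Bouts are
  compressed relative to free-ranging sheep (lying bouts can last hours)
  so a desk-scale recording holds many bouts of each activity.
- **Orientation.** A constant 1 g offset on one randomly chosen
  accelerometer axis per recording, aligned with the main dynamic
  component so the magnitude inherits the dynamics linearly; magnitude
  differencing must — and does — remove it exactly.
- **Walking.** Gait oscillation at `gait_frequency` (default 1.9 Hz)
  with a weak second harmonic on accelerometer and gyroscope. The stride
  phase performs a random walk (0.2 rad/sample), as real gait is not
  phase-locked over a bout; the harmonic's and cross-axis components'
  relative phases drift likewise. Lame walking: the gait frequency
  shifts by `effect_size × 0.15 Hz` and a head-nod component appears at
  half the (lame) gait frequency with per-cycle phase jitter — nodding
  in line with the stride is the classic visual sign — whose incoherence
  raises spectral entropy.
- **Standing.** Low-amplitude postural noise with sparse weight-shift
  bursts (raised-cosine pulses, ~1 s, baseline 8/min). Lame sheep shift
  weight `(1 + effect_size)` times as often and `(1 + 0.3 effect_size)`
  times as vigorously.
- **Lying.** Minimal noise with rare restlessness events (~1.5 s,
  baseline 6/min), same lame rate and amplitude scaling.

Two deliberate departures from naive realism serve the generator's null
contract (at `effect_size = 0`, lame and sound sheep must be
*distributionally identical*, and no classifier should beat chance
without leakage):

1. events are **stereotyped** (fixed amplitude and duration per type)
   and arrive on a **jittered-regular renewal** schedule rather than a
   Poisson process — per-event shape variability and Poisson count
   dispersion would hand each individual sheep a distinctive realised
   signature that a flexible classifier can memorise through the leaky
   protocol even with no effect present;
2. the default flock shares one gait frequency — individual gait
   frequencies (supported via `SheepProfile.gait_frequency`) would make
   sheep identifiable, which the leaky protocol converts into label
   information.

What the generator does **not** emulate: biomechanics, breed/terrain/
weather effects, grazing and other unmodelled behaviours, diurnal
structure, sensor dropout, or inter-sheep variability in signal scale.
Passing tests on this generator therefore demonstrate that the pipeline
recovers the *kinds* of differences reported for lame sheep at the
stated effect sizes — not that it would reach any particular accuracy on
field data.

## Problem sizes and numerical notes

The test suite and the acceptance script run the full chain at desk
scale: flocks of 12–24 sheep with 300–1150 s recordings
(≈ 80–330 windows per sheep), chosen so each experiment completes in
minutes on one CPU while keeping ≥ 2000 windows where a calibration
band is asserted. Recovery experiments use 24 sheep × ≥ 300 windows at
effect size 2 against an effect-size-0 control.

Seeds: one master seed per run; stage seeds derive from it by fixed
offsets; flock generation spawns one child stream per recording, so
flocks are bit-reproducible and individual recordings independent.

Degenerate-input conventions (zero-variance windows, all-zero spectra,
zero metric denominators, singleton groups, identical Mann–Whitney
groups) are each pinned by an explicit test.

## Known limitations

- Binary lameness only; severity grading (scores 1–5) is out of scope.
- The published per-activity accuracies of the original field study
  (76.83–84.91 %) depend on a private dataset and are not reproduction
  targets; what is reproduced exactly is the study's arithmetic
  (accounting percentages, sheep-level accuracies) and its procedures.
- The σ-difference assumes roughly unimodal per-group ratio
  distributions; with heavy-tailed ratios the 1-SD interval reading is
  loose.
- ReliefF hyperparameters (k, sampling) are unreported in the original
  protocol; the exhaustive k = 10 variant here is deterministic but need
  not reproduce any published ranking exactly.
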