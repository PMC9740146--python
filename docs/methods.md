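# Methods

This note records the modelling and numerical choices behind `eegauth`:
what the pipeline assumes, what the synthetic cohort does and does not
emulate, and where the design was genuinely open.

## The authentication task

Verification, not identification: one subject is the claimed *genuine*
user and every other cohort member is an *imposter*. Each decision is
made on a single 0.5 s window of multichannel EEG, so the reported
accuracy is a per-window statistic over a held-out test split, with an
11:1 imposter majority for a 12-subject cohort. No score fusion across
windows or bands is attempted, and the decision threshold is the
forest's majority vote at 0.5 — no ROC/EER machinery.

## Filtering

All filters are Butterworth band-passes designed from normalized edges
`Wn = f_cutoff/(fs/2)` and applied forward–backward (`sosfiltfilt`), so
the effective magnitude response is the squared design response and the
phase is exactly zero. Design is in second-order sections: at a 0.2 Hz
edge on 500 Hz data the polynomial transfer-function form is
numerically ill-conditioned while SOS is stable. The delta band uses a
2nd-order design because a 0.2 Hz high-pass corner is below the safe
range for higher-order IIR recursions; every other band is 4th order.
Edge handling is scipy's default odd-reflection padding; the slowest
(0.2 Hz) poles ring with a ~2 s time constant, which is why response
tests read the steady state far from signal edges. Band edges are
shared by adjacent bands exactly as tabulated (4 Hz belongs to both
delta and theta); no gap or overlap correction is applied.

## Features

Eleven statistics per window and channel, in fixed order: mean,
population standard deviation, mean absolute value, RMS, skewness
(biased moment ratio m₃/m₂^1.5), kurtosis (non-excess m₄/m₂², Gaussian
→ 3), Hjorth activity/mobility/complexity, Shannon entropy, spectral
entropy. Zero-variance windows return 0 for the ratio-based features,
so every feature is finite for finite input (fuzz-tested). Choices that
were open:

* **Shannon entropy** is computed over a 16-bin fixed-width amplitude
  histogram spanning the window's min–max (0 when min = max), in bits.
  This is a deterministic, parameter-light stand-in for the many
  "signal entropy" variants in circulation; the bin count is a
  parameter of the implementation, not of the science.
* **Spectral entropy** is the Shannon entropy of the normalized
  periodogram divided by log₂(number of spectral bins), giving a
  dimensionless value in [0, 1] comparable across window lengths
  (≈1 for white noise, ≈0 for a pure tone).
* **Hjorth derivatives** are adjacent-sample first differences without
  sampling-rate scaling: mobility and complexity are variance ratios in
  which fs cancels.
* The default feature set has 11 members; the table layout is
  channel-major so a channel's columns form one contiguous block.

Windows are rectangular, length 0.5 s and step 0.25 s, with sample
counts rounded half away from zero and any trailing partial window
dropped: a recording of N samples yields ⌊(N−L)/S⌋+1 windows.

## Splitting, binarization, SMOTE

Splitting is per-subject stratified uniform sampling without
replacement, 80/10/10, validation and test counts floored and the
remainder assigned to training. Window-level splitting means two
half-overlapping windows can land in different splits; this optimistic
protocol is deliberate (it is the protocol the pipeline models), and a
contiguous-block splitter is provided for leakage-controlled
experiments.

SMOTE is applied to the training split only, upsampling the genuine
class to exact parity. Synthesis runs in raw feature space (trees are
scale-invariant downstream); an optional flag z-scores features for the
neighbour search only. k defaults to 5. Original rows are always
preserved verbatim and synthetic rows are convex combinations of
minority neighbours, so they stay inside the minority bounding box.

One consequence discovered during development and worth knowing:
interpolation shrinks the minority class's variance in *every*
coordinate (factor 2/3 for u ~ U(0,1)), which lets a booster separate
the classes using entirely uninformative columns. Channel ranking is
therefore computed on the *pre*-SMOTE training data.

## Classifier and tuning

A scikit-learn random forest with Gini splits. `feature_subsample`
(the fraction of columns examined per split) defaults to 0.1: the
channel-major tables are wide (352 columns at 32 channels) and mostly
uninformative for any one subject, and an all-features forest is an
order of magnitude slower with no accuracy gain. Tuning is an
exhaustive Cartesian grid scored by validation accuracy, ties to the
first point in grid order; the chosen combination is frozen for the
benchmark and every ablation refit, so accuracy changes are
attributable to channel removal alone. The default grids
(n_trees {50,100,200}, max_depth {8,16,∞}, min_samples_split {2,8})
are centred on library defaults. Wall-clock training and classification
times are recorded descriptively and never asserted on — they are
hardware facts, not method facts.

## Channel ranking and ablation

Ranking fits a shallow gradient-boosted tree classifier (XGBoost,
30 trees of depth 3 by default) and sums per-column gain importances
within each channel's block, renormalized to fractions summing to 1.
The default ranking is **multiclass on subject labels** — it scores the
inter-subject variance each channel accounts for across the whole
dataset — because that is both the quantity of interest for montage
design and far more robust than a single genuine-vs-imposter gain
(which under-weights a channel on which that one subject happens to sit
mid-range). A binarized input is accepted for single-hypothesis
ranking. Shallow boosting matters: deep/long boosting chases residuals
into noise columns and dilutes the ranking.

Ablation removes the lowest-ranked remaining channel one step at a
time — one ranking computed once up front (a per-step re-ranking flag
exists as an experiment) — retraining the forest with frozen
hyperparameters at every montage size from C down to 1, on both
training and test splits reduced to the surviving channels. The
minimum-montage rule scans the curve from the full count downward and
returns the smallest n such that all counts ≥ n stay within
1 percentage point (by default) of the full-montage benchmark.

## The synthetic cohort

The generator emulates the acquisition geometry the pipeline targets —
12 subjects, 32 channels named by 10-10 positions, 500 Hz — with 90 s
of signal per subject by default (enough windows for stable training
while a full ranked ablation still runs in a few minutes on one CPU).
Each channel carries one sinusoid per rhythm at a seeded in-band
frequency plus pink (1/f) background noise. Subject identity lives only
in a small planted set of informative channels: on each, the subjects
take equally spaced amplitude levels spanning ±50 % of baseline under a
channel-specific permutation. Adjacent levels are deliberately blurred
by the noise (in the γ band, in-band noise RMS is comparable to the
level spacing), so a single channel identifies a subject only
coarsely while the joint pattern across the planted set separates the
cohort cleanly — which is exactly what produces the flat-then-collapse
ablation curve and makes the planted set recoverable by ranking.
Non-informative channels share one baseline amplitude and frequency per
band across all subjects and so carry no identity information at all.

Numerical choices: narrowband components are sinusoids (not filtered
noise) so their spectral location is analytic; oscillation frequencies
avoid the outer 15 % of each band to stay clear of filter roll-off;
pink noise is synthesized by spectrally shaping seeded white noise and
normalized by its *analytic* expected power — normalizing each
realization empirically would let a handful of low-frequency bins
modulate every band's power and imprint spurious per-subject
signatures on uninformative channels. All generation is a pure
function of the cohort spec and its seeds.

What the generator does **not** emulate: event/trial structure,
evoked responses, artifacts (blinks, EMG), electrode drift, volume
conduction between channels, or non-stationarity. Tests that pass on
this cohort therefore demonstrate that the pipeline recovers planted
band-power signatures through the full filtering→features→SMOTE→
forest→ranking→ablation chain — they do not certify performance on
real EEG, where identity information is weaker, correlated across
channels, and non-stationary.

## Chance calibration

With an 11:1 test imbalance, a signal-free model collapses to
all-imposter prediction and plain accuracy pins at 11/12 — a useless
chance reference. The permutation null (`shuffled_label_accuracy`)
therefore scores the shuffled-label model on a class-balanced test
subsample (all genuine windows plus an equal seeded draw of imposter
windows), where chance is 0.5 regardless of predictor bias. At the
study scale the null sits at ~0.5 while the signal condition exceeds
0.95.

## Problem sizes used by the test suite

Unit and property tests run on 6–12-subject cohorts of 8–12 channels
and 15–20 s; the parameter-recovery study runs once at the full
12 × 32 × 500 Hz scale with 90 s per subject, 50-tree depth-16 forests,
and five planted channels, chosen as a scale at which the full ranked
ablation completes in minutes on a single CPU.

## Known limitations

* Ranking robustness was tuned for wide, mostly-uninformative feature
  tables; on dense low-dimensional data a deeper booster may rank
  better.
* The 1-point minimum-montage rule applied to a single subject's curve
  is sensitive to refit jitter at small test sizes; the cross-subject
  averaged curve (`min_channels_table`) is the stable quantity.
* Feature extraction assumes stationarity within 0.5 s windows and
  ignores cross-channel structure entirely.
* SMOTE's variance shrinkage slightly over-tightens the genuine
  acceptance region; genuine recall (not imposter rejection) is the
  accuracy bottleneck at small training sizes.
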