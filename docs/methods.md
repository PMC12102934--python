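# Methods

`actipheno` turns multi-day wrist-actigraphy recordings into a
subjects × features table of rest–activity, sleep-movement and wavelet
descriptors, and then ranks those features by pooled Shapley values
under two complementary selection frameworks. This note documents the
models, the defaults and why they are what they are, the synthetic
cohort the tests run on, and the known limits of both.

## Preprocessing

Recordings enter as per-minute activity counts. Raw triaxial
acceleration (10 Hz) is reduced to counts with a PIM-style scheme:
zero-phase Butterworth band-pass of each axis (0.25–2.5 Hz, order 4),
Euclidean magnitude across axes, the maximum magnitude within each
second, summed over the 60 seconds of the epoch. Filtering each axis
before combining is the default; filtering the combined magnitude is a
flag (`combine_first`). Counts are kept as reals — sums of filtered
magnitudes are continuous.

Days are midnight-to-midnight; leading and trailing partial days are
trimmed so windows such as M10 are comparable across subjects. Whole
days of all-zero counts (device off or off-wrist) are excluded;
partial days never are. The exclusion is idempotent.

## Sleep detection

An epoch is "rest" when its count is at or below a low-activity
threshold (default 10 counts/min). Maximal rest/wake runs shorter than
a minimum segment (default 30 min) are flipped to the opposite state —
shortest run first, earlier run on ties — until a fixed point, which
absorbs brief stirrings inside a bout and brief lulls during the day.
Runs touching the record boundaries are exempt because their true
length is unknown. The order rule makes the fixed point deterministic;
the test suite checks it against a from-scratch re-implementation on
exhaustive small inputs and 10 000 random binary strings. Bouts longer
than 900 min (15 h) are discarded as device artefacts. The threshold
and minimum-segment defaults were chosen to give the synthetic cohort
a 6–9 h modal sleep duration; both are configuration, and no claim is
made that they equal any particular device's internal settings.

## Circadian metrics

M10 / L5 scan consecutive 600-/300-epoch windows within each day (no
wrap-around) and average the per-day extrema across days; a
mean-profile variant is available. RA = (M10 − L5)/(M10 + L5), defined
as 0 for an all-zero subject. ADAT is the grand mean count.

Interdaily stability and intradaily variability use the classical
variance-ratio forms

    IS = N · Σ_h (x̄_h − x̄)² / (p · Σ_i (x_i − x̄)²)
    IV = N · Σ_{i≥2} (x_i − x_{i−1})² / ((N−1) · Σ_i (x_i − x̄)²)

with the per-minute daily profile (p = 1440) by default; the hourly
variant is a flag. IS is 1 for a perfectly repeated daily pattern and
≈ 1/d for d days of white noise; IV reaches 4 on an alternating
series. Constant records yield NaN for both.

The sleep fragmentation index of a bout is the fraction of epochs
spent moving, where zero-runs of at most 2 epochs are credited as
movement (the "short passive interval" is counted in epochs, not
intervals — a choice, not a claimed equivalence). `activity_std` is
the population SD.

Undefined features propagate as NaN; before model training, columns
missing in more than 20% of subjects are dropped and the rest are
median-imputed within label group.

## Nocturnal peak taxonomy

Inside each sleep bout, a peak is a maximal run of non-zero counts;
zeros separate peaks. Peak amplitude is the maximum count of the run
(mean-within-run behind a flag). Small/large classes are formed per
night either by the amplitude median (ties to small) or by the
quartiles (small ≤ Q1, large ≥ Q3 with the Q1 tie going to small;
middle peaks unclassified). Quantiles are linear-interpolation
(type 7) — stated because Q1/Q3 depend on the estimator.

For each category (all / small / large × median / quartile split) the
per-night vectors of amplitude, length and end-to-start gap are
summarised with avg/std/max/min/med; the per-night peak count and the
number of consecutive same-class pairs closer than 2 epochs ("close
peaks") are recorded; the night's first and last peak contribute their
amplitude and start offset. Gaps within a class ignore interleaved
peaks of the other class. Everything is averaged across the subject's
valid nights, skipping nights on which a feature is undefined (e.g. no
large peak). Feature names follow `<category>_<metric>_<func>` and the
name set is fixed, so tables are column-stable across runs.

## Wavelet structure factors

The counts of all valid sleep bouts are concatenated chronologically
and transformed with a complex Morlet CWT (ω₀ = 6), 64 log-spaced
pseudo-periods spanning 1–200 min by default. Coefficient magnitudes
normalized to the map maximum (per-scale normalization optional) form
a correlation-coefficient map; the structure parameter of a scale is
the fraction of time points at or above a 0.7 threshold, and
`structure_pms` integrates it over the scale window with the trapezoid
rule. `wavelet_fi` = 1 − mean per-scale structure parameter is a
wavelet-based fragmentation indicator. This threshold-occupancy
definition reproduces the intended qualitative behaviour — high values
where the map shows prominent, persistent structure — but is a
package-defined statistic; threshold, normalization and window are all
configuration.

## CFFS — clique-forming feature selection

1. **Screen**: keep features with Welch two-sample p < 0.05 *and*
   discretized mutual information with the label ≥ 0.02 nats
   (equal-frequency binning, 4 bins). Screening generates candidates,
   so no multiple-testing correction is applied. With 47 subjects the
   plug-in MI estimate carries an upward bias of roughly
   (B−1)/(2n) ≈ 0.03 nats, so the Welch arm does most of the gating.
2. **Graph**: nodes are survivors; an edge joins two features with
   |Pearson r| ≤ 0.3. Zero-variance features get no edges.
3. **Cliques**: maximal cliques with 3–6 members, deterministically
   sorted; optionally their sub-cliques. When more than 500 exist the
   list is thinned to 500 by evenly spaced picks. The 0.3 / 500
   defaults keep the candidate count in the hundreds across cohort
   draws — sparser graphs leave no cliques in the size band, denser
   ones explode combinatorially.
4. **Models**: each clique is trained as logistic regression (L2,
   C = 1), random forest (200 trees) and a single-hidden-layer network
   (8 logistic units, L2 10⁻³, ≤ 500 iterations) under stratified
   3-fold CV, standardizing inside the training folds only. Models
   with mean CV accuracy ≥ 60% (boundary inclusive) are retained.
5. **Shapley pooling**: each retained model is refit on all subjects
   and explained with *exact* Shapley values — full coalition
   enumeration is affordable at ≤ 6 features — using the interventional
   value function (class-1 probability with absent features at the
   feature means). Per-feature (value, Shapley) pairs are pooled
   across retained models and ranked by mean |Shapley|.

Accuracy is the plain fraction correct (arms are near-balanced). All
seeds derive deterministically from the master seed, so
`ranking.csv` is byte-identical across runs.

## AHFS — adaptive hybrid (greedy forward) selection

At each step, five measures score every remaining feature given the
selected set — MIM, mRMR, JMI, MMIFS (β = 0.5) and a correlation-based
score (LCFS); MI terms use the same 4-bin discretization. Each measure
proposes its argmax; the deduplicated proposals are evaluated by a
2-unit single-hidden-layer network under stratified 3-fold CV, and the
candidate with the best mean accuracy joins the set (CV accuracy, not
training error — the held-out variant is the defensible one at these
sample sizes; 2 units because larger evaluator networks overfit). A
run makes 20 such extensions; the ensemble repeats 20 runs with
distinct seeds, giving 400 selected-feature slots and 20 best models
(each run's highest-accuracy prefix, earliest on ties). Best models
are explained with antithetic permutation-sampled Shapley values (256
permutations plus their reversals — exact enumeration is infeasible at
up to 20 features); the telescoping estimator keeps the efficiency
identity to float precision. Pooling and ranking are identical to
CFFS.

## Synthetic cohorts

The generator emulates the data shape the pipeline assumes: per-minute
counts over 10 days; a smooth diurnal envelope (raised-cosine hump
between ~06:30 and ~23:30) scaled by a daytime amplitude (250
counts/min) with day-level lognormal jitter (SD 0.25) and within-day
gamma noise; one sleep block per night (start ≈ 23:00 ± 30 min, length
≈ 450 ± 40 min) whose floor is zero. Nocturnal movement is two Poisson
burst processes — equal-rate small- and large-amplitude populations
(6 peaks/h total), geometric run lengths (mean 2 epochs), gamma
amplitudes with means separated ×4 and shapes chosen so a per-night
median split recovers the populations. Between-subject heterogeneity
is lognormal trait multipliers (SD 0.2) on amplitude, peak rate, peak
length and sleep length: without it any single feature separates small
cohorts perfectly and selection experiments degenerate.

Group effects are multiplicative knobs; two presets encode the target
phenotypes: `psf_like` (small-peak length ×1.5, large-peak rate ×0.7)
and `cs_like` (daytime amplitude ×0.6, day-to-day jitter ×0.4, which
raises IS). Default arms are 25 controls vs 22 cases.

What the generator does *not* emulate: non-wear artefacts other than
whole missing days, device noise spectra, naps, weekday/weekend
structure, demographic covariates, or any dependence between daytime
behaviour and nocturnal movement. Passing recovery tests therefore
show that the pipeline finds effects of the planted kind at realistic
arm sizes and heterogeneity — not that the specific clinical rankings
of any real cohort would be reproduced.

## Problem sizes and numerical choices

The test suite and the acceptance script run on the default cohort
(47 subjects × ~107 features from 10-day records). Recovery
experiments use ten cohort draws per condition with the
logistic-regression clique ensemble and a 6-run × 10-step greedy
ensemble — enough models to make pooled rankings stable while keeping
each experiment in seconds-to-minutes; the full three-algorithm clique
ensemble and the default 20 × 20 greedy ensemble are each exercised
once. Ties are always broken deterministically (earlier run, lower
alphabetical name, earlier step). Degenerate inputs — constant
features, empty nights, subjects with no detected sleep — yield NaN
features that the imputation layer handles; a subject whose whole
record is missing raises.

## Limitations

The structure-factor definition, the sleep-detection thresholds and
the fragmentation-index epoch counting are package choices among
several defensible readings; all are configuration, and comparisons
with other implementations should fix them explicitly. Plug-in MI at
n ≈ 47 is biased and only used for ranking. Exact Shapley values are
computed on models refit to all subjects, so they explain the fitted
ensemble, not out-of-sample behaviour.
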