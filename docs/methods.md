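# Methods

This note documents the models, parameters and numerical choices behind
`sleepscratch`, and what the synthetic data generator does and does not
emulate.

## Hierarchical model

The pipeline assumes that nighttime scratching can only be assessed once
two layers of context are established: the device must be on the body, and
the analysis must be restricted to the window in which sleep is the
intended behavior (the *total sleep opportunity*, TSO — lie-down to rise).
Without the TSO gate, daytime hand movement floods a scratch classifier
with false positives; without the wear gate, an unworn device looks like
perfect sleep. Each 24-h day (noon to noon, on the participant's clock)
yields at most one TSO window and one set of nightly endpoints per wrist.

## Wear detection

Near-body temperature is smoothed with the same cascade used for the
arm-angle metric — 5-s rolling median, consecutive 5-s average, rolling
5-min median — so wear flags land on the TSO metric's 5-s grid. A
processed sample strictly below **25 °C** marks non-wear; exactly 25 °C
counts as worn. Candidate TSO windows containing *any* off-body sample are
discarded (a fraction-based rule can be substituted via
`TSODetector(wear_threshold=...)` plus pre-filtering if a device reads
cold transiently). Missing temperature streams are treated as worn
throughout, since several devices lack the sensor.

## TSO detection

Per 5-s epoch, each acceleration axis is smoothed (5-s rolling median,
then 5-s block mean — gravity must be preserved, so no high-pass filter
here) and converted to the wrist elevation angle
`θ = atan2(z, √(x²+y²))·180/π ∈ [−90°, 90°]`. The absolute successive
change `|Δθ|` is smoothed by a centred 5-min rolling median. The per-day
threshold is `max(0.1°, P₂₅)`, the 25th percentile taken over on-body
samples with a floor of 0.1°; on a normal day the percentile falls below
the floor and the fixed 0.1° rule applies.

Runs below threshold shorter than `min_block_min` (default **30 min**) are
removed first; surviving runs separated by gaps shorter than
`merge_gap_min` (default **30 min**) are then bridged. The order matters:
the adaptive percentile guarantees ~25 % sub-threshold samples even on a
fully active day, and bridging those scattered fragments before length
filtering would chain them into a spurious all-day candidate. Removing
fragments first leaves an active day with no candidate at all, while a
genuine night — whose sub-threshold runs are hours long on either side of
brief wake bouts — survives intact. The longest worn candidate is the TSO;
a day can also legitimately have none.

Known limitation: a cluster of wake bouts that fragments the night into
pieces shorter than 30 min separated by more than 30 min of disturbance
can truncate the detected TSO to the longest intact fragment. Both
parameters are configuration, not constants.

## Sleep/wake scoring

The classic count-based actigraphy heuristic expects proprietary activity
counts; raw-accelerometry devices provide none, so the per-minute
**activity index** `AI = √(max(0, mean over axes of per-axis variance −
σ²_noise))` (units: g) stands in, with `σ²_noise = 0` by default. The
epoch score is the 1-min Cole–Kripke weighted sum

```
D_t = P · (106·A_{t−4} + 54·A_{t−3} + 58·A_{t−2} + 76·A_{t−1}
           + 230·A_t + 74·A_{t+1} + 67·A_{t+2}),    sleep ⇔ D_t < 1
```

with missing neighbours treated as zero. The count→index calibration is
the method's acknowledged open point: the exposed `scale` constant `P`
defaults to **0.05 per g**, chosen so that accelerometer-noise-floor sleep
(AI ≈ 0.005 g) scores `D ≈ 0.2` and overt in-bed movement (AI ≳ 0.05 g)
scores `D ≳ 1.7`. Deployments against a reference should treat `P` as a
per-device calibration.

Webster's five rescoring rules then improve wake specificity (each
switchable): after ≥ 4 / 10 / 15 min of scored wake the next 1 / 3 / 4 min
of sleep are rescored wake; sleep islands of ≤ 6 min inside ≥ 10-min wake,
or ≤ 10 min inside ≥ 20-min wake, are rescored. Rescored minutes count as
wake for subsequent rule applications, and only sleep→wake changes are
ever made, so rescoring can never increase TST. Epochs align to the TSO
start; a trailing partial epoch is dropped. For comparison against 30-s
reference scorings each 1-min state is duplicated.

## Scratch detection

Within the TSO, non-overlapping 3-s windows (60 samples at 20 Hz) are
gated by hand movement: the coefficient of variation (SD/mean) of the raw
acceleration magnitude over rolling 0.5-s sub-windows (one-sample stride)
must exceed **0.023** in *every* sub-window. The threshold is the
published operating point (a 25th-percentile rule over a reference data
set); re-derivation from user data is a one-liner on the CoV
distribution. A sub-window with near-zero mean magnitude has an undefined
CoV and fails the gate. The boundary is strict: CoV exactly at threshold
is not movement.

Gated windows are high-pass filtered per axis (1st-order Butterworth,
0.25 Hz cutoff, causal) to remove gravity, then reduced to three
orientation-robust signals: the vector magnitude (SVM) and the first two
principal components of the filtered samples. The PC rotation is fit per
window; each loading's largest-magnitude entry is forced positive for
determinism. Filtering precedes the magnitude/PC step so the rotation is
fit on gravity-free data.

Twelve descriptors per signal give the frozen 36-feature vector
(`features.FEATURE_NAMES`, version 1): mean cross rate (mean-level
crossings/s), dominant frequency and its power ratio (periodogram, DC
excluded), spectral entropy, spectral flatness, SPARC (spectral arc
length, 4-level zero padding, 10-Hz cutoff, 0.05 amplitude threshold),
jerk ratio (RMS of the first difference × rate / RMS), RMS amplitude,
range, IQR, skewness and kurtosis. All-zero signals return zeros for
crossing/spectral/shape features by convention. The periodicity and
smoothness members are the discriminative core: scratching is faster, more
periodic and jerkier than restless repositioning.

Training: annotated events of ≥ 3 s are tiled into 3-s windows with 50 %
overlap (the final window right-aligned to the event end; prediction-time
windows never overlap). The majority class is randomly down-sampled to the
minority count, features are selected by recursive feature elimination
with 5-fold cross-validated scoring and a decision-tree estimator, and a
**50-tree random forest** is fit on the selected features. Predictions use
a **0.5** probability threshold. Leave-one-subject-out validation re-runs
balancing and selection inside every fold so nothing from the held-out
subject leaks into training.

## Endpoints

Per night and wrist: TSO minutes; TST = sleep epochs × epoch length;
PTA = 100·TST/TSO; sleep-onset latency (TSO start to first sleep epoch);
WASO (wake minutes after onset); number of wake bouts; total scratch
events (maximal runs of consecutive predicted-scratch windows — strict
contiguity, a single non-scratch window ends a bout) and total scratch
duration (3 s × scratch-window count). Across wrists sleep endpoints are
averaged and scratch endpoints summed; a bilateral scratch event therefore
counts once per wrist, matching the summation convention. With one wrist
missing, values pass through flagged `single-wrist`. Skewed scratch
endpoints are compared on a log(x+1) scale so zero nights remain defined.
If a night has no sleep epoch at all, SOL is the full TSO and WASO and
wake-bout count are zero, by convention.

## Agreement statistics

Epoch-level: accuracy, sensitivity, specificity, PPV, NPV, F1 from the
confusion matrix, AUC when scores are available; zero-denominator ratios
are NaN with a warning. Endpoint-level: Pearson r with the two-sided
t-transform p-value, and Bland–Altman bias = mean paired difference with
95 % limits of agreement = bias ± 1.96 × sample SD (ddof = 1) of the
differences. Evaluation of scratch predictions against annotations labels
each 3-s window by majority overlap (≥ 50 % of the window inside an
event).

## The simulator

`SimConfig` scripts the study conditions; the defaults describe one
realistic overnight wear session: recording 18:00–10:00, lights-out near
23:00 and rise near 07:00 (±20 min per-subject jitter), two brief in-bed
wake bouts (~6 min), about 6 scratch and 6 restless bouts per hour of
night with lognormal durations (median 10 s, σ = 0.5, clipped to
3–120 s), scratch oscillations in 2.5–5 Hz at ~0.35 g with impulsive jerk
spikes and amplitude modulation, restless repositioning in 0.5–1.5 Hz at
~0.3 g with a smooth envelope (floored at 30 % so movement persists
through the bout) plus a small broadband tremor, quiet sleep at the
0.005-g sensor noise floor, waking movement at 0.1 g with per-minute
re-orientation, wear temperature 32 °C / non-wear 22 °C with a 5-min
exponential transition. In-bed wake bouts produce low-amplitude
restless-style movement rather than white noise, because a classifier
trained on scratch-vs-restless must also face in-bed wake movement at
prediction time. A `difficulty` knob widens per-subject frequency offsets
and in-bout noise to shrink class separation.

What the simulator does **not** emulate: limb biomechanics, real scratch
waveforms (no public raw exemplars exist), posture-dependent temperature
drift, device clock drift, or sub-second timestamp jitter. Passing the
recovery tests therefore demonstrates internal consistency of the pipeline
under its own assumptions — correct windowing, gating, scoring, recovery
of scripted structure — not clinical accuracy; the class separability of
simulated scratch vs restless movement is by construction more favourable
than annotated clinical video data.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at desk scale,
chosen to exercise every stage: 50 nights for TSO recovery in the
acceptance suite, 20 nights for the end-to-end endpoint agreement, a
10-subject × 120-window cohort for LOSO validation, and exhaustive
enumeration of all 2¹⁰ ten-epoch sequences for the rescoring invariant.
Decimation uses polyphase FIR anti-aliasing with linear edge padding;
non-integer rate ratios fall back to linear interpolation. Intervals are
half-open `[start, end)` throughout. Window tiling uses a 1-ns tolerance
on duration arithmetic so decimal durations land on the intended count.
All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawns; identical seeds give bit-identical simulations and identical
forests.
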