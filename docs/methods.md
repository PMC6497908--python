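# Methods

## Signal conditioning and events

EMG is highpass filtered with a second-order Butterworth applied forward
and backward (`scipy.signal.sosfiltfilt`, default cutoff 30 Hz), which
squares the magnitude response (80 dB/decade roll-off) and cancels the
phase, then full-wave rectified. No lowpass envelope is applied
afterwards: the phase-binning stage performs the only smoothing the
analysis needs. Edge transients are handled by `sosfiltfilt`'s default
odd-reflection padding.

Gait events come from the vertical ground-reaction force of each belt:
heel-strike when Fz rises above 10 N, toe-off when it falls below, each
crossing required to persist for a debounce window (default 20 ms) in
both directions, so isolated dips or spikes around the threshold never
produce events. The alternation invariant (heel-strike first, strictly
alternating per leg) is enforced by keeping the first of any same-type
pair. All modalities live on a common time base in seconds; events
detected on the force clock are applied to the EMG (2000 Hz) and marker
(100 Hz) streams by time, never by sample index.

## Activity vectors

Each leg's gait cycle, from its own heel-strike to the next, is divided
by the contralateral events into double support, single stance, second
double support and swing; the double-support phases are halved and the
other two quartered (2/4/2/4), giving 12 contiguous half-open bins
`[start, end)` that tile the cycle exactly. Rectified EMG is averaged
over the samples whose timestamps fall in each bin. Because each leg is
aligned to its own heel-strike, the two legs' grids are asynchronous;
legs are paired stride-by-stride in within-condition order.

Normalization is per (leg, muscle): the across-stride mean of each bin
over the last 40 included baseline strides (the condition's final stride
is excluded first, then the preceding 40 are used) defines a 12-bin
profile; its minimum maps to 0% and maximum to 100%, and the same
affine map is applied to every condition, so values outside [0, 100]
occur and are meaningful. A muscle with a flat baseline profile raises a
degenerate-normalization error naming the channel rather than silently
dropping it. The flat vector ordering is fixed — slow-leg block then
fast-leg block, muscle-major, phase-minor — because the leg-transposition
(mirroring) operation and all serialization depend on it; the component
count is not hard-coded to 360 and any consistent (legs × muscles ×
phases) indexing is accepted.

## Epochs, deltas and the structure regression

Epochs exclude each condition's first and last stride (treadmill
start/stop artifacts): *early* is the mean of the 5 strides after
dropping stride 1 (so strides 2–6; a 15-stride sensitivity variant is
available via `early_n`), *late* the mean of the 40 strides before the
final one, and *whole* (used for the 10-stride short exposure) the mean
of the 8 interior strides. The off-transition after the short exposure
uses the whole-short-exposure epoch as its "before" and the early epoch
of the following condition as its "after".

The regression design is `[-Δon(+), mirror(Δon(+))]` with no intercept,
so both coefficients are positive in the regimes of interest and
β_no-adapt = +1 reproduces the pure environment-switching limit.
Confidence intervals use normal-theory OLS covariance with n − 2
residual degrees of freedom, treating the vector components as
observations; R² is uncentered (1 − Σr²/Σy²), the appropriate statistic
for regression through the origin. The fit refuses to run when the
factors are nearly collinear (|cos(mirror(Δ), −Δ)| ≥ 0.99, i.e. when
the on-response is essentially anti-symmetric across legs), reporting
the measured cosine. Factor noise biases both coefficients toward zero;
the expected attenuation under iid component noise has the closed form
used by the recovery checks: with G = fᵀf, C = fᵀMf and λ = p·s₁²
(p components, s₁² the per-component variance of the measured factor),
E[β̂] ≈ [[G+λ, −C], [−C, G+λ]]⁻¹ [b_na·G − b_a·C, b_a·G − b_na·C].

Group-level delta vectors are the across-subject median by default
(a config switch selects the mean); the same regression and cosine
analyses are then applied to the aggregated vectors.

## Group statistics

Per-component epoch contrasts use the two-tailed Wilcoxon signed-rank
test on paired per-subject differences, with zero differences dropped
before ranking (Wilcoxon's original treatment) and average ranks for
ties. The exact null distribution (generating-polynomial recursion) is
used for n ≤ 25 untied pairs; above that, or with ties, the normal
approximation with tie correction. Effects are across-subject median
differences in % of baseline maximum.

FDR control is the Benjamini–Krieger–Yekutieli two-stage linear
step-up: stage 1 runs BH at q′ = q/(1+q); the null count is estimated
as m₀ = m − r₁; if r₁ = 0 nothing is rejected and if r₁ = m everything
is; otherwise stage 2 runs BH at q′·m/m₀. The realized critical p value
(largest rejected p, 0 if none) is reported. The display mask
additionally requires |median effect| > 10% so that significant but
negligible components are not shown. Paired short-vs-long comparisons
use the paired t test with Cohen's d = mean(diff)/sd(diff); identical
pairs are flagged degenerate rather than erroring. Spearman correlations
use average-rank ties with the t approximation for n ≥ 10 and an exact
permutation distribution below.

## The synthetic generator

The generator defines the study conditions and produces trials in which
every estimated quantity is known exactly.

**Protocol.** The default schedule is the six-condition session — slow
(50 strides, tied at 2/3·v), mid (50, tied at v), short exposure (10,
split 2:1), baseline (150, tied), long exposure (900 in three blocks),
washout (600 in two blocks) — with the treadmill stopped between
blocks (2 s gaps with both feet unloaded, wind-down events closing each
block's last strides). A compact 262-stride variant preserves every
epoch the analysis needs (early 5 / late 40 / whole-short / 40-stride
normalization window) for desk-scale runs; its faster transient
time-constant (τ = 2, zero by stride 18) dies out before the shorter
late windows just as the default (τ = 50, plateau 10, zero by stride
110) does for the full schedule.

**Activity model.** Baseline activity per muscle is a sum of truncated
Gaussian bursts in gait-cycle fraction (plantarflexors in late stance,
TA around heel-strike and swing, quadriceps in early stance, hamstrings
in late swing) over a tonic floor, identical for the two legs; burst
amplitude scales with belt speed, and the split steady state adds an
anti-symmetric modulation (slow leg up, fast leg down by the same
fraction). The on(+) corrective pattern is a smooth random field per
muscle, weighted by the local baseline activation level (corrective
responses modulate bursts, and rectified EMG cannot drop below zero at
quiet phases) and correlated across legs so that the inferred on(−)
factor stays far from collinear with −on(+) (|cosine| typically
0.2–0.5; the fit requires < 0.99).

**Transients.** After each environmental transition the activity adds a
transient equal to the stride-1 corrective delta — the on(+) pattern for
split entries, the configured mixture −b_no-adapt·Δon(+) +
b_adapt·mirror(Δon(+)) for off transitions (separate, default
environment-based, mixture for the short exposure) — anchored to where
the previous condition actually ended (the 10-stride short exposure
never reaches steady state). The transient holds its stride-1 value for
a 10-stride plateau and then decays as a shifted exponential reaching
exactly zero at a configurable stride. The plateau covers every
early/whole epoch window and the zero point precedes every late window,
so epoch-level deltas equal the stride-1 deltas exactly and the
regression recovers the configured mixture to machine precision in the
noiseless case; a plain exponential would entangle steady-state and
transient terms in the epoch averages and make exact recovery depend on
b_adapt + b_no-adapt = 1. Activity is affine in the on(+) pattern, so
if any intended value would fall below the zero-raw-amplitude floor the
corrective component alone is shrunk by one exact common factor rather
than clipped, preserving the mixture relations (the shrink engages only
for unlucky pattern draws).

**Noise** is iid Gaussian per muscle-phase-stride in normalized units
(default sd 10% of baseline max, a realistic stride-to-stride
variability relative to corrective-response components of 10–30%). The
fast path (`simulate_stride_vectors`) emits these noisy normalized
stride vectors directly — the binning-equivalent construction used for
Monte-Carlo studies; the continuous path encodes the same values in raw
signals (clipping the rare sub-zero raw excursions noise can produce).
A `pattern_seed` lets a cohort share one population response pattern
while keeping subject-specific noise.

**Signal rendering.** Events are placed on the force-sample grid with
uniform ±5% stride-duration jitter (contralateral toe-off at 15% and
heel-strike at 50% of the cycle, stance 65%, matching typical adult
interval durations); the force profile is a smooth single-hump curve
that crosses 10 N exactly at the event samples, so the detector returns
the ground-truth events bit-exactly. EMG is a ±1 square-wave carrier
(250 Hz, far above the highpass cutoff, phase-offset per channel so no
sample hits a zero crossing) amplitude-modulated by the intended bin
values in raw units (per-channel log-normal gains emulate electrode
variability; normalization cancels them). Because envelope steps leak a
little energy into the filter stopband, the generator calibrates the
envelope iteratively against the actual analysis front-end — filter,
rectify, bin with the same segmentation code — until binning returns the
intended values (5 iterations reach ~1e-9). Markers are piecewise-linear
ankle trajectories whose landing positions realize the per-stride target
step-length asymmetry (split early −0.25 adapting to −0.02, washout
aftereffect +0.15 decaying with the same transient profile) with the hip
midpoint oscillating at stride frequency.

**What the generator does not emulate** — and hence what passing tests
do not establish about real recordings: motor-unit physiology, volume
conduction, electrode crosstalk and movement artifacts; muscle-specific
adaptation time courses (one transient profile is shared); timing
asymmetries between the legs during split walking beyond stride-duration
jitter; leg-asymmetric baseline patterns (the exact-recovery guarantee
in fact relies on leg-symmetric baseline ranges — real sensor-placement
asymmetries bias β_adapt downward, which the regression itself cannot
correct); and any kinematic detail beyond ankle/hip AP positions.

## Numerical choices and problem sizes

Half-open bins make sample assignment a true partition; the boundary
sample belongs to the following bin. Empty bins raise with the stride
and phase named (impossible at 2000 Hz with 75–120 ms bins). The
detector's warning (not error) on a never-crossing force channel keeps
batch runs alive. Epoch means are plain arithmetic means; tie-breaks in
the signed-rank test and BKY edge cases follow the published definitions
noted above. Default tolerances in the test suite: 1e-6 for noiseless
end-to-end coefficient recovery (measured ~1e-13), 1e-9 for the
normalization contract, 3 Monte-Carlo standard errors for the 100-subject
attenuation check, and 2 standard errors above q = 0.05 for the 500-rep
empirical FDR bound. Tests and examples use the compact 262-stride
protocol for anything that renders continuous signals (~0.5 M EMG
samples per channel) and the full 1760-stride protocol via the
stride-vector path for Monte-Carlo work; these sizes were chosen so the
whole suite runs on a laptop in a few minutes while still exercising
every stage at the study's sampling rates and stride counts.

## Known limitations

The inferred on(−) factor is a modeling assumption (mirror symmetry of
the two legs), not a measurement; the package reports the collinearity
cosine as the diagnostic of its usability but cannot validate the
assumption itself. The per-subject attenuation of β under factor noise
is predicted, not corrected — no errors-in-variables estimator is
provided. Kinematic outputs are limited to step-length asymmetry and
stance-phase hip displacement. The CSV reader infers the sample rate
from timestamps and requires a uniform grid.
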