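# Methods

This note records the modeling conventions, tunable parameters, numerical
choices and known limitations behind `smiledyn`. The README gives the
high-level method; here we document the decisions a maintainer or reviewer
would want to audit.

## Coordinate conventions and head-motion removal

Landmarks are row vectors in OpenFace's world frame (X right, Y down, Z
depth, mm) or the image plane (px). Rotation correction post-multiplies
each frame by `Rx(−pitch)·Ry(−yaw)·Rz(−roll)` with right-handed axis
matrices; the synthetic generator applies the exact inverse product
(`Rz·Ry·Rx` forward), so correction round-trips to machine precision. The
angle-sign convention of a real pose source is not pinned by the formula
alone; the round-trip tests pin *our* convention, and a source with
opposite signs would need negated angles at ingestion. Correction is an
inverse, not a projection: applying it twice with the same pose does not
return the input.

Translation removal subtracts the inner-nostril landmark (1-based point 34,
0-based column 33) per frame. The anchor is configurable (`RunConfig.anchor`)
for sensitivity checks; eye-corner anchors are deliberately not the default
because they move during blinks. Because rotation is undone about the
camera origin rather than a head-fixed pivot, rotation correction must
precede anchoring; the composed pipeline is then exactly invariant to
per-frame rigid motion (verified to 1e−6 in tests).

Frames with failed detection are linearly interpolated from valid
neighbours; runs longer than `max_invalid_gap` (default 5 frames = 0.1 s at
50 fps) abort the episode with a QC error, since long dropouts cannot be
reconstructed. The tracker's own output is silent about how to handle
these, so this is a package policy, not an upstream one.

## Displacement variants

`from_rest` (default in both 2D and 3D modes) measures each corner's
Euclidean travel from its first-frame position and averages the sides. The
first frame is the rest reference because episodes are assumed to start
near-neutral; `reference_frame="min"` switches to the minimum-lip-width
frame for non-neutral starts. The `half_width` variant (distance from the
per-frame lip midpoint to the right corner) and the scale-free
`midpoint_normalized` variant are selectable; `half_width` is kept because
some 2D processing chains use it, but its per-frame midpoint wanders when
the corners move asymmetrically, and within-subject designs need no size
normalization — hence the from-rest default everywhere. Per-side signals
D_L/D_R are always per-corner travel from rest regardless of the pooled
method: under `half_width` both corners are equidistant from the midpoint
by construction, which would make every symmetry feature degenerate.

## Segmentation

Thresholds: apex peaks above `apex_frac`·Dmax (default 0.7), onset/offset
valleys below `onset_frac`·Dmax (default 0.2), both against the smoothed
signal's maximum; smoothing is a centred 3-frame moving average with
shrunken end windows. All downstream features are computed on the smoothed
signal so indices and values refer to the same series.

Extrema are standard local maxima/minima (a printed source formulation with
inconsistent inequality signs reduces to this under any coherent reading).
Runs of consecutive values within 1e−9 of the signal maximum's magnitude
collapse to one extremum — the tolerance absorbs last-ulp noise from the
distance arithmetic that would otherwise shatter a flat apex into spurious
micro-extrema. An extremum's reported index is its run start, but phase
boundaries use the run extent: a flat apex plateau yields an apex spanning
the whole plateau. Endpoints are eligible valleys only; a signal still
rising at its last frame has no complete apex and raises `NoSmileError`.

Onset valley search permits the episode's first frame; a flat valley's
frame is the run edge facing the apex; argmin fallbacks break ties toward
the apex. The phase partition onset = [onset, apex_start), apex =
[apex_start, apex_end], offset = (apex_end, offset] guarantees
F(S+) + F(S=) + F(S−) = F(S), matching the additivity of the published
duration statistics (0.93 + 2.97 + 1.10 = 5.00 s).

**Noise sensitivity.** On noise-free trapezoids all four boundaries are
recovered within ±1 frame (1,000 random parameterizations in the test
suite). Under i.i.d. landmark-scale noise the outer boundaries stay within
2 frames (100% of trials at σ ≤ 1% of amplitude), but the apex boundaries
are intrinsically less stable: noise inflates Dmax and creates qualifying
peaks where the 70% threshold crosses the ramps, so at σ = 2% roughly half
of trials move an apex boundary by more than 2 frames (up to ~13). This is
a property of the threshold algorithm itself, not of the implementation;
the property test asserts the measured behaviour at 1% noise (apex
boundaries within 5 frames in ≥95% of trials).

## Features

Speeds divide the summed positive (onset) or negative (offset) frame
increments by the phase duration in seconds, giving signal units per
second; this reproduces the magnitude relation max(D)/onset-duration ≈
onset speed seen in the published tables. A zero-length phase leaves the
speed NaN rather than infinite. Irregularity-a counts peaks by topographic
prominence (height above the deepest saddle toward the nearest higher
peak) exceeding 0.1·Dmax — local adjacent-valley prominence would discard
a dominant peak shattered by ripple. Irregularity-b uses the n−1 sample SD
(apex frame counts can be small); a one-frame apex has SD 0. Symmetry-a
correlates the sides over the union of the two independently segmented
smile spans (full-episode window selectable); a zero-variance side yields
NaN. Symmetry-c is right-minus-left onset frame, in frames (positive =
right corner starts later); the sign convention for Symmetry-b
(right-minus-left apex means) is fixed here but was not recoverable from
the calibration source, whose printed means are compatible with either
reading.

## Cohort statistics

QC rule (1) compares *mean* displacement over the offset phase against the
apex phase (means, not maxima: computer-vision signals are noisy, and the
same reasoning the source gives for apex means applies). The 17 features
contain two exact linear dependencies (ratios sum to one; total duration is
the sum of the phase durations), so the multivariate test drops
`total_duration` and `apex_ratio` for a 15-variable set with df1 = 15 —
one valid resolution; any other pair from the dependent groups would do.
The joint test is a one-sample Hotelling T² on condition differences:
F = T²(n−p)/(p(n−1)) on (p, n−p) df, partial η² = T²/(T² + n − 1); with
p = 1 it reduces exactly to the paired t (asserted to 1e−9), and the
implementation is cross-checked against an independent Hotelling
implementation (pingouin) in the tests. No multiple-testing correction is
applied; α = 0.01 with emphasis on effect sizes, because at n ≈ 300
trivial effects reach conventional significance.

## Synthetic episodes

The generator emulates the *structure* of the UvA-NEMO corpus — one smile
per episode at 50 fps, neutral or near-neutral start and end, genuine and
posed conditions per subject — with a stylized 68-point face whose lip
corners travel along fixed lateral/upward unit vectors following a
rise / plateau / fall scalar trajectory:

- **Ramps** are C¹ smoothstep (linear joints would create degenerate
  extrema); the plateau holds the amplitude; the fall ends at a residual
  displacement (the "trace of a smile").
- **Apex wobble** is Gaussian-smoothed white noise (kernel σ = 3 frames)
  windowed onto the plateau with short smoothstep tapers. Its scale is
  standardized so that the wobble *as seen through the 3-frame moving
  average* has exactly the drawn sample SD over the plateau — the same
  measurement convention under which the apex-SD statistics it is
  calibrated to were collected.
- **Asymmetry**: the right corner's trajectory is delayed by a signed
  integer lag, scaled by an amplitude ratio (SD 0.10, a modest realistic
  asymmetry), and its wobble shares a fraction `lr_noise_corr` of a common
  field with the left side.
- **Head motion**: optional slow sinusoidal pitch/yaw/roll (distinct
  frequencies, random phases) applied as the exact forward rotation, plus a
  rigid translation drift; i.i.d. Gaussian landmark noise is added last.

Cohort sampling draws per-subject durations, amplitude, residual and
wobble from truncated normals whose *post-truncation* mean and SD equal the
condition-level values (genuine: onset 0.93 ± 0.55 s, apex 2.97 ± 1.55 s,
offset 1.10 ± 0.89 s, amplitude 12.19 ± 3.43 mm, residual 3.04 ± 1.58 mm,
wobble 0.89 ± 0.48 mm; posed: 0.57 ± 0.24, 1.84 ± 0.74, 0.68 ± 0.34 s,
12.97 ± 3.05, 2.62 ± 1.22, 0.66 ± 0.38 mm). Truncation bounds are physical
minima (durations ≥ 0.1 s, amplitude ≥ 1 mm, residual and wobble ≥ 0, and
residual capped at 0.8 × amplitude); the underlying location/scale are
solved by moment matching, because naively truncating N(mean, SD) at the
bound would inflate e.g. the genuine offset-duration mean by ~0.22 s. The
right-corner onset lag is plain normal (genuine −1.28 ± 5.93 frames, posed
−0.49 ± 3.85), which by itself reproduces most of the observed left–right
decorrelation. Landmark noise defaults to 1% of each subject's amplitude.

**Symmetry-a calibration.** The shared-wobble fraction is solved so the
expected left–right Pearson correlation matches the condition target (0.92
genuine, 0.96 posed). Per episode, to first order,

    r ≈ (V_s − ½·lag²·M + c·ρ(lag)·f·σ_side²) / (V_s + f·σ_side² + v_noise)

with V_s the clean-trajectory variance over the smile span, M its mean
squared per-frame slope (the lag-misalignment penalty), f the apex fraction
of the span, σ_side the per-side wobble SD (itself a function of c through
the pooled-SD normalization), and ρ(lag) the wobble kernel's
autocorrelation at the lag. Short episodes have much steeper ramps, so
this expression is averaged over a fixed, deterministic 256-point parameter
quadrature drawn from the cohort distributions before solving for c; for
both conditions the solution saturates at c = 1 (fully shared wobble —
consistent with a common zygomaticus drive), the lag alone supplying the
remaining decorrelation.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: appearance-driven tracking error (noise here is
white and homoscedastic, real landmark error is correlated with pose,
expression and lighting), motion of the 66 non-corner landmarks, eye-region
action (AU6), multi-smile or interrupted episodes, perspective projection
(2D mode sees an orthographic projection), and any dependence between a
subject's two conditions (paired draws are independent, making the
synthetic paired tests conservative in power but valid in level).
Irregularity-a and the onset-lag *mean* asymmetries emerge from the wobble
and lag models rather than being separately calibrated, and sit somewhat
below the published rates; the extra-bump knob (`peak_count_extra`)
defaults to 0 and exists to exercise the prominence filter.

## Problem sizes and determinism

Recovery studies use 200 episodes per cohort and the direction-replication
analysis 297 subjects per condition — comfortably desk-scale (the full
acceptance run completes in well under a minute). All sampling flows
through `numpy.random.Generator` seeded from a single integer;
`SeedSequence.spawn` separates the two conditions' streams (the same raw
seed would otherwise give them identical standardized draws). Pipeline
outputs are bit-reproducible given config + inputs, and every feature
table records the configuration hash in its run log.

## Known limitations

- Phase boundaries inherit ±1-frame discretization from smoothing and run
  conventions; cohort onset-duration means recover ~0.02–0.05 s short and
  apex means ~0.05–0.13 s long of the generative targets at 1% noise
  (within 3 SEM at n = 200; the biases cancel in the total).
- Apex-SD recovery attenuates a few percent through sub-span selection even
  after the measurement-convention standardization above.
- The apex boundaries are noise-sensitive near the 70% threshold (see
  Segmentation); consumers needing stable apex statistics on noisy data
  should smooth more aggressively or raise `apex_frac`.
- Hotelling's T² assumes multivariate normality of difference vectors;
  with n ≈ 300 paired subjects the F approximation is robust, but at small
  n (< ~50) the per-feature bootstrap would be preferable.
- 2D mode cannot remove head rotation; on synthetic cohorts with gentle
  head motion the contrasts survive but effect sizes shift (see
  `analysis/04_2d_mode_comparison.py`).
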