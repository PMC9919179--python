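# Methods

## Sensor model and device frame

Each sensor is a tri-axial accelerometer reporting in units of g at 20 Hz.
The device frame is fixed as x = longitudinal (toward the head; along the
thigh toward the hip), y = mediolateral (positive toward the participant's
right), z = anterior (away from the skin), and sensors are assumed worn
upright; a different mounting is handled by remapping axes before
processing. At rest the measured signal is the gravity *reaction*, a unit
vector along "up": supine chest = (0, 0, 1), standing chest = (1, 0, 0),
right-side lying chest = (0, 1, 0).

Two placements are supported interchangeably — chest midclavicular left
with right thigh (MCL-TR) and chest midclavicular right with left thigh
(MCR-TL). Both diagonals run through the identical pipeline; the simulator
treats them as the same kinematics with independent noise and mounting
draws, and the test suite checks that per-class recovery differs by well
under 10 percentage points between them.

## Signal conditioning

* **Median filter**: three-point running median per axis, endpoints by edge
  replication (output length equals input length). Removes single-sample
  spikes without affecting posture content.
* **Gravity extraction**: the paper-style low-pass IIR at 0.25 Hz is
  realized as a 2nd-order Butterworth applied forward–backward
  (`filtfilt`, zero phase), so the tilt estimate does not lag reference
  annotations. Order and cutoff are parameters. The DC gain is exactly 1;
  a 2 Hz component is attenuated by ≈ 36 dB (the forward–backward pass
  squares the magnitude response).
* **Tilt angles** per sample from the gravity components (gx, gy, gz):
  φ = atan2(√(gy² + gz²), gx) ∈ [0°, 180°] (inclination of the
  longitudinal axis: 0 upright, 90 horizontal), θ = atan2(gy, gz) ∈
  (−180°, 180°] (roll, positive toward the right side), ψ = atan2(gy,
  √(gx² + gz²)) ∈ [−90°, 90°] (mediolateral tilt). These conventions are
  chosen so that supine rest reads φ ≈ 90 before any correction. θ and φ
  invert exactly back to the gravity direction, which the tests verify to
  1e−9 over random orientations. Zero-magnitude gravity samples are
  flagged and carry the previous sample's angles.
* **Baseline correction**: the mean angles over a supine rest window
  (≥ 2 s; the pipeline refuses a window whose SMA exceeds the rest
  threshold) are subtracted so that θ = ψ = 0 and φ = 90 in supine rest.
  This absorbs constant mounting misalignment exactly at supine and to
  first order elsewhere (for the ≤ 5° offsets considered realistic, the
  residual error away from supine is ≪ the 25° decision margins). Drift
  beyond a single static offset is not modeled; one calibration per
  recording.
* **SMA**: body acceleration b = raw − GA per axis; SMA(t) =
  (1/T) Σ_axes ∫ |b| dt over a T = 1 s window hopped at 0.2 s, so values
  appear natively at the 5 Hz epoch rate, centered on their windows.
  Division by T makes the value a mean rectified acceleration in g,
  commensurate with published rest-activity thresholds (0.03–0.8 g).
  Numerically, b is upsampled 4× (band-limited polyphase interpolation)
  and the rectified interpolant is integrated exactly with segments split
  at zero crossings; a plain trapezoid on 20 Hz samples of |b|
  under-reads a 2 Hz component by ≈ 3%, which is material against a
  0.03 g threshold. The SMA of a sinusoidal burst of amplitude A is
  2A/π.
* **Epoch fusion**: both sensors' angles (taken at the epoch center) and
  SMA (window centered on the epoch) are merged on a common 5 Hz grid
  covering the temporal overlap, together with the gravity magnitudes used
  by the wear guard.

## Classification

Each epoch is **static** when both sensors' SMA ≤ the rest-activity
threshold (default 0.03 g; a 0.04 g preset is provided, reflecting the
two values reported for this class of algorithm) and **dynamic** when
either is strictly above.

Static decision boundaries (degrees, all configurable):

| test | label |
|---|---|
| φ_MC < 45 and φ_T < 45 | STAND |
| φ_MC < 45 and φ_T ≥ 45 | SIT |
| 45 ≤ φ_MC < 70 and φ_T ≥ 45 | SEMI_SIT |
| 45 ≤ φ_MC < 70 and φ_T < 45 | SIT (slouched) |
| φ_MC ≥ 70, \|θ_MC\| ≤ 45 | SUPINE |
| φ_MC ≥ 70, \|θ_MC\| ≥ 135 | PRONE |
| φ_MC ≥ 70, otherwise | SIDE_SEMI_LEFT / RIGHT by roll sign |

The 45° trunk boundary separates upright from reclined, 70° reclined from
lying; the same geometry drives the semi-sit band. Side lying and semi
(reclined-side) lying merge into single left/right "side-semi" categories,
and sitting on the bed edge versus in a chair merge into SIT — distinctions
that proved clinically unimportant and geometrically marginal. A narrower
configured semi-sit band leaves a dead band that maps to UNKNOWN, as does a
resting gravity magnitude outside 1 ± 0.3 g (non-wear guard; applied to
static epochs only, because movement legitimately distorts the filtered
magnitude). Non-finite features label the epoch UNKNOWN with a logged
warning rather than raising mid-stream.

Dynamic epochs are resolved with run-level context computed in a first
pass:

* **CYCLE** — the thigh inclination shows sustained pedaling periodicity
  (dominant detrended spectral peak within 0.2–2.0 Hz (half-open band), at
  least 2 full revolutions inside a centered 4 s window, peak carrying
  ≥ 50% of the band power, amplitude ≥ 0.5°) while the trunk is not
  upright (φ_MC ≥ 45): bed cycling happens lying or semi-sitting.
  Detection uses the angle rather than the SMA because one-shot movement
  bursts put broadband power into the SMA and would masquerade as
  periodicity, while the rest-activity threshold already guarantees the
  leg is moving.
* **WALK** — the epoch lies in a *maximal upright stretch* (φ_MC < 45 and
  φ_T < 45 simultaneously) of a dynamic run lasting ≥ 3 s, with the thigh
  itself moving. Self-initiated transfers take roughly 3–5 s but change
  posture partway, so their upright stretch stays short; walking keeps
  both segments vertical throughout. (A run-level "mostly upright"
  criterion fails when walking flows directly into a sit-down, which
  merges into one dynamic run — hence the sub-run formulation.)
* **TRANSITION** — any other dynamic epoch.

Exactly one label exists for every finite feature combination (verified on
a dense grid), and a static epoch can never be WALK, CYCLE or TRANSITION.
An optional minimum-bout smoother (off by default) can absorb bouts
shorter than a configured duration into their predecessor.

## Validation statistics

* **Alignment**: sensors start before the reference video, so the clock
  offset is the time of the first SMA value exceeding an alignment
  threshold minus the start of the first annotated transition. The default
  threshold is 0.08 g — about half the plateau of a self-initiated
  transition burst — because the 1 s SMA window smears a ~0.04 g shoulder
  roughly 0.3 s ahead of the movement, and a crossing on the steep rise
  recovers injected offsets to within one 0.2 s epoch. A single global
  offset is used (no drift term).
* **Resampling**: annotations are intervals [start, end) at arbitrary
  resolution; each 0.2 s epoch takes the label covering its center
  instant (deterministic, no ties); gaps become UNKNOWN.
* **%Agr**: per class c present in the reference, 100 · #(ref = c ∧ test
  = c) / #(ref = c); asymmetric by construction, with the reference
  (ground truth or first rater) authoritative. Classes absent from the
  reference are not reported; UNKNOWN reference epochs form their own
  class and do not enter other denominators. Confusion-matrix rows sum to
  the reference class counts.
* **ICC(A,1)**: from the two-way ANOVA mean squares, ICC = (MSR − MSE) /
  (MSR + (k − 1)MSE + (k/n)(MSC − MSE)); the 95% CI uses the standard
  F-based construction for absolute-agreement single measures. A
  zero-variance matrix reports ICC 1 with a degenerate CI and a warning.
  The implementation is cross-checked in the tests against an explicit
  brute-force ANOVA and against pingouin.

## Synthetic protocols

The simulator emulates the four scripted sessions used to develop
algorithms of this kind, with a ground-truth label stream at 5 Hz:

* **natural** (408 s) and **strict** (389 s): supine → side left → side
  right → prone → semi-sit → semi-side left/right → sit → stand → 6–6.5 s
  walk → sit, with self-initiated 3–4 s transitions; static holds 34–40 s.
* **healthcare provider** (403 s): supine, side left/right, semi-sit and
  sitting only (no prone, standing or walking), returning to supine
  between activities, with 1.5–2 s provider-assisted transfers.
* **bed cycling** (287 s): 19 s supine rest, then 130 s flat cycling and
  132 s semi-sitting cycling at 0.5 Hz cadence with 25° thigh swing.

Static postures are fixed gravity orientations; transitions rotate the
gravity vector along a great circle with a minimum-jerk profile (velocity
peaks mid-transition), routed through supine for near-antipodal turns such
as side-to-side rolls. A movement burst (2 Hz carrier under a smooth
envelope, rectified mean equal to the burst amplitude) accompanies each
transition: 0.10 g when self-initiated, 0.02 g when assisted. Walking adds
2 Hz, 0.3 g bursts on both sensors (SMA ≈ 0.19 g); cycling oscillates the
thigh orientation, which both drives the SMA above threshold and leaves a
small (~1.5°) in-band ripple in the filtered thigh inclination that the
periodicity detector keys on.

For assisted transfers the provider eases a passive patient over a
handling envelope ~8× longer than the annotated 1–2 s core in which the
posture visibly changes (raters mark transition onset at the velocity
peak). This keeps the slow rotation inside the gravity filter's passband:
a geometrically faithful 90° roll executed entirely within 1–2 s would
leak 0.05–0.2 g into the SMA through the 0.25 Hz filter and make assisted
transfers trivially detectable — the opposite of their documented
signature. With the envelope, assisted-transfer SMA peaks at ≈ 0.026 g,
just under the 0.03 g threshold, reproducing the failure mode: transition
agreement collapses to ~0% on the healthcare-provider script while
natural/strict transitions stay near 90%.

Noise model (defaults): white accelerometer noise 0.005 g per axis; slow
(< 0.1 Hz) posture wobble of 2°; a fixed random mounting misalignment of
up to 5° per sensor, which the supine calibration later removes. All
randomness flows from one seed; identical (script, seed, configuration)
inputs give bit-identical recordings.

What the simulator does *not* model: biomechanical gait or ergometer
dynamics, soft-tissue artifacts, sensor drift over hours, irregular or
hesitant real-patient movement, and rater disagreement. Passing the
synthetic validity bar therefore demonstrates the internal consistency of
the pipeline (signal model → features → rules) under controlled, idealized
kinematics, not clinical performance on patients.

## Numerical choices and degenerate inputs

* Threshold ties: SMA exactly at the rest-activity threshold is static
  ("strictly above" is dynamic).
* θ is wrapped to (−180°, 180°]; −180 maps to +180 (prone is one class for
  both senses of the wrap).
* The 5 Hz epoch grid places centers at (k + ½) · 0.2 s; an n-sample
  stream at rate r spans n/r seconds; frames cover the overlap of both
  sensors.
* Label smearing: the 1 s SMA window and the zero-phase 0.25 Hz filter
  spread movement evidence ~0.5–2.5 s around each posture change, so
  predicted transitions are slightly wider than annotated ones. The
  noiseless consistency test therefore demands exactness only in bout
  interiors (> 2.6 s from a boundary); with default noise this smearing
  bounds per-class agreement on the synthetic protocols at roughly 89–96%
  rather than 100%.
* Problem sizes: the validation runs use single protocol sessions
  (~6.5 min, ~2000 epochs each), which gives every activity class dozens
  to hundreds of reference epochs while keeping the whole suite fast.

## Known limitations

* Angle cut-offs are geometric defaults, not patient-fitted; slumped
  sitting, walking aids, or atypical mountings will need tuning (the
  config is a single dataclass and every boundary is exposed).
* Assisted transfers are, by design of the threshold, largely invisible —
  the package reproduces and quantifies this failure mode rather than
  solving it.
* A single supine calibration assumes the patient can be placed supine at
  rest once per recording.
* The cycling detector assumes quasi-periodic pedaling at 0.2–2 Hz; very
  slow or very irregular cadences fall back to TRANSITION.
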