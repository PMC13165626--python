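# Methods

This note documents the modelling and numerical choices behind the
package, the parameters that matter, and what the bundled synthetic data
can and cannot establish.

## Kinematic definitions

All angles are arccos of normalized dot products and therefore invariant
to global translation, rotation (with a co-rotated vertical axis) and
uniform positive scaling; the cosine is clamped to [−1, 1] so near-collinear
inputs never raise a domain error. The degeneracy epsilon for vector norms
is 1e-9 input units (configurable).

Two conventions exist in the ergonomics literature for the elbow and trunk,
and both are exposed rather than silently chosen:

* elbow *vector* convention (angle between shoulder→elbow and elbow→wrist,
  straight arm = 0°) versus *anatomical interior* (straight arm = 180°);
* trunk *deviation from vertical* (upright = 0°) versus *interior*
  trunk/hip angle (upright = 180°).

The kinematics layer always reports the vector/deviation forms; each fuzzy
input variable declares a `transform` (`identity` or `supplement`) stating
which scale its membership table is written on. Reach distance is defined
as the Euclidean wrist↔mid-hip distance — mid-hip (midpoint of the hips,
pelvis as fallback) is the stable seated-trunk origin — optionally
normalized by arm length (|shoulder→elbow| + |elbow→wrist|). Side selection
defaults to the right arm (the side nearest the furniture in seated cabinet
work) and is always an explicit parameter, never inferred.

A frame missing a joint needed for one angle yields an invalid (NaN) entry
for that angle only; frames are never dropped, so counts are conserved
through the whole pipeline. Optional linear interpolation across gaps of at
most 5 frames exists but is off by default — fabricating coordinates should
be a deliberate choice.

## Membership tables (shipped defaults)

No published parameter set exists for this fuzzy system, so the defaults
are constructed from the classical RULA angle bands, with ±5° complementary
ramps at every internal boundary (memberships of adjacent labels sum to 1
in each transition region):

| variable | scale | labels (plateaus) |
|---|---|---|
| shoulder | elevation = 180° − raw angle | low ≤15, medium 25–40, high 50–85, very_high ≥95 |
| elbow | interior angle | neutral ≥140, moderate 110–130, extreme ≤100 |
| trunk | deviation from vertical | upright ≤15, slight_forward 25–55, bent ≥65 |
| trunk_rotation (optional) | axial twist | not_twisted ≤20, twisted ≥30 |
| risk (output) | score | low [1,2], medium [3,4], high [5,6], very_high {7}, ±0.5 ramps |

Shoulder breakpoints 20°/45°/90° are the classical upper-arm bands. The
elbow table runs on the interior scale with severity increasing as the arm
flexes (boundaries 105° and 135°): the moderate plateau 110–130° brackets
the flexed-elbow envelope characteristic of low-drawer reaches, while a
near-straight arm is neutral. This is a deliberate monotone simplification
of the classical lower-arm rule (which also penalizes full extension
slightly); a monotone severity ordering per variable is required for the
risk surface to be monotone, which we consider the more valuable property
for a continuous score. Trunk breakpoints 20°/60° follow the classical
trunk-flexion bands.

The trunk-rotation variable has no geometric formula in this package (no
reliable twist angle can be derived from the 17-joint skeleton without
additional assumptions); rules that reference it are inert unless the
caller supplies a rotation channel explicitly.

## Rule base

Eight representative multi-joint rules (R1–R8, covering combinations from
all-neutral → low up to very-high shoulder ∧ extreme elbow ∧ twisted trunk
→ very high) are combined with seven single-antecedent *backbone* rules,
one per non-neutral label of each joint (e.g. `elbow is moderate → medium`,
`trunk is bent → very_high`). Two properties motivated the backbone design:

* **Coverage.** With multi-joint rules alone, most of the input space fires
  nothing. With the backbone, any posture with a non-zero severe membership
  fires a backbone rule, and an all-neutral posture fires R1 — so the
  no-activation state is unreachable under the defaults (hitting it with a
  custom config raises by default; `neutral` and `carry` fallback policies
  are available).
* **Monotonicity.** Backbone rules exist only for non-neutral labels; the
  low band is asserted solely by the all-neutral rule R1. If neutral labels
  also pushed the low band, a fully relaxed joint would pin low-band mass
  at 1 under max-aggregation and *dilute* the centroid when another joint
  escalates — the score could fall as severity rises. As shipped, a dense
  1° sweep of any input from its mildest to its severest plateau (others
  mild) is non-decreasing; this is asserted in the test suite. The trunk
  `bent` and elbow `extreme` backbone consequents map to `very_high`
  because max-aggregation with a wide `high` consequent would otherwise cap
  extreme single-joint postures near 5.6.

Rule weights default to 1.0 (no published values exist); with weights the
firing strength is min(antecedent minimum, w), so a weight acts as a
credibility ceiling on a rule. With only single-antecedent rules the
aggregate reduces exactly to the per-joint max–min form
μ_total(r) = max_i min(μ_i, w_i).

## Defuzzification

Centroid over [1, 7] by trapezoidal quadrature on a uniform grid with step
0.01 (601 points, enforced as a minimum). Against a 10×-refined grid the
centroid deviates by < 1e-4 across random rule activations (asserted in
tests); the piecewise-linear aggregate makes the trapezoid rule nearly
exact, with the residual coming from grid points straddling clip corners.
Scores are deterministic: identical inputs and config give bitwise
identical output.

## Temporal layer

Smoothing is the trailing (causal) mean over {t−w+1, …, t}, w = 5 frames at
30 fps by default. Partial windows at the start average over the frames
available so far, and invalid frames are excluded from numerator and
denominator alike, so one bad frame neither poisons nor biases its window.
w = 1 is the exact identity (special-cased to avoid cumulative-sum
round-off). Discretization is round-half-up (4.49 → 4, 4.50 → 5), chosen as
the symmetric rule about band centers; categories follow the standard
action bands. A separate binary reporting flag counts frames above a
configurable threshold (default 4.0). Phase segmentation is purely
index-based with half-open intervals and defaults (30, 120) appropriate for
~150-frame task recordings; there is deliberately no changepoint detection.
Exposure (high + very-high share of valid frames) is computed on smoothed
levels by default — smoothing exists precisely to stop single-frame jitter
from flipping categories — with `use_raw` available for sensitivity checks.

## Synthetic motion generator

The generator is a minimal trajectory model, not a biomechanical
simulation: each angle follows neutral → plateau → neutral with
half-cosine ramps across the approach and withdrawal phases, a per-sequence
Gaussian subject offset on the plateau (SD 3°/3°/2° for
shoulder/elbow/trunk), and i.i.d. Gaussian frame noise (SD 2°, a
placeholder for pose-estimator jitter — no quantitative noise level for
monocular 3D keypoints was available to calibrate it). Randomness comes
from one stream per (seed, task) pair, so adding tasks never perturbs
existing sequences, and generation is bitwise reproducible.

The five task profiles place execution-phase plateaus inside the envelopes
characteristic of each task: shoulder raw angle 140–160° for sliding-door
and mid-height tasks versus 130–140° for low tasks; interior elbow 110–130°
for low reaches (flexed arm) versus ≥135° otherwise; interior trunk
165–175° (deviation 5–15°), leaning further forward as the target lowers.
Under the default fuzzy config these profiles yield mean smoothed risk
increasing strictly in the order sliding door < mid drawer < mid hinged
door < low drawer < low hinged door (hinged doors and low placements are
worse), with every task showing the inverted-U phase shape — execution
outranks approach and withdrawal.

Pose synthesis is the constructive inverse of the angle definitions: the
torso and right-arm chain are laid out in the sagittal plane with in-plane
rotations equal to the requested angles, so kinematic recovery reproduces
the series to ~1e-12 degrees (tested at 1e-6); the remaining joints are a
static seated template whose segment lengths can be scaled without
affecting any angle.

What passing these tests does *not* show: the generator contains no
camera model, no occlusion, no correlated or heavy-tailed estimator error,
no left-right asymmetry and no genuine inter-joint coordination, so results
on it demonstrate the correctness and calibration of the scoring pipeline,
not the field accuracy of any pose estimator feeding it.

## Problem sizes and determinism

The test suite and acceptance script use 1000 random vector pairs for the
geometry oracle, 200–500 random membership tables for the fuzzy-engine
oracles, and 50 seeded 150-frame sequences per task (250 total) for the
end-to-end statistics — sizes at which every statistical margin in the
assertions is several standard errors wide while the whole suite runs in
well under a minute. All randomness is seeded; CLI outputs are written
atomically (temp file + rename) and are byte-identical across reruns.

## Known limitations

* Only shoulder, elbow and trunk enter the score; classical RULA's wrist,
  neck and leg items have no formulas here and are out of scope.
* Absolute score levels depend entirely on the membership tables; the
  shipped defaults are a documented, checksummed reference point, not a
  clinically validated calibration. Comparative statements (task A worse
  than task B, phase-resolved structure) are the robust outputs.
* The trunk-rotation channel must be supplied externally; R7/R8 are inert
  without it.
* Exposure thresholds (30%/50%) and the binary threshold 4.0 are reporting
  conventions, configurable per run, and carry no statistical guarantee.
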