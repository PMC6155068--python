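# Methods

`planotaxis` models how a planarian with two pigment-cup eyes turns away
from light, and provides the statistics used to summarize orientation
assays. This note records the model, its assumptions, the default
parameters, and the design choices made where the sources of the model
leave the design open.

## The optical model

Each eye is a nondioptric pigment-cup ocellus: the semilunar pigment cup
shades the photoreceptors from one side, so the input is proportional to
the illuminated receptor area, which for a semicircular cup is the sine
of the angle between the incoming light and the shading plane. With the
light bearing θ measured from the anterior body axis (degrees, positive
to the animal's right) and the eyes each rotated by β = bf/2 toward the
midline, the per-eye inputs are

    L(θ) = max(0, −sin(θ − bf/2)),   R(θ) = max(0, sin(θ + bf/2)),

clamped to [0, 1] (maximum input 1.0). The clamp is the total-function
form of restricting θ to the range where the sine is non-negative. The
model implicitly gives each eye a 180° monocular field; the measured
monocular field (α ≈ 172.6°) enters only the morphometric helper
`posterior_blind_field` = 2(180 − α + β), never the simulator.

Closed forms used throughout (θ > 0, mirror-symmetric on the left):

* binocular zone (θ ≤ β): R − L = 2 cos β · sin θ;
* front blind-like spot half-angle at threshold τ:
  `asin(τ) − β` when `asin(τ) ≥ bf` (crossing in the monocular zone),
  else `asin(τ / (2 cos β))`;
* response band upper edge: `180 − asin(τ) − β`.

With bf = 40° and τ = 0.5 these give a blind-like spot of ±15.43°
(rounds to 15°) and a response band of (15.4°, 130°). Every closed form
is checked in the test suite against a 0.01° brute-force grid scan.

## The behavioral rule

The animal thresholds the absolute input difference. At or below the
response threshold τ (default 0.5) it glides straight; above it, it
turns away from the brighter side by

    Δφ = gain · (|R − L| − τ)   [radians, converted to degrees],

with gain = 3. The gain term is interpreted on the radian scale
(`gain_units="radians"`, a config switch exposes the degree reading):
radian-scale turns reach ~86°, commensurate with the head-sway angles
the coefficient is meant to approximate, whereas degree-scale turns of
≤1.5° would also put the wigwag-off twin-tail separation near 100°
instead of the observed ~58°. The turn law is applied symmetrically
left/right (sign of R − L chooses the direction away from the light).

## Wigwag self-motion

Wigwag is spontaneous, brain-independent side-to-side head sway. Sway
angles follow Normal(0, 18.7°²); intervals between sways follow a
log-normal with log-mean μ = −0.15 and log-SD σ = 0.44 (seconds), hence
natural-scale mean exp(μ + σ²/2) ≈ 0.948 s and median exp(μ) ≈ 0.861 s.
(Reported per-event frequencies of "once per ~0.7–0.77 s" bracket these;
the package's defaults follow the fitted (μ, σ), and the turn-away-time
helper takes the interval as an explicit argument.)

**Coupling of sway to motion.** The simulator's default,
`wigwag_mode="sensing"`, treats the sway as a motion of the *head*, the
organ carrying the eyes: at each event the world is sensed at the swayed
bearing θ + ξ; if the sensed difference stays at or below τ the head
swings back and the body glides straight, and if it exceeds τ the body
executes the commanded turn and follows the head (ξ enters the new
heading together with the turn term). This coupling is what makes the
front blind-like spot behaviorally meaningful: an agent facing the light
glides toward it until a sway larger than the spot half-angle lets it
sense the light's side — with the 15° spot and 18.7° sway SD, a fraction
2(1 − Φ(15/18.7)) ≈ 42% of sways suffice, so at ~0.7 s per sway the
animal turns away within ~1.7 s. The alternative reading, in which ξ is
simply added to the gliding direction every event and sensing uses the
true body bearing, is available as `wigwag_mode="heading"`; under that
reading the heading random-walks out of the blind-like spot within a
couple of events regardless of bf, toward-light stragglers never occur,
and the escape efficiency becomes monotone in bf (no optimum at an
intermediate binocular field) — measurably at odds with the behavior the
model exists to explain, which is why it is not the default.

When wigwag is disabled, ξ ≡ 0 but the event clock still runs on the
same log-normal intervals.

## The arena simulation

Light is directional (parallel rays): the physical source sits ~30 cm
from a 4 cm arena, so ray divergence is negligible and the light bearing
depends only on the agent's heading. Agents start at the arena center
with uniform random headings and advance one unit step per wigwag event
(positions `(x + sin φ, y + cos φ)`); a step corresponds physically to
roughly speed × mean interval ≈ 0.8–0.9 mm. A run ends at the arena edge
(default radius 40 steps) or after `max_events` (default 400). The
two-source assay (OA2L) combines inputs per eye by summation before the
final clamp — the minimal linear rule, which reproduces the bow-tie
escape pattern perpendicular to both sources.

Perturbation models: lidocaine anesthesia multiplies the affected eye's
input by a gain in [0, 1]; eyecup removal strips the pigment shield, so
the eye responds as |sin| (light admitted from both sides). Silencing
one eye biases escape toward the silenced side; unshielding one eye
biases away from it, and the bias is rescued by lowering the same eye's
gain — both directions match the classic manipulations.

Randomness: each agent draws from a generator seeded by
`(master_seed, agent_index)`, so enlarging a cohort never reshuffles
earlier agents, and identical (config, seed) gives byte-identical
trajectories.

## Trajectory statistics

* **Circular summary.** Mean resultant length R of the exit bearings;
  circular SD √(−2 ln R); precision index 1/√(−2 ln R) (infinite for
  R = 1, zero for R = 0).
* **Escape value.** Net displacement projected on the light-propagation
  axis divided by path length: 1 = straight away, −1 = straight toward.
* **Twin-tail separation.** Exit bearings in the light-at-0° frame are
  split at 180° into left (<180°) and right (≥180°; the boundary is
  assigned right for totality) groups; the separation is the absolute
  difference of group medians.
* **Rose histogram.** 90°-wide bins centered on toward/right/away/left.
* **Turn-vs-light regression.** OLS r² of the signed turn angle on the
  signed light bearing, on all pairs and restricted to |bearing| ≤ 130°.
  Signed rather than magnitude regression is used deliberately: the turn
  *magnitude* is an inverted-U in |θ| (the input difference rises to 90°
  and falls again), so magnitude-on-magnitude OLS is near zero even on
  noiseless model data, whereas the signed turn-away rule is an odd,
  near-linear function of the bearing inside the band.
* **Wigwag extraction.** Turning events are sign reversals of the
  supra-deadband heading increments; the sway angle is the heading
  change accumulated over the run a reversal ends, the interval the time
  between reversals. The deadband (default 1°) suppresses tracking
  jitter; on clean, noise-free heading channels use deadband 0, because
  a deadband drops sub-threshold sways and merges their same-sign
  neighbours, inflating the fitted SD by several percent.
* **Distribution fits.** Maximum likelihood: normal (mean, 1/n-variance
  SD) for sway angles; log-normal via the normal MLE of log intervals.

Per-animal orientation averaging, where needed, uses the circular mean
(the arithmetic/circular choice is not otherwise pinned down).

## Synthetic tracking fixtures

`generate_tracking` emulates video-tracking exports in physical units
(mm, s): gliding at 1.0 mm/s sampled at 30 Hz in a 40 mm arena, heading
piecewise constant between sway events, event times log-normal, sway
amplitudes |Normal(0, 18.7°²)| with strictly alternating sign. The
alternation is the side-to-side structure of real head sway; it leaves
the pooled signed sway distribution exactly Normal(0, sd²) while making
reversal-based extraction recover every individual sway. Events are
scheduled in continuous time but executed at the next frame boundary, so
per-frame displacement is exactly speed/frame_rate and interval
quantization error is below one frame (negligible against the 3-SE
recovery tolerances). With phototaxis enabled the threshold-gated turn
rule acts at each event on top of the sway.

What the fixtures do *not* emulate: body deformation and head-vs-
centroid tracking offsets (heading = movement direction is a deliberate
simplification), wall-following, occlusions, pixelation noise. Passing
round-trip tests therefore shows the analytics are correct on data with
the assumed statistical structure, not that they are robust to every
artifact of real video.

`generate_turn_dataset` emulates turn-angle scatter: uniform light
bearings; inside the response band the model turn plus Normal(0, 20°)
noise (a realistic behavioral/measurement scatter); outside it a uniform
reorientation on (−180°, 180°].

## Problem sizes and numerical choices

Simulated cohorts in the tests and the reproduction script use 40–250
agents per condition (40 matches the wigwag-off cohort convention;
sweeps use 250 per binocular-field value), 20–25 replicate cohorts for
seed-averaged quantities, and 10⁴ draws for parameter-recovery checks;
these sizes put Monte-Carlo error well inside the tolerances asserted.
Angles are stored in degrees at every interface and converted to radians
only inside trigonometric calls; bearings are wrapped to (−180°, 180°]
(headings, light bearings) or [0°, 360°) (exit bearings). Resultant
lengths within 10⁻¹² of 1 (or 0) are flagged as infinite (zero)
precision rather than propagated through the logarithm.

## Known limitations

* The turn rule is memoryless; temporal integration of flashed light and
  habituation are out of scope.
* Wall interactions (thigmotaxis, wigwag restriction by a wall) are not
  simulated; the arena edge only terminates a run.
* The event-driven unit-step kinematics ignore speed variation; the
  physical calibration of a step is recorded in metadata, not used in
  dynamics.
* Whether summed two-source inputs should saturate before or after the
  per-eye clamp is not derivable from first principles here; summation
  then clamping is the package's choice, flagged in the config schema.
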