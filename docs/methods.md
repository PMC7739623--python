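# Methods

`stsbalance` analyzes the balance of sit-to-stand (STS) transfers from
optical motion capture and two force plates (one under the stool, one
under the feet).  This note documents the models, the numerical
choices, and what the synthetic validation data do and do not show.

## Whole-body state

Every balance metric derives from five aggregate quantities computed
per sample from body-segment states (mass `m_i`, COM position `r_i`,
velocity `v_i`, world-frame inertia `J_i`, angular velocity `w_i`):

- COM position and velocity: mass-weighted means.
- Inertia about the COM (parallel-axis sum over segments):
  `J_C = sum_i J_i + m_i ((d_i . d_i) I - d_i d_i^T)`, `d_i = r_i - r_C`.
- Angular momentum about the COM:
  `H_C = sum_i J_i w_i + d_i x (m_i (v_i - v_C))`.
- Average angular velocity `w_avg`: solution of `J_C w_avg = H_C` --
  the angular velocity of the single rigid body that carries the same
  angular momentum as the whole multibody system.  Samples with a
  near-singular `J_C` (condition number above 1e12) are flagged as
  missing rather than raised.

Segment states come from each segment's marker cluster via a
least-squares rigid fit (batch Kabsch/SVD).  Velocities are central
differences on the filtered 150 Hz signals (one-sided at the series
ends); segment angular velocities come from finite rotations between
the samples two steps apart.  These schemes are design choices -- the
underlying event definitions do not prescribe a differentiator -- and
are deliberately mirrored by the synthetic generator's ground truth so
that noise-free round trips are exact.

Marker and force streams are low-pass filtered with a bidirectional
(zero-phase) Butterworth filter, cut-off 10 Hz.  The order is not
dictated by the event definitions; we use 4th order applied
forward-backward (effective 8th-order magnitude), configurable.  Force
streams (900 Hz) are decimated 6:1 onto the marker clock (150 Hz) after
filtering; the 10 Hz filter anti-aliases the decimation.  Marker gaps
are linearly interpolated up to a configurable span (default 0.1 s);
longer gaps reject the trial.

## Functional base of support (BOS)

The functional BOS of one foot is the convex region in which the centre
of pressure (COP) can be placed under at least half body weight with
the foot flat.  It is measured from COP-excursion recordings:

- Foot frame: origin midway between the ankle markers (FAL lateral, TAM
  medial); y-hat toward the midpoint of FM1/FM5; x-hat the component of
  (TAM - FAL) orthogonal to y-hat; z-hat = x-hat x y-hat.  A
  calibration transform anchors the origin to the ground with z-hat up
  (heading preserved); in this calibrated frame a right foot's medial
  side maps to negative x, which is why right-foot profiles are
  reflected about y-hat before averaging.
- Foot width `w = x . (1/2 (TAM - FAL) + 1/2 (FM1 - FM5))` and length
  `l = y . (FM2 - FCC)`.
- Flatness: with an intrinsic X-Y'-Z'' Euler decomposition of the foot
  rotation relative to its calibration pose, the foot is flat when
  `w sin(psi_X) <= 1.5 cm` and `l sin(theta_Y) <= 1.5 cm` (inclusive);
  the 1.5 cm allowance covers heel-pad plus shoe-sole compression.
- Template: valid COP samples (flat, normal force > body weight / 2)
  are normalized by (w, l), hulled per foot, right feet reflected, and
  the hulls averaged radially about the anchor (-0.15, 0.3) in
  left-foot normalized space.  "Dense" ray sampling uses 360 rays by
  default (sub-millimetre radius resolution at foot scale).  A ray
  average of convex polygons need not be convex, so the result is
  convexified by a final hull.
- Per trial, the template is rescaled by each foot's (w, l), placed via
  the calibrated frames, and the whole-body BOS is the convex hull of
  both feet's polygons.  Balance margins are signed distances to the
  hull boundary: positive inside, negative outside.

The packaged default template (`data/bos_template.json`) is built from
a synthetic COP-excursion recording and is labelled as such; users with
real excursion data should build their own with `build_template`.

## Static balance

A body is statically balanced when it has not fallen and its linear and
angular speeds are *small*, operationalized as the range observed in
quiet standing.  Four per-sample metrics: signed COM-ground-projection
to BOS-edge distance (`d_bg`), COM-to-COP distance, COM speed
`||v_C||`, and average angular speed `||w_avg||`.  Still-standing
bounds are the per-subject minima/maxima over a 10 s quiet-standing
window, averaged across subjects; signed metrics (here the vertical
average angular velocity used by the applicability check) are
symmetrized by the larger magnitude.  The COM-COP alignment bound is
taken from quiet standing rather than zero because segment-model error
keeps that distance nonzero even at rest.  The static-balance test
itself requires `d_bg >= 0` (COM ground projection inside the BOS) plus
the three speed/alignment bounds.

## Foot placement estimator (FPE)

The FPE is the ground contact point at which an inverted-pendulum
abstraction of the body would passively rotate up into a balanced
standing pose.  Per sample:

1. Travel frame: t-hat along the horizontal component of the angular
   momentum about the COM ground projection,
   `H_G = H_C + h z-hat x (m v_C)`; s-hat = t-hat x z-hat.  The cross
   product order is fixed so forward travel gives positive `v_s1`.
   When the horizontal momentum is below threshold the frame falls back
   to the horizontal COM velocity direction, then to the previous
   frame; leading samples with no usable heading are flagged.
2. Planar projection: `v_s1 = v_C . s`, `v_z1 = v_C . z`,
   `w1 = w_avg . t`, `J = t^T J_C t`, `h = r_C . z`.
3. Contact angle: the residual

       f(phi) = (m h (v_s1 c + v_z1 s) c + J w1 c^2)^2 / (m h^2 + J c^2)
                + 2 m g h c (c - 1),     c = cos(phi), s = sin(phi)

   (angular-momentum conservation at contact combined with the energy
   balance `1/2 (J + m l^2) w2^2 = m g (l - h)`, leg length
   `l = h / c`) vanishes at the balancing angle.  `f(0) >= 0` always
   and `f -> 0^-` at `pi/2`, so a sign change brackets the root:
   bisection (48 halvings) followed by a Newton polish with the
   analytic derivative, falling back to bisection whenever a Newton
   step leaves the bracket.  Solutions must satisfy `|f| <= 1e-8 m g h`.
   Bodies whose net planar angular momentum about the contact,
   `m h v_s1 + J w1`, is negative are solved in the mirrored plane and
   the angle negated (the travel-frame construction makes this case
   impossible in the pipeline, but raw inputs may hit it).  The FPE
   ground point is `r_F = r_G + (h tan phi) s-hat`.
4. Metrics: vertical average angular velocity `w_avg . z` (the
   applicability check flags samples whose magnitude exceeds the
   still-standing bound -- the planar projection then loses
   information, cautioning interpretation without suppressing values),
   the dynamic balance margin `d_bf` (signed FPE-to-BOS-edge distance),
   and the COP-to-FPE displacements along t-hat (turning) and s-hat
   (propulsion).

In the point-mass limit (`J = 0`, `v_z1 = 0`, `w1 = 0`) the residual
reduces to `v^2 cos^3(phi) = 2 g h (1 - cos(phi))`, a depressed cubic
in `cos(phi)` with a Cardano closed form; the solver is checked against
it and against exhaustive 10^6-point scans of `|f|`.

`post_contact_outcome` classifies a candidate step by the first
integral of the post-contact rotation instead of integrating the
pendulum ODE -- equivalent under energy conservation: momentum transfer
gives the post-contact rate `w2`; if the rotation moves away from
upright-over-contact the model falls in that direction; otherwise the
kinetic energy is compared against the `m g (l - h)` climb, with a
small arrival-rate tolerance defining "balances".

## Movement segmentation

Stage one clusters COM height and seat-plate vertical force into three
k-means++ clusters each (scikit-learn, 10 restarts, seeded), labelling
clusters by mean (height: lowest = seated, highest = standing; force:
largest = seated, lowest = standing).  Candidates are standing-height
runs of at least 0.5 s connected backwards in time to a seated-force
run (also >= 0.5 s) with exactly one transition-force -> standing-force
switch in between; "connected backwards" is operationalized as: the
most recent seated-force sample before the standing run, with the
transition count taken over the span between.  Candidates during which
fewer than 3 of either foot's 6 markers stay within 15 mm of vertical
excursion are rejected (`foot_moved`).  A seated-force run that is
unloaded and re-loaded with no accepted stand in between is recorded as
a `sit_back` failure.

Stage two refines events with adaptive thresholds: initiation where the
COM speed first exceeds its minimum over the seated-force set by
1 cm/s; seat-off where the seat force first comes within 1 N of its
unloaded reference (median over standing-height samples), searched on
the filtered, decimated force stream; stance where the COM height is
within 1 cm of the median standing-cluster height while the vertical
COM speed is below 1 cm/s in magnitude (the absolute value is used for
robustness to small overshoots).  Unreachable thresholds reject the
candidate with reason `event_not_found`.

## Statistics

The eight balance metrics at seat-off plus the total (initiation to
stance) and rise (seat-off to stance) durations are averaged over
repetitions per participant; within-subject variability is the range
(max - min) over repetitions, analyzed as its own metric.  Group
contrasts use the Wilcoxon rank-sum test (unpaired) and the Wilcoxon
signed-rank test (paired condition contrasts), two-sided, alpha 0.05,
no multiplicity correction.  For groups of at most 25 the p-value is
exact: the null distribution of the (midrank) rank-sum statistic is
enumerated by dynamic programming over doubled midranks, giving
`P(|W - E[W]| >= |w_obs - E[W]|)`; identical groups yield p = 1 under
this convention.  Larger samples use the normal approximation with tie
correction.  Summaries are medians with 25-75% interquartile ranges
(linear-interpolation quantiles).

## Synthetic data

The generator emulates the mechanical structure the analysis assumes,
not any particular cohort's trajectories (which are not publicly
specified): a planar sagittal chain -- shank, thigh, head-arms-trunk
(HAT) over two static feet -- follows smooth quintic-interpolated
segment-pitch schedules from sitting (trunk lean, then hip rise and
trunk extension) to standing, with about 2 s of still sitting and
standing on either side.  Markers (IOR-style foot markers plus
four-marker clusters per chain segment), seat and foot plate forces and
COPs are emitted at 150/900 Hz with white Gaussian noise added last
(defaults 0.5 mm markers, 0.5 N forces).  Segment parameters come from
a packaged anthropometric table (documented constants in
`anthropometry.py`); gravity is 9.81 m/s^2.  Ground-truth events,
whole-body state and metric series are computed from the same chain
with the same finite-difference schemes the pipeline uses, so noiseless
round trips agree to numerical precision.

Notable design points:

- **Seat force taper.** The seat unloads over a fixed phase window via
  a quintic smoothstep blended with a linear ramp whose end slope is
  fixed (165 N/s).  A pure smoothstep approaches zero with vanishing
  slope, which would place the 1 N seat-off detection threshold many
  samples before the designed zero-force instant; the fixed linear end
  slope puts the crossing within a fraction of a 150 Hz sample of the
  designed event for any body weight and pace, while keeping the
  slope-change at zero small enough that the zero-phase filter moves
  the crossing by well under a sample.  The force is exactly zero from
  the designed seat-off onwards (before noise).
- **Subject variation as outcome targets.** Each subject draws seat-off
  targets -- COM speed (anchor 0.45 m/s, SD 3 cm/s), COM ground
  projection shift (SD 1.2 cm) and FPE forward-offset shift (SD
  0.7 cm) -- and the plan is solved to hit them: the active-phase clock
  is rescaled for speed (exact, since positions are functions of phase
  only), a trunk pitch-rate boost through seat-off is found by 1-D root
  finding for the FPE offset (nested inside the speed anchoring), and a
  whole-chain translation realizes the COM shift last.  This emulates
  how humans regulate movement outcomes rather than joint angles, and
  keeps within-group spreads at the tight end of what such cohorts
  exhibit so that designed group effects of a few centimetres are
  cleanly detectable at 8-10 subjects per group.  Older-group offsets
  (`group_offsets`, in cm and cm/s) add to the same targets.
- **Failure designs.** `sit_back` partially unloads the stool with a
  brief hip-rise bump and returns to sitting; `foot_lift` raises four
  of the right foot's six markers by 20 mm during the rise.  Both must
  be rejected by segmentation.
- **Quiet standing** applies band-limited (1 Hz low-pass) ankle-strategy
  pitch and roll sway to the standing pose, rescaled so the horizontal
  COM excursion SD matches the configured value exactly; the COP
  follows the COM ground projection with a small fixed bias and
  band-limited wander.  The seat plate is unloaded.
- **COP excursion** loads one foot at a time at 62% body weight while
  the COP spirals over a known convex region fixed to the calibrated
  foot frame, with deliberate foot-roll segments (violating the 1.5 cm
  flatness allowance) whose COP strays outside the region; the roll
  on/off transitions are accompanied by unloading below half body
  weight, as when a person rolls onto the toes.  Template recovery is
  validated against the known region's area.
- The trunk-lean onset causes a sub-millimetre dip in COM height just
  after initiation; the monotone-rise contract on the generator is
  therefore stated to a 1 mm running-max drawdown.
- An optional yaw parameter injects nonzero vertical angular momentum
  to exercise the FPE applicability check; the default trials are
  perfectly planar, so `w_avg . z` is zero up to noise.

What passing tests show -- and not.  The synthetic cohort validates the
*machinery*: exact aggregation, solver correctness, geometric
recovery, segmentation timing, statistical calibration, and end-to-end
effect recovery.  It does not validate biomechanical fidelity to real
STS kinematics: trajectory shapes, noise spectra (real soft-tissue
artifact is neither white nor stationary), force-plate dynamics
(emitted forces are quasi-static plans, not inverse dynamics), and the
true inter-subject covariance structure are all stylized.  Conclusions
about real cohorts require real recordings.

## Problem sizes and runtime choices

Default validation sizes: 10 young + 8 older subjects x 5 repetitions
(~6-7 s per trial at 150/900 Hz); 1000 random solver inputs against
10^6-point residual scans; 1000 random point/polygon pairs; 20
no-effect replicate cohorts for false-positive calibration in the test
suite (5 in the acceptance script).  These sizes give stable estimates
while keeping the full validation in the minutes range on one CPU.

## Known limitations

- No C3D reader: the on-disk format is the documented TSV dialect.
- The planar generator cannot produce genuinely three-dimensional
  momentum patterns (e.g. asymmetric pathologies); the yaw parameter
  is a perturbation, not a model of turning.
- The BOS template averaging assumes the anchor point is interior to
  every profile hull, and mirror symmetry of the averaged template is
  exact only when the anchor lies on the mirror axis.
- `compare_groups` implements exactly the two designs used here
  (unpaired two-group, paired two-condition); it is not a general
  modelling interface.
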