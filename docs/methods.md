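# Methods

This note documents the models and numerical choices in `funkam`, the
conventions a user must know to interpret its output, and the limits of
what the synthetic test bed demonstrates.

## Frames and sign conventions

The laboratory frame is X anterior, Y up, Z to the subject's right; the
model is right-sided. Every segment frame is lab-aligned in the neutral
standing pose, with origins at the proximal joint centers (thigh at the hip
joint center HJC, shank at the knee joint center KJC, talus at the ankle
joint center AJC). A `RigidTransform` maps local to lab coordinates
(`p_lab = R p_local + t`); columns of `R` are the segment axes in the lab.

Knee and ankle joint frames use the joint-coordinate-system (JCS)
orientation produced by the functional construction — `z` along the
flexion axis pointing medial→lateral, `x = unit(z × u)` with `u` the unit
vector from KJC to HJC (knee) or AJC to KJC (ankle), `y = unit(z × x)` — so
in the neutral pose `x` points posteriorly and `y` distally. Coordinate
axes inside those frames are chosen so that flexion, adduction, internal
rotation, dorsiflexion, inversion and toe extension are positive. The knee
rotation sequence is intrinsic Z–X–Y (flexion, adduction, rotation);
gimbal lock sits at ±90° adduction, far outside the protocol's range.

**EAM definition.** All pipelines report the *external* knee moment — the
moment exerted on the distal segment system about the joint center by
gravity, inertia and the plate load — projected onto the *floating
adduction axis* of the JCS sequence (the frame `x`-axis after the flexion
rotation, with the adduction-positive sign). For generalized-coordinate
models this is identically the external generalized force of the knee
adduction coordinate, which is what an inverse-dynamics tool reports for
that coordinate; for the model-free REF standard the same axis is formed
from the transferred JCS and the decomposed flexion angle. Projecting the
moment into the distal joint frame instead (`express_moment_distal`) gives
the same number whenever the knee internal-rotation angle is zero, which
holds exactly for the generator's trials. Using one definition everywhere
makes CON / FUN 1 / FUN 2 / REF differences attributable to the models, not
to the reporting convention.

## Functional calibration

* **OCST.** Alternating optimization: pose the current common shape to
  every frame (weighted SVD Procrustes with a `diag(1,1,det)` reflection
  guard), update the shape as the mean of back-transformed observations,
  re-center, repeat until the max marker displacement between successive
  shapes (after optimal alignment) falls below 1e-9 m or 200 iterations.
  Initialization is the first fully visible frame; for rigid-dominant data
  any frame works. Non-convergence flags the result instead of raising.
  The per-frame residual is non-increasing by construction (each step
  solves a least-squares subproblem exactly).
* **SCoRE.** The stacked system `[R_p(f) | −R_c(f)]·[c_p; c_c] = t_c − t_p`
  over all frames, solved by least squares. A smallest-singular-value ratio
  below 1e-8 (pure hinge, or no relative rotation) raises an ill-posed
  error; a total relative rotation below 15° only warns — an advisory
  threshold chosen here.
* **SARA.** The axis direction is the right-singular vector of the smallest
  singular value of the same system, its halves normalized per segment; the
  axis points come from the null-suppressed particular solution, shifted to
  the point closest to each cluster centroid (minimum-norm solutions depend
  on the local origin; this choice is reproducible). Ill-posedness is
  declared when no isolated near-null direction exists (`s5 < 2·s6`, or
  rank < 5 for motionless input). The ±sign of the axis is fixed by the
  medial→lateral epicondyle (knee) / malleolus (ankle) vector in the static
  reference, keeping flexion signs stable.
* Joint centers: the epicondyle/malleoli midpoints projected orthogonally
  onto the functional axes. All parameters are stored in carrier frames
  (OCST shapes of the pelvis markers, thigh/shank clusters and foot
  markers) and transferred to any trial by posing the carriers frame by
  frame. Calibration documents serialize to versioned JSON/YAML.

OCST-corrected poses feed SCoRE/SARA directly; cluster shapes are estimated
once (pelvis from the StarArc, thigh/shank from the knee sweep, foot from
the ankle sweep) and reused everywhere so stored parameters live in a
single consistent frame per carrier.

## Model, scaling and functional-axis integration

The generic subject is 1.74 m / 64 kg. Segment lengths follow stature
fractions (thigh 0.245·H, shank 0.246·H), masses are fractions of body
mass, and inertias are diagonal with radius-of-gyration fractions of
segment length; the table lives in `funkam.anthropometry` as a declared
constant. Because the model is unilateral, the contralateral leg, arms and
head are lumped into the torso so the 7 segments conserve total body mass —
the torso lump never enters the knee/ankle/hip moments, which depend only
on the distal subtree. The optional flexion-coupled tibiofemoral
translation is a piecewise-linear lookup in the femur-side knee frame,
default off: the EAM is governed by axis orientation, not by the small
sagittal gliding translation.

Scaling (CON) is isotropic per segment: thigh and shank factors from the
functional HJC–KJC and KJC–AJC spacings, pelvis from the inter-ASIS span,
foot from the heel→metatarsal-II span (both configurable choices), torso
following the pelvis. Lengths, marker placements and centers of mass scale
linearly, masses keep the generic fractions of the subject's mass, and
inertia scales by mass × length². Model markers are then re-seated on each
segment from the static reference (per-segment SVD pose; the markerless
talus and single-marker toes are placed through the chain at zero joint
angles), so the scaled model reproduces the static capture exactly.

* **FUN 1** reorients only the proximal joint frames (femur-side knee,
  tibia-side ankle) to the functional JCS expressed in the segment through
  its cluster markers. Because each segment's scale factor derives from its
  own joint spacings and markers, the iterative proximal-to-distal ordering
  reduces to per-segment scaling here. FUN 1's distal frames stay generic,
  so with tilted axes its neutral pose cannot match the static capture
  exactly at the hinge ankle — the small residual that distinguishes it
  from FUN 2.
* **FUN 2** reorients proximal *and* distal frames of knee and ankle on the
  already-scaled CON model, leaving translations, default relative segment
  orientations and markers untouched. With an identity calibration both
  variants reduce bitwise to CON.

## Inverse kinematics and dynamics

IK minimizes the weighted squared marker residual per frame with a damped
Gauss–Newton iteration on the analytic marker Jacobian (axis/lever-arm
form, assembled from the same forward pass that caches every coordinate's
instantaneous world axis). Convergence: step norm < 1e-8 or objective
change < 1e-12, at most 100 iterations; non-converged frames are flagged
with the best iterate. Cluster/tracking markers weigh 1.0, anatomical
landmark markers 0.1 (they constrain points, not segment rotations, and
carry more skin artifact); the ratio is configurable. Trials are solved
with warm starts, coordinates are filtered (zero-lag Butterworth, 6 Hz
default), and derivatives use central differences with one-sided endpoints.

Inverse dynamics is a two-pass Newton–Euler evaluation: an outward pass for
segment kinematics, an inward pass accumulating subtree loads (inertial
terms, weights, the plate wrench at its center of pressure; moments
accumulated about the world origin for a branch-free recursion). The
generalized force of a coordinate is the transmitted wrench projected on
its instantaneous axis. Three independent oracles pin the implementation:
the gravity-off statics closed form `(p − KJC) × F + couple`, a direct
subtree-summation of every joint moment, and the power balance
`Σ τ·q̇ = dKE/dt − P_gravity − P_external`, which holds to machine
precision for any consistent state. Wrench transport invariance (moving
the application point with the transported couple) is asserted as well.
`g = 9.81 m/s²`; %BWHt is `100·M/(m·g·h)`. High-rate wrenches are low-pass
filtered before decimation onto the kinematic grid, with the same cutoff
as the kinematics.

**REF** computes moments without generalized coordinates: transferred
functional centers and JCS triads define the frames, segment inertial
parameters come from the same anthropometric table (lengths from the
transferred centers, the lumped foot offset carried by the foot markers'
static anatomical triad), angular kinematics from finite differences of the
carried triads. REF and the coordinate models therefore share anthropometry
by construction — a deliberate choice so that variant differences isolate
axis geometry.

## Real-time mode

Each frame: one warm-started IK solve, causal EMA on the coordinates
(α = 0.1525), first/second backward differences on the filtered
coordinates, one ID evaluation. The step clock is injectable, so replay
tests are deterministic and the 8 ms robot-control deadline accounting
(mean ± SD, max, overrun count/percent) can be tested with a mock clock;
wall-clock step times are reported but never asserted — they are
hardware-dependent. The stream interface is a plain iterator of
timestamped marker/wrench samples; on an IK failure the previous
coordinates are held and the frame flagged.

## Synthetic test bed: what it does and does not show

A synthetic subject is a scaled generic model (anthropometry sampled
around 64 ± 8.3 kg, 1.74 ± 0.052 m; per-segment scale jitter 2 %) whose
knee/ankle joint frames are rebuilt from a *tilted* flexion axis via the
same JCS construction the calibration uses — so the functional parameters
are exactly recoverable and every pipeline error is attributable.
Reference movements (StarArc rays + circumduction arc, 40° default
amplitude; knee/ankle sweeps) and leg-press trials are rendered by forward
kinematics at 100 Hz by default. Static trials hold 80° hip / 50° knee
flexion while the plate force ramps (0.5 s smoothstep) to 60 % of a
1200 N MVC proxy; dynamic trials extend along a fixed hip-to-foot ray at
0.025 m/s from 80° to 40° knee flexion (the grid duration is rounded so
the endpoints land exactly on the sampled frames; with tilted axes the
prescription is applied in coordinate space, so the foot speed deviates at
the sub-percent level). The plate force points from the contact point
toward the hip, tilted ±12° in the frontal plane for the everted/inverted
foot positions. Ground-truth moments come from the subtree-sum oracle on
the true state, never from the recursive pass they validate.

Noise is optional and seeded: white Gaussian marker noise (anatomical
landmark markers get 3× the cluster sigma, reflecting their larger skin
artifact — and motivating both their low IK weight and the sensitivity
result that cluster-less marker sets track the reference worst), a
low-frequency sinusoidal per-cluster soft-tissue-artifact field with random
phase and direction, and random occlusions.

The generator does **not** model real soft-tissue artifact fields,
marker-placement error relative to the bony landmarks, force-plate noise or
drift, muscle-driven dynamics, or plate compliance. Passing tests
demonstrate the *algorithmic* correctness and the geometric mechanism of
the CON-vs-functional comparison (axis misalignment leaking sagittal moment
into the frontal plane), not the magnitudes any real cohort would produce.

## Problem sizes

The test suite and acceptance script run reference movements of 4–8 s and
trials of ~2 s at 25–100 Hz, cohorts of 20–100 seeded subjects per
property — sizes chosen so the full suite exercises every pipeline stage in
a few minutes on one core while leaving the medians and orderings they
assert stable across seeds.

## Known limitations

* Scaling is isotropic per segment; no per-axis factors.
* The knee translation coupling, when enabled, is piecewise linear.
* REF's inertial terms rely on finite differences of marker-derived frames
  and are only exercised in quasi-static regimes; its statics are exact.
* The CLI covers single trials; cohort orchestration is the library's job.
* C3D input is not supported; TRC/MOT/STO text formats are the interchange.
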