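# Methods

## Model overview

The simulator represents the right upper limb as a rigid-body tree rooted at
the thorax: thorax, head, clavicle, scapula, humerus, ulna, radius, hand
(eight segments), plus the four implant bodies (glenoid ring, PE bearing,
ball head, offset adapter) in the dual-bearing configuration.  Joints are
fixed (0 DOF), hinge (1), gimbal (2) or ball (3); multi-axis joints are
ordered intrinsic rotations about declared unit axes through a common centre.
The elbow and wrist are fixed joints: they do not move during the protocol
motions.  Ligaments, contact and friction are not modelled; the friction
omission is justified quantitatively by the Coulomb bound below.

Quasi-static assumption: motions are slow (and noisy captures are made slow
by the ×1000 time stretch), so inertial terms vanish and equilibrium holds
pose by pose.  The muscles plus idealized reserve actuators must balance the
generalized gravity torques of the segment masses and the 2 kg hand load.

### Coordinates and the gleno-humeral parameterization

Global frame: right-handed, y up, x anterior, z lateral (right side).
The gleno-humeral ball joint uses the intrinsic sequence
Z (plane/flexion) – X⁻ (elevation) – Y (axial, internal positive).  A Y–X–Y
(plane-of-elevation) sequence was rejected deliberately: it is singular at 0°
elevation, which is exactly where the entire internal/external-rotation
protocol lives — axial rotation would be unidentifiable from markers there
and the IK round-trip property would fail by construction.  The chosen
sequence is well conditioned at the arm-at-side posture; its singularity sits
at 90° elevation, an isolated interior pose.  Trajectory samples straddle it
(the minimum-jerk profile never lands a sample within ~3° at the default 25
steps) and the forward-kinematics layer emits a gimbal-lock warning if a pose
comes within 2° of alignment.  The DBSP realizes the same 3 rotational DOF as
hinge (ring axis) + gimbal (elevation, axial); protocol trajectories are
mapped onto each model's coordinates by inverting the joint parameterization
against the desired humerus-relative-to-scapula rotation (3-angle nonlinear
least squares, warm-started along the motion).

### Shoulder girdle

Scapulo-thoracic gliding is replaced by a simplified scapulohumeral rhythm:
one driven hinge coordinate (scapular upward rotation) set to
(elevation − 30°)/2 above 30° of elevation, zero below, and toggleable off
for a scapula-fixed ablation.  The coordinate is marked *driven*: its reserve
actuator is an ideal drive excluded from the effort penalty and from the
feasibility verdict, mirroring the use of trunk actuators to follow the
prescribed motion.

## Muscle apparatus

39 tensile elements over the seven studied groups: anterior/middle/posterior
deltoid 4/4/7, subscapularis 11, infraspinatus 6, teres minor 3,
supraspinatus 4.  All three models share the identical attachment coordinates
and Hill parameters; only the joint assembly and wrap surface differ.  The
supraspinatus elements remain present but inactive in both prosthesis models
(zero force, zero equilibrium columns), reflecting its surgical sacrifice.

Force model: `F = a·f_max·f_L(l̃)` with rigid tendon
(`l_fiber = L_path − l_slack`, clamped at 0), force–velocity ≡ 1
(quasi-static), and the active force–length curve a Gaussian bell
`exp(−((l̃−1)/0.45)²)` truncated to zero outside `l̃ ∈ [0.5, 1.5]`.  An
exponential-toe passive term exists but is disabled by default: the
comparison concerns activation-driven forces.  Linearity of `F` in `a` at
fixed geometry is what makes the redundancy resolution a convex QP.

Parameters (defaults, units):

| parameter | value | why |
|---|---|---|
| hand load | 2.0 kg at the palm | the held object in the protocol |
| group Σf_max | ant. deltoid 505 N, mid. 1190 N, post. 1580 N, supra 620 N, infra 1420 N, teres minor 500 N, subscap 1430 N | calibrated to the force/activation ratios implied by the packaged reference table (e.g. 136.3 N / 0.27); split evenly across elements |
| l_opt | deltoid 0.14 m; cuff 0.06–0.10 m | keeps normalized fiber length within the active range over the full 120° excursion |
| l_slack | per element | fixed once on NS geometry so each element sits at l̃ = 1 at 45° elevation; reused unchanged by RSP/DBSP (shared muscle set) |
| wrap inflation | 10 mm (half deltoid thickness) | deflects the muscle mid-line, not its surface |
| reserve weight w_r | 10⁴ (gain 1 N·m) | reserves engage only when muscles cannot produce the torque; reserve > 0.01 N·m on a non-driven DOF flags the step |
| friction coefficient μ | 0.05 | upper bound for UHMWPE on CoCr |

The attachment coordinates are synthetic and anthropometrically plausible
(168 cm male proportions; humerus 310 mm, forearm 245 mm, arm segment masses
2.03/0.65+0.55/0.45 kg); they are **not** cadaver ground truth.  They were
chosen so the baseline lever arms are realistic — NS middle-deltoid elevation
arm ≈ 23 mm at 30°, rising with elevation; the medialized RSP/DBSP centres
lengthen it to ≈ 35–38 mm, the design mechanism of reverse-type implants.

## Muscle path geometry

Paths are polylines origin → via points → insertion, deflected by at most one
wrap surface per segment.  Sphere wrapping is exact: the tangent–arc–tangent
route in the plane through the two points and the centre, with the grazing
tie broken to *unwrapped* (the length is continuous across the boundary).
Ellipsoid wrapping discretizes the on-surface portion as 8 surface points
(spherical-angle parameterization of the scaled sphere), seeded from the
exact sphere solution in the scaled space and minimized by L-BFGS with an
analytic gradient.  The polyline chord-vs-arc error is ~10⁻⁵ m at implant
scale — far below any physiological relevance, though short of the 10⁻⁹
attainable for spheres; increasing the point count tightens it quadratically.

Moment arms follow the tendon-excursion definition `r = −∂L/∂q`, available
two ways: central finite differences of the solved path length, and the
analytic anchor-Jacobian (virtual-work) form used to assemble the
equilibrium matrix.  By the envelope theorem the wrap tangent points count as
material points of the wrap body, so only straight segments contribute; the
two routes agree to ≤ 10⁻⁵ m and both match the geometric
perpendicular-distance oracle on toys.  Wrap-side selection is by shortest
path; when a segment passes very near the wrap centre the selected side can
switch between poses — the length is continuous there even though the arm
changes sign, which is why the default geometry keeps the deltoid line
clearly lateral of its wrap centre.

## Load resolution

Per pose: `τ_required = −τ_gravity`; activations solve
`min Σa² + w_r Σ(s_j/g_j)²` s.t. `R·diag(f_gain)·a + s = τ_required`,
`0 ≤ a ≤ 1`.  Eliminating the reserves `s` reduces this to box-constrained
linear least squares (`scipy.optimize.lsq_linear`, BVLS, tol 10⁻¹⁴) — a
strictly convex problem with a unique, deterministic minimizer; KKT
stationarity is verified in tests.  Driven coordinates carry unpenalized
ideal drives.  Equilibrium holds to ≤ 10⁻⁶ N·m at every accepted step of
every motion on all three models; infeasible steps (none under the default
conditions) would engage reserves, be flagged and kept, never dropped.

The joint reaction force is the Newton free body of the subtree distal to
the named joint: gravity plus the net muscle forces applied to distal bodies,
each straight path segment pulling its two anchors together and wrap contact
entering through the tangent-point anchors on the wrap body.  For the DBSP
the reported joint is the scapula–ring interface, so the deltoid's pressure
on the ring wrap is part of the reported reaction — deliberately so, since
that is the load the unanchored ring transmits to the glenoid.

## Synthetic motion capture and IK

The marker stage emulates a surface-marker capture: 11 landmark-style
markers (3 thorax, 3 scapula, 3 humerus, 2 forearm/hand) at 100 Hz-style
sampling, i.i.d. Gaussian noise per axis (default studies use σ = 2 mm),
deterministic per seed.  What it does *not* emulate: soft-tissue artifact
(markers ride rigidly on their segments), marker dropout, correlated noise,
and subject-specific anthropometry.  Passing IK tests therefore demonstrate
estimator correctness — noise-free round trips recover coordinates to
≤ 10⁻⁶ rad, 2 mm noise leaves the elevation estimate unbiased within 0.2°
over 100 seeds — not robustness to real capture pathologies.

IK is per-frame Gauss–Newton on the stacked marker residuals using the
analytic point Jacobian, warm-started from the previous frame, minimum-norm
steps via least squares (100-iteration cap, flagged frames on
non-convergence).  No smoothing is applied; instead, noisy coordinate series
are made quasi-static by stretching the time base ×1000, which scales implied
accelerations by 10⁻⁶.  A screening helper flags series whose peak implied
angular acceleration exceeds 10⁻³ rad/s²: raw noisy IK output fails it, the
stretched series passes.

## Protocol motions

Abduction and scaption: 0→120° elevation (scaption in a plane 30° anterior
to the coronal — a fixed convention choice), with the scapular rhythm.
Internal rotation 0→40°, external rotation 40→0° by default (the source
protocol is ambiguous about the ER direction; a switch selects 0→40°).
Elbow posture per motion: extended for elevation motions; flexed 90° with
the forearm anterior for IR/ER — the clinical rotation-testing posture, and
necessary for the rotations to be mechanically meaningful (with a straight
hanging arm, gravity exerts no torque about the vertical humeral axis).
Profiles are minimum-jerk, so start and end at rest.  Default 25 samples per
motion: static optimization has no temporal coupling, so sampling density
only affects peak localisation; 25 samples resolve the peak tables while
keeping the full 3×4 study under a minute on one CPU.

## Implant geometry

RSP: centre of rotation on the anteroposterior glenoid midline 18 mm above
the inferior rim (≈ 25 mm medial, 2 mm superior of the natural centre in
this geometry), 36 mm glenosphere, wrap 56 mm.  DBSP: 55 mm ring tilted 10°
downward on the glenoid face; hinge about the ring axis at the ring centre;
gimbal centre offset 10 mm laterally along the ring axis (the true offset is
not published — 10 mm is a declared, configurable assumption); medium offset
adapter folded into a single 14 mm lateral translation; ellipsoid wrap
75×75×28 mm (ring diameter inflated in-plane by the 10 mm half-thickness of
the deltoid).  The scapula–ring connection is modelled as welded, which is
what makes the ring reaction force observable.

## Friction bound

The simulator is frictionless.  Justification, recomputed on the simulated
models themselves: the Coulomb moment of a spherical/annular bearing is at
most μ·JRF·r at the outer bearing radius (r = 18 mm RSP, 27.5 mm DBSP).
With μ = 0.05 and each model's own peak abduction JRF and peak gleno-humeral
moment, the ratio is ≈ 2.2% (RSP) and ≈ 3.5% (DBSP) — below 4%, so
neglecting friction does not affect the comparison.  This outer-radius bound
is a conservative reconstruction; the original analytical calculation is not
public.

## Known limitations

* Synthetic geometry: absolute forces and reactions are not comparable to
  the published magnitudes (which rest on an unpublished cadaver-calibrated
  138-element model); only mechanical properties and directional trends are.
* The other 22 muscle groups are representable in the data model but carry
  no calibrated parameters; their role is absorbed by the driven scapular
  coordinate and reserve actuators.
* Single wrap surface per path segment; no cylinder/torus wraps, no
  muscle–muscle collision, no volumetric muscle.
* No activation dynamics, fatigue, force–velocity effects, contact
  mechanics, wear, or dislocation analysis.
* The scapulohumeral rhythm is a fixed 2:1 kinematic rule, not a
  physics-based scapulo-thoracic joint.
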