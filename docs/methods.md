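# Methods

## Coordinate spaces and transforms

Six named spaces cover the guidance chain: IMAGE (the preprocedural MRI/CT
volume), PATIENT_FRAME (the fiducial-bearing reference frame), NEEDLE_FRAME
(the tracked plate on the needle), WORLD (the headset), CAMERA and
SNAPSHOT_2D (the calibrated monocular snapshot).  A `RigidTransform` maps
the coordinates of a point from its source space to its destination space,
so chained products read left to right.  Rotations are stored as 3×3
matrices validated orthonormal with det +1 to 1e-8; quaternions are
accepted at I/O boundaries and normalized on read.  All lengths are mm and
all API-boundary angles degrees.  Scaling, affine and deformable maps are
out of scope: every link in the chain is rigid.

## Registration and the error budget

`register_points` solves the least-squares rigid fit between labeled
fiducial sets by the Kabsch/Umeyama SVD construction with the reflection
corrected through the sign of the determinant; correspondence is by label,
so row order is immaterial.  The fit is exact (FRE < 1e-9 mm) on noise-free
correspondences; an independent numerical optimizer over a rotation-vector
parameterization is used in the test suite as a brute-force oracle.

The fiducial localization model is isotropic zero-mean Gaussian per
coordinate, FLE² = 3σ².  Because only the FRE of a deployed system is
observable, simulations are calibrated by inverting the small-noise
identity E[FRE²] = (1 − 2/N)·FLE²; for the 7-marker frame and an FRE of
0.81 mm this gives FLE ≈ 0.958 mm (σ ≈ 0.553 mm per axis).  The FLE
magnitude is always a calibrated or configured quantity, never a constant:
how fiducials were localized in the source images (sphere centroids vs
manual clicks) is unknown, so no default pretends to know it.

TRE prediction offers two methods.  The closed form
TRE²(r) = FLE²/N·(1 + ⅓Σₖ dₖ²/fₖ²) is evaluated about the fiducial
principal axes (dₖ: target distance from axis k; fₖ: RMS fiducial distance
from axis k).  The frame's seven markers are coplanar on a flat plate,
which drives one fₖ to zero and makes the closed form ill-conditioned, so
`MONTE_CARLO` is the default prediction method and `CLOSED_FORM` raises a
degenerate-configuration error (directing the caller to Monte-Carlo) when
any principal RMS extent is ≤ 1e-6 mm.  The Monte-Carlo path perturbs the
fiducials, refits, and maps the target, vectorized over replicates (a
stacked-SVD batch fit), so 1e5 replicates run in under a second.

Caliper error on the physical frame measurements is a separate, independent
Gaussian on the PATIENT_FRAME-side coordinates, default 0 (no caliper
accuracy is known).

## Scene geometry

PATIENT_FRAME convention: origin at the center of the working-window base
edge, x lateral, y up along the lower plate, z into the phantom, so
"distance from the frame base" is a single axis.  The working window is
95×70 mm in the z = 0 plane; the 90×80 mm upper plate shares the window's
top edge as a hinge and is tilted 60° away from the phantom (dihedral angle
between plate normals 60°).

The exact marker layout on the plate is not part of the published hardware
description.  The default is a fixed asymmetric 7-point pattern spanning
the plate whose 21 pairwise distances are all distinct, so label
correspondence is geometrically unambiguous and registration has no
symmetric degeneracy; it is overridable via config.  Fixture scenes carry a
fixed non-identity PATIENT_FRAME→IMAGE pose so the registration problem in
simulations is never trivially the identity.

Generators:

* **Test plate** — four beads at the corners of a 40×40 mm square centered
  on the working window, at 50 or 100 mm depth (eight targets over the two
  positions).
* **Gel phantom** — four beads inside a D=100 × L=120 mm cylinder at
  60–80 mm depth; four entry points drawn (seeded, rejection sampling) on
  the surface so plan depths are N(79.6, 3.1) mm in [70, 90] and approach
  angles from the surface normal N(12.8°, 6.8°) in [0°, 28°], matching the
  physical protocol's statistics; plan depth equals ‖target − entry‖ by
  construction.
* **Pelvic fixture** — a synthetic stand-in with five targets (two
  seminal-vesicle surrogates, three pseudolesion centroids with 0.5–0.7 cm³
  spherical extents, radii 4.92–5.51 mm).  Positions are invented,
  anatomically plausible values for guidance scenarios, not measured data.

## Guidance logic

`free_hand_update` is a pure function of target, needle pose, needle model
and thresholds.  The proximity display uses the 5-mm vicinity ring
(tip-to-target-center, since experimental targets are beads); a 1-mm "hit"
threshold — a design addition, configurable — gives simulated controllers a
stop criterion.  The shaft alignment threshold (default 3°) is likewise a
configurable design choice: the display distinguishes correct from
off-center angles without publishing a numeric cut.  Predicted miss is the
closest approach of the *forward* needle ray to the target (tip distance if
the target is behind the tip), so it never exceeds the tip-target distance.
Depth remaining in free-hand mode is the along-axis distance to the point
of closest approach: this mode has no planned depth and the stop decision
is the operator's.

`planned_path_score` returns the common-perpendicular distance between the
needle axis and the planned segment (plan parameter clamped to the planned
depth), the inter-axis angle, and the inserted depth along the plan minus
the planned depth (positive = past the length marker).

## Simulated experiments

The frame is fixed in the world (true frame-to-world pose = identity);
tracking noise perturbs that pose as a random rotation (axis uniform on the
sphere, Gaussian angle) about the tracked plate's centroid plus a Gaussian
translation.  The snapshot camera is an ideal pinhole at 450 mm working
distance whose mm calibration is fixed by the known 40-mm bead square at
that distance; snapshot bead-detection error is not modeled, keeping the
overlay metric a pure function of pose and registration noise.

* **Overlay**: per device position (default 7 positions × 8 beads = 56
  records) a fresh registration with fiducial and caliper noise and a fresh
  tracking draw; the bead is mapped image→world through the noisy chain and
  codisplayed with the physical bead; the calibrated 2-D distance is the
  record.  The protocol count is a parameter (`n_positions`): the published
  n of 56 corresponds to 7 positions, while the protocol text describes 9 —
  the two cannot both hold, so neither is hard-coded.
* **Targeting**: the physical tip touches each bead from 3 seeded approach
  poses (24 records); the virtual tip passes through the noisy
  needle-tracking chain and the virtual bead through the frame chain;
  snapshot distance recorded.  With both chains active the error variance
  is the sum of the single-chain variances (independent draws).
* **Placement**: per operator (default 3), per method, per plan (4): the
  displayed target/plan goes through the noisy frame chain; a simulated
  operator inserts in 1-mm steps; the record is the 3-D distance from the
  final physical tip to the true bead.  The planned-path operator perturbs
  entry (lateral σ) and direction (angular σ) once — it has no tip feedback
  — and stops at the planned depth plus a depth-σ draw.  The free-hand
  operator re-aims at the displayed target each step with angular noise and
  stops at closest approach plus a depth-σ draw; its per-insertion
  needle-tracking perturbation is inverted to find where the physical tip
  is actually steered when the displayed tip meets the displayed target.

Operator sigmas are not observable separately in a physical study (only
totals are reported), so the defaults are *calibrated*: planned-path
(angle 1.1°, lateral 1.0 mm, depth 3.4 mm) and free-hand (1.0°, 1.0 mm,
4.8 mm) were chosen once so default placement runs land near ~4.1–4.2 mm
total error, and are labeled as calibrated, not measured.  The split of
overlay error between registration and device tracking is likewise not
identifiable from a total; the noise model keeps them as separate knobs and
the default sets only the registration component (tracking σ = 0).
Repositioning lag and display jitter affect usability rather than static
accuracy; an optional jitter σ on the perceived tip exists and defaults
to 0.

An all-zero noise model provably produces zero error in all three
experiments; every experiment is reproducible under a fixed seed.

## Statistics

`compare_groups` applies a Shapiro–Wilk gate per group (gate alpha 0.05 by
default — not published, so configurable), then a pooled Student's t-test
if both pass, otherwise a Mann–Whitney U; all tests are two-sided.
`t_test_from_summary` recomputes pooled (or Welch) t-tests from mean/sd/n
triples, enabling re-analysis of printed summaries; on raw-data summaries
it matches the raw-data Student's t to 1e-9.  `anova_oneway` takes whatever
grouping the caller supplies with df (k−1, N−k); no attempt is made to
reverse-engineer groupings behind published df that are inconsistent with
the stated protocol.  Degenerate conventions: equal-mean zero-variance
groups give p = 1; unequal-mean zero-variance input is an error.

## Problem sizes and numerical choices

Monte-Carlo sizes were chosen for tight estimates at interactive runtimes:
1e5 replicates for identity/agreement checks (relative MC error ≈ 0.3%),
5000 for FRE closure, 2000 for TRE at the bead positions, 1-mm operator
step size, and 50–200 seeds for null-behaviour checks.  Ties and degenerate
inputs fail fast with typed errors (collinear fiducial sets, label
mismatches, space mismatches in transform chains, coplanar closed-form TRE
requests).

## Limitations

The simulator reproduces geometric error propagation, not human factors:
learning effects, viewing-angle-dependent display calibration, stereo
perception and timing are out of scope.  The snapshot model omits
bead-detection error, so simulated overlay error is a lower bound on a
physical measurement at equal pose noise.  Operator models are minimal
policies matching the two described behaviours; real operators correct
laterally in planned-path mode too, so the per-method error decomposition
(not the totals) should be read qualitatively.  Passing tests demonstrate
self-consistency of the calibrated simulation with the reported
registration accuracy, not agreement with any new hardware.
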