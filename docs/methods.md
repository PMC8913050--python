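# Methods

`aclgait` models how the tibial insertion site (TIS) chosen in single-bundle
ACL reconstruction changes the graft force during walking.  The pipeline has
four stages: synthetic knee kinematics → a femur→tibia rigid transform per
cycle sample → a passive straight-line ligament element → an insertion-site
sweep with waveform statistics.

## The ligament element

The ACL graft is a single passive elastic strand on a straight line between
a femoral insertion point (femur frame) and a tibial insertion point (tibia
frame).  With length `L`, resting length `L0` and strain `e = (L − L0)/L0`,
the tension is the standard toe-region law

    f(e) = 0                    e ≤ 0
    f(e) = 0.25 k e² / e_l      0 ≤ e ≤ 2 e_l
    f(e) = k (e − e_l)          e ≥ 2 e_l

with stiffness `k = 3100 N`, linear strain limit `e_l = 0.03` and
`L0 = 2.8 cm` by default (generic-model ACL values; insertions
femoral (−1.1, −40.5, 0.7) cm, tibial (1.2, −3.2, −0.1) cm).  The quadratic
toe and linear branches agree at `e = 2 e_l` (both give `k e_l`), so the law
is continuous and monotone; there is no viscoelasticity, no multi-strand
bundle, and no failure model (the 600–2300 N cadaveric ultimate-force range
appears only as a report annotation).

Because the element is passive, its force is fully determined by its length:
no muscle-force resolution is needed, which is why the pipeline can run on
joint kinematics alone.

## Frames and the knee transform

Both frames use x anterior, y proximal, z lateral; the femur frame sits at
the femoral head, the tibia frame at the epicondylar midpoint (knee centre)
at the default pose, `(0, −40, 0) cm` from the femoral head.  (Anatomically
the epicondylar midpoint is a femoral landmark; the tibia frame is defined
to coincide with it at the default pose.)  The three knee angles are applied
as successive body-fixed rotations — flexion about z (negative sense, so
flexion swings the tibia posteriorly), adduction about x, internal rotation
about y — approximating the standard knee joint-coordinate-system
convention; the source anatomy does not fix the sequence.  Left knees are
handled by mirroring the angle signs and the z coordinates of attached
geometry, which provably preserves all distances.

The anteroposterior (tx) and superoinferior (ty) positions of the tibia
frame are coupled to flexion through small piecewise-linear knot tables, as
in generic musculoskeletal knee models.  The default tx table runs from 0 at
0° to −0.42 cm at 120° flexion — millimetre-scale posterior translation,
the magnitude published generic knee models use.  Out-of-domain flexion is
clamped, not extrapolated (a bounded anatomical function), and each clamp is
logged.

### Calibration of the joint-space offset

The generic geometry leaves one free constant: the superoinferior offset
`ty` (cm) between the frames.  It was calibrated once, by grid search over
0.50–0.95 cm with the default synthetic cohort, to the physiological regime
in which the centre-position graft is taut through stance (peak force
~85 N at the default) and slack through swing, the graft goes fully slack
when the TIS moves ≥ 5 mm posteriorly, and small but non-zero forces remain
at posterior 2.5 mm and lateral 7.5 mm.  Any value in 0.75–0.95 cm
reproduces the same qualitative pattern; the default is `ty = 0.80 cm`
(`DEFAULT_TY_OFFSET_CM`).  With the geometry in this regime, the direction
of every insertion-site effect (anterior ↑, posterior ↓/slack, medial ↑,
lateral ↓) follows from the orientation of the ligament path alone and is
insensitive to the exact value.

## Synthetic gait kinematics

Each knee angle over the normalized 101-point cycle is a shape-preserving
piecewise-cubic (PCHIP) spline through a small knot list.  Landmark knots
carry the calibration targets — stance flexion max 14°, swing flexion max
64°, adduction peak 10° at 85% cycle, swing internal/external rotation
7°/12°, stance fraction 0.60 — and are snapped to sampling-grid times, so
at `variability = 0` every landmark is attained exactly at a sample.
Because PCHIP is monotone between knots and flat at interior extrema, a
landmark knot is exactly the curve maximum of its region, which also makes
the landmark response exactly linear (raising a landmark by 10° raises the
corresponding trace maximum by 10°).

Non-landmark knots are generator conventions for a normal-looking cycle
(heel-strike flexion ≈ 5°, stance peak at 15% cycle, mid-stance minimum
≈ 3° at 40%, swing peak at 72%, small ±1.75° transverse-plane stance
excursions) and are configurable via `GaitShape`.

Inter-subject variability multiplies knot amplitudes by `1 + N(0, 0.08 v)`
and shifts knot times by `N(0, 0.02 v)` for variability scale `v` (default
1), seeded per subject; endpoints share one draw so the cycle stays closed.
At the default scale this produces a few degrees of between-subject spread
at the landmarks, comparable to reported standard-deviation bands.  The
generator emulates *joint angles only*: no markers, ground-reaction forces,
stride-time variability, or within-subject cycle-to-cycle variation, and no
realistic inter-angle covariance — so passing tests establish the pipeline
arithmetic and the geometric direction of insertion-site effects, not
subject-level force magnitudes, which depend on real kinematics.

Cohort anthropometrics are sampled as `N(1.63, 0.098) m` height and
`N(72.04, 15.22) kg` mass.  The height SD is read as 0.098 m: the printed
cohort value of 0.98 m is physically implausible and is treated as a typo,
but the parameter is configurable.  The subject scale factor is
`height / 1.70 m` (generic model height).

## Subject scaling

Scaling a subject multiplies the insertion coordinates, the frame origin
offset and the coupling translations by the uniform scale; the resting
length is multiplied by the ratio of default-pose path lengths after/before
scaling (for a uniform scale this ratio equals the scale factor), and the
stiffness is never scaled.  This preserves default-pose strain exactly, so
differently sized subjects differ only through their kinematics.

## The insertion-site sweep

The TIS grid is the centre plus 2.5/5.0/7.5 mm displacements in the
anterior, posterior, medial and lateral directions — 13 conditions.
Displacements are applied in the tibia frame's x (anteroposterior) and z
(mediolateral, sign resolved by side) axes to the *unscaled* footprint
before subject scaling, because tunnel placement is a decision on the
anatomy, which scales with the subject.  The femoral insertion never moves.
Every subject × condition cell stores the full 101-point force curve.

## Statistics

Stance-phase peaks are maxima over [0, 30%] (initial contact) and
(30%, 60%] (terminal stance); the 30% split is a convention separating the
two named events, which the source analysis does not make explicit.  Offset
curves are compared to the centre curve by sample Pearson correlation over
all 101 points, with a two-sided p-value from the exact t transform with
n−2 df, and peaks by classical paired t-tests vs. the centre.  Conditions
whose curve never leaves zero (slack graft) are N/A throughout — excluded
pairwise from t-tests rather than zero-filled, since a non-functional graft
is a different regime, not a zero force measurement.  No multiple-testing
correction is applied across the twelve comparisons (matching the original
analysis); the report notes this.  Degenerate cases: zero-variance paired
differences with non-zero mean report p = 0 with a `zero_variance` flag;
constant curves make the correlation N/A; fewer than two valid pairs make
the t-test N/A rather than an exception.

## Problem sizes and numerical choices

Default runs use n = 7 subjects × 13 conditions × 101 samples (91 curves);
a full generate→sweep→report pass takes well under a second.  Lengths are
in cm, forces in N, angles in degrees; offsets given in mm are converted at
the API boundary.  Rotation matrices are validated orthonormal (det +1) to
1e-9.  All randomness derives from a single master seed through
`numpy.random.SeedSequence`, so identical seeds give byte-identical output
files.

## Known limitations

- The knee coupling table and joint-space offset are generic stand-ins; the
  source model's coupling splines are not published, so absolute force
  magnitudes are indicative, not subject-accurate.
- The straight-line path ignores wrapping around bone and soft tissue,
  which matters most in deep flexion (where the element is slack anyway).
- A single-strand element cannot represent bundle-specific tensioning.
- The resting length is constant per subject (scaled from the generic
  value), not set from an in-vivo reference strain.
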