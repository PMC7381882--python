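# Methods

This note documents the models, defaults and numerical choices behind
`laaview`, and what its synthetic experiments can and cannot say about
real patients.

## Coordinate conventions and projection model

The patient frame is fixed: x = left, y = posterior, z = superior.  A
C-arm pose is (primary, secondary) in degrees with RAO/CRAN positive,
and the beam direction is

    v(α, β) = (−sin α cos β, −cos α cos β, sin β),

so (0, 0) is the antero-posterior beam and (90, 0) a right-lateral one.
Image axes are u = normalize(v × z) (v × y at the poles) and w = v × u.
No angle-to-direction convention is canonical across vendors; any
consistent one reproduces the study's logic, but absolute personalized
angle values are convention-dependent and should not be compared across
conventions.

Projection is orthographic.  A real C-arm is a cone-beam system whose
magnification depends on the source–object distance; in practice that
magnification is removed by calibrating against a pigtail catheter of
known size in the field.  We therefore model the calibration explicitly
(a marker of known length read off the image) and absorb residual
divergence effects into the multiplicative calibration error, keeping
the geometry exact and testable.  Silhouettes are the outer boundary of
the union of projected beam-facing triangles (shapely polygon union);
interior holes are discarded, as a contrast-filled chamber shadow has
none.

## Synthetic anatomy

Each case is a swept elliptical tube (the appendage) attached to an
ellipsoidal left-atrium body, in millimetres.  The orifice cross-section
at the landing level is an exact ellipse with the prescribed long/short
axes; the tube extends proximally into the body (guaranteeing a single
connected shadow) and tapers distally.  Morphology rules are qualitative
caricatures chosen to reproduce the documented error mechanisms, not
patient statistics, which are unavailable:

* windsock / cactus — single dominant lobe (cactus adds two small side
  lobes); distinct neck, low measurement difficulty;
* cone — strong monotone taper (small level errors change the measured
  diameter steeply);
* chicken wing — a 60–100° centerline bend (bend radius 5 mm) at ≥10 mm
  depth; the folded wing can overlap the neck in projection;
* bilobed — two comparable lobes from a shared trunk (ambiguous
  implantation axis and tip);
* cauliflower — short, with a lumpy radius modulation and a para-ostial
  bulge starting ≥12 % of the length distal to the orifice, so the
  ground-truth orifice stays exact while the silhouette neck becomes
  ambiguous.

Components (lobes, bumps, body) are individually watertight closed
meshes stored concatenated; they may interpenetrate.  Shadows are unions
and plane sections are taken per component with the contour at the
centerline selected, so all measured quantities equal those of the true
boolean union, which no offline boolean engine was needed to build.
Default mesh edge length is 1.0 mm (the scale of clinical CT slice
thickness); planning uses a coarser 2.5 mm twin of the same anatomy for
speed.  Landmarks are constructive: the inferior deflection is an exact
rim vertex, the tip is the distal cap centre, and the LUPV limbus is the
nearest body-surface point to the analytic limbus position.  All mesh
construction is deterministic given (parameters, seed).

### Cohort defaults

The default 28-case cohort uses the study's morphology frequencies
(windsock 15/28, cactus 4/28, bilobed 3/28, chicken wing 3/28, cone
2/28, cauliflower 1/28) and uniform parameter ranges: orifice long axis
14–34 mm (spanning and exceeding the 17–31 mm eligible band), short/long
ratio 0.65–0.95, length 20–45 mm (cauliflower shortened), LUPV offset
11–19 mm.  Orientation is sampled in two parts: the orifice major-axis
spin about the appendage axis uniform in ±90° (the ellipse's orientation
is anatomically arbitrary) and a rigid body tilt uniform in ±30° per
axis (moderate anatomical variability).  These are the fixed study
conditions for every seeded experiment in the tests and the acceptance
script.

## Landing zone and Control measurements

The landing line runs from the inferior deflection to a point t anterior
of the limbus; t is scanned over 10–20 mm in 0.5 mm steps and the plane
through the line whose normal is closest to the local centerline tangent
is scored by |normal·tangent| (two fixed-point iterations locate the
tangent at the actual plane/centerline crossing).  Ties break toward
t = 15 mm; if no candidate is within 30° of perpendicular the best zone
is returned with a warning flag.  Cross-section diameters use the convex
hull of the cut contour: maximum = largest vertex-pair distance (the
caliper equivalent of the two-fiducial D1–D2 measurement), minimum =
smallest hull width.

Length is reported two ways: the centerline arc length from the landing
plane to the tip, and the straight landing-zone-centre→tip chord.  The
cohort statistics use the **chord** as the Control length: the clinical
definition draws a straight line "coaxial with the cavity", a silhouette
can only ever show the chord, and the noise-free exactness limit
(Referred = Control) is only meaningful chord-to-chord.  The arc length
stays in the control table as a sensitivity column; for straight
morphologies the two coincide.

## Personalized views

Beams perpendicular to a segment form a one-parameter family (rotation
about the segment).  The planner scans this family in 4° steps inside
the gantry feasibility box (default primary ±90°, secondary ±45°),
scores each member by the distance of the two projected segment
endpoints to the silhouette border (computed on the coarse twin), and
returns the tangent member (both distances ≤ 0.5 mm) closest to the
standard view, minimizing gantry travel.  If no member is tangent, the
best score is refined by golden-section search and returned flagged.
Within the family the projected segment length is exactly the true
length, so the returned pose is optimal by construction; tests verify it
against an exhaustive 1° pose grid.

A single view serves both the diameter and the length chord when their
exact common perpendicular ±(d̂ × l̂) lies in the box (or its clipped
pose stays within 1° of perpendicular to both).  A view further off
perpendicular would foreshorten *both* measurements, which is worse for
each than two dedicated acquisitions, so no wider tolerance is accepted;
`combined_tol_deg` (default 10°) only caps the clipping allowance.  On
the documented default cohort 12/28 cases get a combined view (pinned as
a regression constant; the clinical study reported 8/28 on its own
anatomy).

## Measurement strategies and the noise model

All strategies calibrate against a 10 mm virtual marker placed in the
image plane at the landing-zone centre — an ideally read catheter; the
reading error is the multiplicative `calib_sd` noise (default 3 %),
redrawn for each of the `replicates` (default 3) measurements, which are
averaged.  Landmark imprecision is `landmark_sd_mm` (default 1.0 mm)
along the silhouette border; a landmark that projects >3 mm inside the
shadow cannot be snapped to a border and jitters isotropically instead.
Defaults were chosen so cohort limits of agreement are of the order the
clinical study reports (±5 mm).

* **Standard** (RAO30/CAUD20).  With noise off, the diameter is the pure
  projection of the D1–D2 fiducial pair (the L cos θ law) and the length
  the projected chord.  With landmark noise on, the operator instead
  reads the *apparent neck width*: the extent of the projected
  landing-zone rim perpendicular to the apparent appendage axis.  For a
  circular orifice this span is insensitive to the viewing angle; for an
  elliptical one it lies between the short and long axis, so the induced
  underestimation is governed by the absolute eccentricity — the
  shape-driven mechanism that personalized views are meant to remove.
* **Blinded** (personalized angles, silhouette only).  The landing level
  is re-detected from the silhouette: the width profile w(s) along the
  projected implantation axis is scanned in 1 mm steps; the landing
  level is the most proximal local width minimum (2 % prominence) within
  ±6 mm of the projected ostium, or, for monotone necks, the level just
  distal to the flare into the atrial shadow.  The tip is the farthest
  border vertex on the appendage side of the neck.  Detection failure
  falls back to the projected fiducials with a `degraded` flag.  This
  rule-based detector is one defensible operationalization of an
  unguided operator and is isolated behind the `detector` argument.
* **Referred** (personalized angles + 3D reference).  Endpoints are the
  true projected fiducials; only calibration noise remains.  Noise-free,
  Referred equals Control to machine precision.

The chicken-wing overlap of the folded wing with the neck, the bilobed
tip ambiguity and the cauliflower para-ostial bulge all act through the
Blinded detector; they are modelled error sources, not defects.

## Statistics

Bland–Altman: differences d = fluoroscopy − Control, bias = mean(d),
LOA = bias ± 1.96·sd(d) (sample sd), CI of the bias via the t
distribution, CI of each LOA with se = sd·√(3/n); fixed bias by
one-sample t-test, proportional bias by regressing d on the pair means.
Zero-variance differences are flagged degenerate with exact bias.
Correlations are Pearson for diameters and Spearman for lengths and
device sizes, one-tailed.  The repeated-measures omnibus is rANOVA for
diameters and Friedman for lengths, with Wilcoxon post-hocs at the
Bonferroni reference p = .05/6.  Stepwise regression is pure forward
selection at entry p < .05 (no removal), reporting b, se, R² and ΔR²
per step; the error-prone morphology group {cone, bilobed, cauliflower,
chicken wing} enters the length models as a binary indicator.

## Reproducibility and problem sizes

A single master seed is fanned out through `numpy.random.SeedSequence`
to the generator and to per-case, per-strategy noise streams, so stages
are independently reproducible and identical configs give byte-identical
CSV outputs.  The default experiment is 28 cases at 1.0 mm mesh
resolution with 2.5 mm planning twins (~30 s on one CPU); the test suite
reuses one noisy and one noise-free 28-case run as session fixtures and
completes in a few minutes.  Monte-Carlo checks use 300–1000 repetitions
and n = 10⁴ samples for the Bland–Altman closed form.

## What passing tests do and do not show

The generator emulates the geometry of measurement error — ellipse
foreshortening, neck ambiguity, bent and multi-lobed shapes — with known
ground truth, which real patients never provide.  It does not emulate
contrast dynamics, cardiac-phase motion, human perception, vessel wall
texture, or realistic population shape statistics; cohort-level numbers
(correlations, LOA widths, false-ineligibility counts) therefore
characterize the simulation's study conditions, not any patient
population, and only the *directions* of the effects (LOA narrowing with
personalization, negative length bias at standard angles, eccentricity-
driven diameter error) are expected to transfer.

## Known limitations

* Orthographic projection: no cone-beam divergence, table constraints or
  collision modelling; extreme gantry angles are as cheap as shallow
  ones.
* The Blinded detector is a single rule-based operator; human operators
  vary and may use cues (contrast borders, catheter position) the binary
  silhouette lacks.
* Imported STL meshes need a landmark sidecar; centerline-dependent
  operations additionally require the sidecar's centerline.
* Mesh components may interpenetrate (no boolean union); volume or
  surface-area queries on the concatenated mesh would double-count
  overlap regions and are not part of the public surface.
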