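# Methods

## Geometric model

All computation is built on rigid poses `x_lab = R x_body + t` with
scalar-first unit quaternions `(w, x, y, z)` representing active rotations
in a right-handed lab frame; positions are metres, and every angle crosses
the API boundary in degrees. Dot products are clamped to [−1, 1] before arc
functions, and unit-norm/orthogonality checks use a central 1e-9 tolerance.

Anatomical frames are orthonormal triads `(lateral, anterior, longitudinal)`
with the fixed handedness `anterior × lateral = longitudinal` (equivalently
`lateral × longitudinal = anterior`). This is the unique convention under
which the pelvis-frame construction and the forward cup-axis model below are
mutually consistent; it is enforced by the `AnatomicalFrame` constructor.

### Pelvis frame (lateral decubitus bench)

The bench models a patient lying on their side: the level baseplate under
the hemi-pelvis model acts as the virtual sagittal plane. Three baseplate
markers define that plane by least squares; its normal, oriented toward a
hint point on the model side, is the **lateral** axis. Two bony landmarks —
the anterior superior iliac spine (ASIS) and the pubic tubercle (PT) —
define the anterior pelvic plane (APP). Two points cannot fix a plane, so
the APP is taken as the unique plane containing the ASIS→PT line and the
lateral direction; this is the natural completion because in the true
pelvis the APP is perpendicular to the sagittal plane. Its normal,
`unit((PT − ASIS) × lateral)` up to a configurable sign, is the **anterior**
axis, and `anterior × lateral` completes the head-ward **longitudinal**
axis. Side conventions (left vs right hemi-pelvis) are carried as sign
flags in the calibration file, not hard-coded.

### Femur frame

The anatomical long axis runs from the centre of the intercondylar notch to
the midpoint of the proximal shaft-marker pair (the distal pair is retained
for shaft QC). The posterior condylar axis (medial condyle → lateral
condyle wand points) orthogonalised against the long axis gives the lateral
axis; anterior completes the triad.

### Cup and stem metrics

With unit acetabular axis `c` oriented out of the cup opening:

    OI = arcsin(c · lateral)               in [0°, 90°]
    OA = atan2(c · anterior, c · longitudinal)

and the exact forward model used for scene generation and round-trip tests:

    c(OA, OI) = sin OI · lateral + cos OI (cos OA · longitudinal + sin OA · anterior).

At OI = 90° the sagittal projection vanishes and anteversion is reported as
an explicit error rather than a silent zero.

FNA is the signed axial-plane angle (normal = longitudinal) from the neck
axis projection to the condylar-axis projection, positive when the neck is
rotated anteriorly. FSA is the signed coronal-plane angle (normal =
anterior) from the longitudinal axis to the stem axis, positive for varus
(proximal stem tilted medially). FSA is reported signed rather than as a
total 3-D angle because varus/valgus is inherently a coronal, signed
concept; a magnitude-only mode exists for reports that do not carry the
sign. FNA is measured against the condylar axis itself, not its
perpendicular, matching the operative definition of the reference line.

### Registration

`register_point_sets` is the closed-form Kabsch/SVD least-squares rigid
transform (scipy's `Rotation.align_vectors` under the hood), with explicit
failure on fewer than three correspondences, collinear clouds (rotation
unobservable) and non-planar clouds whose optimal orthogonal map is a
reflection (impossible under a rigid motion; for planar clouds a reflection
is equivalent to a rotation and is accepted).

## Calibration contract

Landmarks are recorded once — a tracked wand tip in the lab frame combined
with the owning body's pose at that instant — and stored body-locally, so
they reproject correctly after any later movement of the bone or
instrument. The contract tested throughout is *movement invariance*: one
common rigid transform applied to every body changes no measured angle by
more than 1e-9°. The four introducer handle markers reduce to two on-axis
points by pairwise (anterior/posterior) midpoints; the stem calibration
stores tip, shoulder-midline, trunnion-apex and lateral-neck-intersection
points, from which the stem axis (tip → shoulder) and neck axis
(lateral point → trunnion) follow. The shoulder-midline point is an
explicit recorded landmark: a "line up the midpoint of the stem" needs a
second on-axis point, and requiring it in the calibration keeps the
measurement model free of implant-specific shape assumptions.

## Simulator

The simulator replaces the physical bench experiments. Scene geometry is
generated in a canonical bench frame (longitudinal +x, anterior +y, lateral
+z, baseplate at z = 0) with landmark positions of realistic scale
(~5–30 cm), then each body receives an arbitrary random pose so that no
code path can rely on axis-aligned geometry. Ground-truth placements are
produced *through the same frame construction and forward models used for
measurement*, which is what makes the noiseless end-to-end identity exact
(≲ 1e-13° over the full grids) rather than approximate. Stem scenes solve a
one-dimensional trigonometric equation for the neck polar angle so that the
neck axis realises the requested anteversion exactly while keeping the
125° neck-shaft angle to machine precision.

The default study conditions are the bench grids: cup OA 10–40° and OI
35–60° in 5° steps (42 placements), stem FNA 0–30° in 5° steps crossed with
FSA ∈ {0, +3°, −3°} (21 placements, 3° being the varus/valgus extreme for
the modelled stem), re-implanted `replicates` times. The published bench
counts (55 cup and 68 stem readings) do not factor over these grids, so the
replicate count is exposed instead of being fitted to them.

### Noise models

No per-system noise figures are available for the physical systems, so the
simulator parameterises both mechanisms and chooses defaults that put the
default-run critical differences inside the 1–7° band typical of such bench
comparisons:

- **System A** (motion-capture stand-in, the reference): isotropic Gaussian
  noise, SD `marker_sigma_m` (default 0.5 mm), added to every lab-frame
  marker; poses are re-estimated by rigid registration of the marker cloud.
  Angular error therefore scales with marker noise over cloud size.
- **System B** (VR-tracker stand-in, the test system): each body pose is
  perturbed by a random rotation whose rotation vector has i.i.d. N(0, σ²)
  components with σ = `tracker_rot_sigma_deg` (default 0.25°). Under this
  model the error of an angle between axes carried by two independently
  jittered bodies has SD √2·σ to first order, a relation the test suite
  checks empirically against the closed form.
- **Systematic cup bias**: `app_bias_deg` rotates system B's pelvis
  reference axes about the lateral axis, emulating a miscalibrated anterior
  pelvic plane — the mechanism by which a test system can read operative
  anteversion with a constant offset while inclination (referenced to the
  baseplate) stays unbiased. A positive bias lowers B's OA reading by
  exactly that amount, so the reference-minus-test Bland–Altman mean
  difference equals +bias; the bias-recovery study injects 3.44° and
  recovers it within 0.1° at ~10⁴ readings.
- **Pelvic tilt** (`pelvic_tilt_deg`) rotates the pelvis model (with its
  baseplate) about the anterior axis before placement, supporting
  simulated intra-operative pelvic adduction scenarios.

What the simulator does **not** model: marker occlusion and soft-tissue
artefact, camera calibration error, latency/asynchrony between systems,
human implantation variability, and any implant-bone interface mechanics.
Passing tests therefore demonstrate the correctness of the geometry,
calibration logic and statistics under the stated noise models — not the
field accuracy of any physical tracking hardware.

## Agreement statistics

Differences are oriented reference − test (A − B), so a positive mean
difference means the reference reads higher; a flag reverses this.
Limits of agreement use the factor 1.96 exactly (not a t-quantile):
`d̄ ± 1.96·SD(d)` with the sample (n−1) SD, and the critical difference is
`1.96·SD(d)` — exactly half the LoA width, an identity the code preserves
to 1e-12 and that also holds for published summary tables at printing
precision. Published reports sometimes label the LoA interval a "95% CI" of
the mean difference; the quantities computed here are limits of agreement.

Pearson's r uses the product-moment formula; its p-value comes from
`t = r√((n−2)/(1−r²))` on n−2 df and its 95% CI from the Fisher
z-transform with half-width `1.96/√(n−3)` (empirical coverage 93–97% at
n = 50, ρ = 0.9 in the test suite). Regression is ordinary least squares of
the reference on the test readings, with `adj R² = 1 − (1−R²)(n−1)/(n−2)`
for the single predictor. |r| within 1e-12 of 1 is treated as an exact
linear relation (p = 0, collapsed CI) to avoid the divergent z-transform.
Report output rounds to 2 decimals, half-up.

For correlations near 1, the adjusted R² computed from r is not the same
number as the regression slope; summaries report intercept, slope, R² and
adjusted R² as four separate fields to keep those quantities distinct.

## Problem sizes and determinism

Every stochastic computation threads one `numpy` Generator seeded from a
single configuration seed; identical seeds give byte-identical CSV outputs.
The test suite and the acceptance script size their Monte-Carlo runs at the
point of statistical sufficiency for the assertion being made: 3000
observations for the √2·σ propagation check (SE of the SD ≈ 1.3%), 1000
draws for Fisher coverage, 1500–2000 replicates for variance-combination
and zero-mean checks, and ~10⁴ paired readings for the 0.1°-level
bias-recovery claim.

## Known limitations

- The reference system's pose estimation is idealised as noisy-marker
  Kabsch registration; commercial optical systems use proprietary bundle
  adjustment whose error structure differs.
- The APP bias model is a pure rotation about the lateral axis; real
  palpation error also perturbs the lateral axis slightly, coupling OA and
  OI errors.
- Orientation grids are exact; the physical bench could only approximate
  intended orientations with alignment guides, which adds placement
  variance the simulator attributes to neither system.
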