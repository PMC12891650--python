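# Methods

## Geometry model

The pipeline measures the iliococcygeus angle (ICA) of the levator ani
muscle (LAM) from two inputs per subject: a 3D binary segmentation (NIfTI,
voxel centers mapped to world millimetres by the image affine, 0-based
indices) and four bony landmarks in world millimetres — pubic symphysis
(PS), sacrococcygeal joint (SCJ), left and right ischial spines (IS_L,
IS_R).

**PICS frame.** The published construction of the 3D Pelvic Inclination
Correction System is specified only through its landmarks, so the frame here
is the minimal landmark-determined one: origin at PS; PICS axis
`normalize(SCJ − PS)`; lateral axis the inter-spine vector IS_L − IS_R with
its PICS-axis component removed (one Gram–Schmidt step), so lateral-positive
is the subject's left; vertical axis `lateral × pics`, which makes the axis
matrix right-handed with determinant +1 by construction. The construction is
deterministic and rigid-motion equivariant; landmark sets are rejected when
PS = SCJ, the spines coincide, or the inter-spine vector is within 1° of the
PICS line.

**Planes.** The plane span D is the *axial projection* of IS_R onto the PICS
line (not the Euclidean PS–spine distance; the planes are perpendicular to
the PICS line, so the axial reading is the consistent one). Plane k sits at
kD/5, k = 1..5: plane 5 at the spine's axial level, plane 1 most anterior —
the placement under which pubic avulsion gaps disturb plane 1. A
`midpoints` scheme ((k−½)D/5) is available for sensitivity analysis.
Geometry with D ≤ 0 (spine not posterior to the pubis along the axis) is an
error.

**Slabs.** An infinitesimal plane contains no voxel centers, so each plane
collects foreground centers whose axial coordinate lies in
`[pos − h, pos + h)`, with half-width h defaulting to 1.5× the smallest
voxel dimension (≈0.74 mm at 0.49 mm isotropic). That yields roughly 1–2
voxel layers — enough points for a stable line fit while staying well below
the ≥8 mm inter-plane spacing of realistic pelvic geometry, so slabs never
mix planes.

**Side split and fit.** Slab points are split by the sign of the lateral
coordinate (midline points, lateral exactly 0, are discarded; the phantom
voxel grid is offset half a voxel so none occur there). Each side's
(lateral, vertical) cloud is fit with ordinary least squares of vertical on
lateral — literally a first-degree polynomial fit — and the side angle is
`atan(|slope|) ∈ [0°, 90°)`, a magnitude relative to the transverse plane.
An orthogonal (principal-axis) fit is available but off by default: OLS is
the plainest reading of a polynomial fit, and on sheet-like slabs the two
agree to well under a degree. A side with fewer than `min_points` voxels
(default 10) or zero lateral spread is unmeasurable; a plane is measurable
iff both sides are, and then `total = 180 − left − right` exactly.

## Defect scoring

Side scores are integers 0–3 per muscle (pubococcygeus PCM, scored on supine
images; iliococcygeus ICM, scored upright — the pipeline records posture as
metadata only; the arithmetic is posture-agnostic). Total = left + right;
category none (0), minor (1–3), major (4–6), with the override that any side
scoring 3 is major regardless of the sum (for the ICM a side 3 is a hernia
and sets a flag). The 16 possible score pairs are pinned exhaustively in the
tests. Prevalence percentages are 100·count/group-size rounded half away
from zero to one decimal; source tables in the literature occasionally print
half-even roundings (e.g. 18.7% for 3/16), and this package prefers a single
deterministic rule over mimicry.

## Group statistics

Per plane: Shapiro–Wilk per group (reported, never used to gate the ANOVA),
classical one-way fixed-effects ANOVA, and Bonferroni post hoc — all six
pairwise pooled-variance t tests with raw p × 6 capped at 1 (Welch available
by option). The family is the six pairs within one plane; no correction
across planes, matching how per-plane p-values are conventionally reported
for this measurement. A plane is dropped from inference when the number of
subjects with an unmeasurable angle exceeds a threshold (default 0 — any
missing subject drops the plane, the strict reading of the omission rule;
in practice this removes plane 1 when avulsions are present). Complete-case
analysis throughout; no imputation. Degenerate inputs: all-identical values
give F = 0, p = 1; constant samples are flagged Shapiro-untestable; groups
with n < 2 make a pair untestable.

## Synthetic phantoms

Two planar sheets attached at lateral ±halfwidth descend toward the midline:
a voxel center (x, y, z) is foreground iff |x| ≤ halfwidth, 0 ≤ y ≤ D and
|z − tan(α(y))·|x|| ≤ thickness/2, with α(y) the prescribed side angle
linearly interpolated between plane positions. Landmarks are placed
analytically in the construction frame (PS at origin, SCJ on the +y axis,
spines lateral at y = D), so the PICS frame and plane span are exact and the
ground truth is `total = 180 − left − right` of the prescribed angles.
Defaults: halfwidth 25 mm, thickness 2.5 mm, axial extent 80 mm, voxel
0.49 mm isotropic — sheet extents of adult pelvic floor scale at the stated
scan resolution. Avulsion removes one side's voxels with axial coordinate ≤
a given extent; note a plane becomes unmeasurable only when the gap covers
its whole slab, so "plane 1 unmeasurable" needs an extent a little past D/5
(tests use 0.25·D). Boundary noise flips 6-neighbourhood surface voxels
(both directions) independently with a given probability, seeded.

Noise-free recovery is essentially exact (max side error ≈ 0.35° across a
5°–70° sweep, dominated by the linear interpolation of α across the slab);
the acceptance tests require 2°. What phantoms do *not* emulate: curved
sheets (real iliococcygeus muscle is dome-shaped), variable thickness,
intensity artefacts, or segmentation bias — passing tests certify the
estimator's geometry, not anatomical realism.

The cohort simulator draws per-subject plane totals from normal
distributions truncated to (0°, 180°) (truncation is negligible at the
published parameters) and defect categories from categorical distributions;
side scores are then drawn uniformly over the pairs compatible with the
category so score aggregation can be round-tripped. Its defaults are the
published four-group study conditions: n = 14/13/12/16, per-plane total-ICA
means and SDs for planes 2–5 (plane 1 has no published value, having been
excluded from that analysis), and the published none/minor/major prevalences
per muscle.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds (`numpy` Generators);
identical seeds give byte-identical artifacts, and the cohort pipeline is
deterministic outright. The test suite uses phantoms of 40–80 mm axial
extent (~10⁵ foreground voxels, well under a second each); the ANOVA
replication uses 200 simulated cohorts of 55 subjects. `scripts/acceptance.py`
runs the same computations from scratch in a few seconds.

## Known limitations

* The vertical-axis convention of the original PICS formulation is not fully
  pinned by its landmarks; any fixed rotation offset about the PICS line
  would leave all angles unchanged, since measurement planes are
  perpendicular to that line, but coordinates exported for other purposes
  follow this package's convention.
* Side angles are fit on the full slab cloud, not a skeletonized midline;
  for thick or strongly curved slabs OLS can underestimate steep angles.
* Angles are magnitudes in [0°, 90°); a sheet sloping the "wrong" way is
  indistinguishable from its mirror, and totals above 180° cannot occur.
* DICOM inputs, mesh segmentations and dynamic (straining) sequences are out
  of scope; masks are measured at native resolution with no resampling.
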