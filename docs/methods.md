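# Methods

## The measurement problem

After bimaxillary orthognathic surgery the mandibular condyle remodels in
response to the altered joint loading.  Clinically this is tracked on
pre-operative (T0) and ~12-month post-operative (T1) CBCT scans through
six parameters per condyle:

1. **Ramus height** (mm): Euclidean distance from the most superior point
   of the condylar head (apex) to the most inferior point of the
   mandibular angle (gonion).  A loss greater than 6 % of the
   pre-surgical value is the Hoppenreijs criterion for condylar
   resorption.
2. **Intercondylar angle** (deg): angle at the anterior border of the
   foramen magnum subtended by the left and right condylar-head centres
   (the midpoints of the maximum transverse condylar diameters).
3. **Condylar axis inclination** (deg): angle between the maximum
   transverse diameter line and the ramus major axis, after orthogonal
   projection onto the coronal plane.
4. **Condylar ROI volume** (mm³): segmented bone from the apex to a point
   15 mm further down the condylar axis.
5. **Mean bone density** (HU) over the same ROI.
6. **Articular surface change** (mm): per-region mean signed
   apposition/resorption distance between the registered T0 and T1
   surfaces, over five anatomical regions (anterior, posterior, medial,
   lateral, superior).

The package implements each measurement as a deterministic operator on
explicit inputs (volume, mask, mesh, landmarks), plus the cohort-level
paired statistics, plus a synthetic phantom generator that provides exact
ground truth for end-to-end validation.

## Conventions

* **Frame.** All physical coordinates are DICOM patient LPS (+x left,
  +y posterior, +z superior) in millimetres; voxel indices are 0-based
  with voxel centre at `origin + index * spacing`.  NIfTI (RAS) input is
  converted on load.  DICOM rescale slope/intercept is always applied;
  volumes without rescale tags are treated as already-HU with a warning.
* **ROI slab.** Membership uses voxel centres and the half-open interval
  `[0, depth)` mm below the apex along the (downward) condylar axis, so
  the boundary plane is never double-counted.  Volume is voxel count ×
  voxel volume — a segmentation-software readout, not a mesh integral.
* **Condylar axis.** The "condyle axis" used for the ROI clip is the
  ramus major-axis direction given by the two ramus-axis landmarks; the
  "highest edge of the condyle" is the apex landmark.
* **Axis inclination.** The coronal plane is the plane orthogonal to the
  patient's anterior–posterior axis; both defining lines are projected
  orthogonally.  Lines are treated as directed (transverse:
  lateral→medial; ramus axis: inferior→superior), so the angle lies in
  [0, 180) and pre/post deltas (`T1 − T0`) keep a meaningful sign across
  the perpendicular configuration.
* **Surface sign.** Positive signed distance = target surface outward
  along the reference outward normal = apposition (rendered red);
  negative = resorption (blue).  Distances are point-to-surface, so they
  do not depend on the target tessellation density.
* **Region rule.** From the condylar centre, a vertex within 45° of the
  superior axis is *superior*; all others are labelled by the 90°
  azimuthal sector (centred on the anterior, medial, posterior, lateral
  axes) of their direction.  The partition is total and equivariant under
  joint rigid motion.  Any fixed rule here is a design choice; this one
  is the simplest that is reproducible from a landmark-defined frame.
* **Registration.** Rigid ICP (no scaling, no reflection — remodelling
  must not be absorbed by a similarity transform), point-to-surface
  correspondences, Kabsch update.  By default registration uses the
  *ramus stump* (moving vertices more than 20 mm below the mesh top) as
  the stable support, because remodelling is concentrated on the head;
  `support="full"` registers on the whole mesh.  Convergence is declared
  when the RMS correspondence distance changes by less than 1e-6 mm
  (up to 300 iterations): with a looser 1e-4 criterion the solution can
  stall ~0.1° short of the optimum on smooth shapes, which is the same
  magnitude as the recovery accuracy the pipeline is validated to.
* **Closest-point queries** are exact: a KD-tree over triangle centroids
  proposes candidates, exact point–triangle distances select the best,
  and a ball re-query with radius `best + r_max` guarantees no closer
  triangle was missed.

## Cohort statistics

* **Wilcoxon signed-rank**, two-sided, with the conventions of common
  clinical statistics software: zero differences dropped, average ranks
  for tied |differences|, tie-corrected variance, *no* continuity
  correction, `z = (W − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48)`.
  An exact variant enumerates the null distribution of `W` over the
  observed rank multiset with the shift algorithm (n ≤ 25), with
  two-sided `p = 2·min(P(W≤w), P(W≥w))` capped at 1.
  The uncorrected normal approximation tracks the exact p to within 0.01
  where significance is decided (exact p ≲ 0.15, n ≥ 20); in the middle
  of the p-range it deviates by up to ~0.02 — essentially the continuity
  correction it omits.  The correction is deliberately not applied
  because the reference tables were produced without it.
* **SD divisor is explicit** (`n` or `n−1`) because published tables mix
  conventions; the bundled reference cohort needs divisor `n` for the
  intercondylar SD and `n−1` for the density SD.
* p-values are reported at 2–3 decimals in tables; full precision is
  retained in machine output.  Report CSVs are byte-deterministic.

## Bundled reference tables

`condylar.datasets` ships the per-patient outcome and demographic tables
of a published 12-patient (24-condyle) bimaxillary-osteotomy cohort,
transcribed *as printed*.  Three kinds of internal inconsistency in the
source print are handled explicitly rather than silently "corrected":

* two density cells whose printed Δ% disagrees with their own pre/post
  values by ≫ one printed ULP (patient 1 left: −36.1 printed vs −38.1
  implied; patient 7 left: −38.9 vs −40.0) — the printed values are kept
  and `flag_density_pct_inconsistencies()` reports them;
* printed summary cells that truncate rather than round (e.g. the
  intercondylar mean −10.808 printed as −10.80) — recomputation is
  asserted to one printed ULP;
* a few summary/test cells that do not reproduce from the printed
  per-patient values at all (intercondylar p, right-height p, left-axis
  p, class-III subgroup mean, per-side height means) — these are
  documented as non-reproducible and are not validation targets.

## The synthetic phantom

Patient CBCT data are replaced by a schematic, fully analytic condyle:

* **Geometry.** A ramus with elliptical cross-section (ML 6 × AP 4.5 mm,
  rounded ends) along +z carrying an ellipsoidal head (semi-axes
  9 × 7 × 9 mm) tilted about the AP axis, its centre 1 mm posterior to
  the ramus axis.  Three properties are deliberate: the head's coronal
  cross-section is *circular*, so a prescribed coronal rotation changes
  the landmark-based inclination without deforming the surface (rotation
  and surface-offset truths stay independent); the ramus cross-section is
  *elliptical*, so surface registration cannot drift about the ramus
  axis; the posterior head offset breaks the remaining 180° ambiguity.
  The geometry is schematic on purpose — ground-truth tractability
  outweighs anatomical realism for validating measurement operators.
* **Intensities.** Air at −1000 HU; a 1.5 mm cortical shell at 1400 HU;
  a trabecular core of N(550, 50) HU noise, seeded.  The mask is the
  analytic inside; the mesh is the marching-cubes isosurface of the
  voxel-sampled signed-distance grid (same grid and provenance as the
  mask).  Extracting the isosurface from the sampled distance field
  rather than the 0/1 mask keeps the surface sub-voxel accurate; a
  binary-mask staircase would bias closest-point distances by about a
  quarter voxel, swamping the 0.05 mm offset-recovery target.
* **Landmarks** (apex, gonion, condylar centre, transverse endpoints,
  ramus-axis points, foramen vertex, virtual contralateral centre) are
  analytic, so height, inclination and intercondylar truths are exact.
  Because the pipeline consumes these landmarks directly — as in the
  clinical workflow, where landmarks are placed manually and are inputs —
  landmark-based recovery validates the measurement plumbing, not
  observer placement error.
* **Remodelling** (T0→T1): the head slides along the ramus axis (height
  change), rotates in the coronal plane (inclination change), gains
  per-region radial surface offsets blended over a 10° band at region
  borders, and its HU field is scaled with fresh additive noise (density
  change).  The intercondylar change is realised at the landmark level:
  the virtual contralateral centre is rotated about the foramen vertex,
  after accounting for the real head's displacement, so the prescribed
  delta is exact.  A superior offset also raises the apex; the recorded
  height truth is the realised value.
* **Quadrature truths.** ROI volume and expected mean HU are computed on
  a half-spacing grid from the same analytic geometry; the density truth
  at T1 is the T0 mixture scaled by the density factor.
* **Cohort generation** draws per-patient remodelling parameters from
  the reference cohort's observed moments (height −0.7 ± 0.8 mm, axis
  rotation +6.95 ± 8.9° right / +1.05 ± 6.71° left, intercondylar
  −10.8 ± 8.22°, density −33.74 ± 4.45 %, per-region offsets from the
  surface table), with the cohort's 2:1 male:female ratio and class-II
  assignment for patients 8 and 12.  All randomness sits behind one
  seed; identical seeds give bit-identical volumes.

### What passing the phantom suite does and does not show

The phantom has exact landmarks, a smooth noise model, no beam
hardening, scatter, motion or metal artifacts, no segmentation error and
no landmark placement variability.  Recovery therefore demonstrates that
the measurement operators are correct and unbiased at voxel scale — not
that the end-to-end clinical workflow is robust to observer or scanner
effects.  One physical superposition is worth noting: a height change
rigidly displaces the head, and the per-region signed distances
correctly include that displacement (mainly superiorly) on top of any
radial offsets; isolated offset recovery is validated with zero height
change.

## Validation tolerances and problem sizes

Phantom recovery is validated at 0.25 mm voxel pitch (the recovery pair)
and 0.5 mm (registration and no-op checks): height within 2 voxel
spacings, angles within 0.5°, per-region offsets within 0.05 mm, density
change within 1 percentage point.  Voxel volumetry is checked against
analytic spheres/cylinders (within 2 % at 0.25 mm, error at least
roughly halving from 0.5 to 0.25 mm).  Registration apply-and-recover is
within 0.1° and 0.05 mm noiseless, 0.5° with 0.1 mm noise on 30 % of
vertices.  The remaining small biases are understood: per-region means
are diluted ~5–10 % of the offset by the 10° blend band at sector
borders, and radial offsets differ from normal offsets by up to
~3 % (cos of the radial-vs-normal angle on a 9:7 spheroid) — both well
inside the 0.05 mm band.

## Known limitations

* Landmark detection is out of scope; landmarks are inputs.
* No automatic segmentation; masks are inputs.
* No non-rigid registration and no curvature-based parcellation; the
  five-region rule is frame-based.
* The per-condyle volume breakdown of the reference cohort is not
  recoverable from the published per-patient table, so volume statistics
  are per-patient only.
* Oblique NIfTI orientations are rejected rather than resampled.
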