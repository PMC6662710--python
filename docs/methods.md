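# Methods

## The statistic

For a binary structure mask *S* and an oriented reference plane *P*, the
pipeline splits *S* into a positive-side half *L* (patient left, by the
package's orientation convention) and a negative-side half *R*, reflects
*L* across *P* to obtain *A*, and superimposes it on *B = R*. It reports

* non-overlapping volume NOV = (|A| + |B| − 2 |A∩B|) · s³ mm³, where s is
  the voxel spacing — the symmetric difference of the two voxel sets;
* similarity index SI = 2 |A∩B| / (|A| + |B|) (Sørensen–Dice).

The two are tied per subject by the exact integer identity
SI = 1 − NOV_voxels/(|A|+|B|); across any cohort with constant |A|+|B| their
Pearson correlation is therefore exactly −1, and it stays strongly negative
whenever total volume varies little. Superimposition is purely by the
reference plane: no post-mirroring re-registration (ICP or similar) is
performed, deliberately, so the MSP-based index is sensitive to
misalignment of the structure relative to the face as well as to shape
asymmetry. Note that a mean of per-subject SIs is a mean of ratios; it need
not equal (and in practice can differ substantially from) one minus the
ratio of cohort-mean NOV to cohort-mean total volume.

## Geometry conventions

World coordinates are in mm with +x = patient left, +y = anterior,
+z = superior. Reference planes:

* FHP through left/right porion and left orbitale, normal oriented
  superior (enforced by requiring menton on the negative side);
* MSP through nasion and sella, constructed perpendicular to the FHP with
  normal `normalize((S − N) × n_FHP)`, then oriented toward the left
  porion — so positive signed distance = patient left, and the deviation
  (Dev) side is a sign test on menton: |offset| > 4 mm (strict) marks the
  clinical inclusion rule;
* AMP through menton, supramentale (B), genial tubercle (G), oriented to
  agree with the MSP;
* ramus/body sectioning plane per side through Go_mid, J_lat, J_med,
  oriented toward the condylion so "positive side = ramus".

Plane pairs passed to the reorientation transform must be perpendicular to
1e-6 rad (far below landmark-placement noise). Plane construction fails on
collinear triples (cross-product norm < 1e-12). The voxel lattice is never
resampled for reorientation: all splitting, cropping, and mirroring operate
on world-coordinate signed distances, so reorientation is only needed when
exporting standardized coordinates.

## Voxel operations and numerical choices

* Binarization bands are closed intervals; defaults 320–520 HU (bone) and
  −480 to −360 HU (soft tissue).
* Hole filling uses 6-connectivity for the background, the standard choice
  for watertight solids.
* Morphological closing uses the discrete Euclidean ball {v : |v| ≤ r}
  (default r = 10 voxels, sized to close the thin open cortical shell of
  the condylar heads). It is computed with exact Euclidean distance
  transforms, which is equivalent to ball dilation followed by ball erosion
  (verified against a brute-force structuring-element oracle) but much
  faster. The grid is padded by r with background before closing and
  cropped after, so structures at the grid edge behave like interior ones.
* Volume = voxel count × s³. Surface area defaults to `face_count` mode
  (exposed foreground faces × s²); a `slice_perimeter` mode (per-axial-
  slice 2D boundary length × s², summed over slices) is provided for
  literal fidelity to boundary-length-based protocols. The slicing axis is
  taken as the z (last) axis. When a structure has been cut by a plane, the
  artificial flat face can be excluded: faces whose centers lie within half
  a voxel of the cutting plane and whose face normal is within 45° of the
  plane normal are omitted. The exclusion is applied uniformly to hemi and
  segment surfaces (configurable), since cut faces would otherwise inflate
  bilateral surface comparisons.
* Plane splitting assigns each voxel by the sign of the signed distance of
  its center; exact zeros go to the positive side (deterministic
  partition). Split halves always partition the input exactly.
* Mirroring resamples the reflected voxel centers with nearest-neighbour
  lookup (preserves binary values with no threshold choice); trilinear
  interpolation of the 0/1 field thresholded at 0.5 is available as an
  option. When the mirror plane is a grid mid-plane orthogonal to an axis,
  nearest-neighbour mirroring is an exact index flip and an exact
  involution. For oblique planes resampling changes voxel counts by well
  under 2 % at the structure sizes used here.
* Anisotropic grids are rejected at the I/O layer with a clear error; the
  target acquisitions are isotropic (0.39 mm).
* Degenerate inputs: empty binarization warns; overlap of two empty masks
  is an error (SI undefined); one empty half warns and scores 0; an empty
  NOV mask reports both segment fractions as 0 with a warning.

## Statistics

Paired t tests (t = mean(d)/(sd(d)/√n), df = n−1, two-sided) and Pearson
correlations go through scipy, wrapped to raise on zero-variance input.
The intraclass correlation is ICC(2,1) — two-way random effects, absolute
agreement, single measures — computed from the two-way ANOVA mean squares;
the specific ICC form is this package's choice (protocols often leave it
unstated) and is cross-checked against pingouin in the test suite. No
multiple-testing correction is applied by default, matching common practice
for these table layouts; Holm adjustment is available via a flag.

## The phantom generator

The generator emulates the *topology* of a CBCT mandible study, not
anatomy: a half-torus body arc (default arc radius 28 mm, tube radius 7 mm,
arc half-angle 112°) joined to two vertical ramus slabs (34 × 9 × 12 mm)
topped by spherical condylar knobs (radius 5.5 mm), with all 22 named
landmarks placed analytically from the same parametric construction and an
optional soft-tissue shell (5 mm) grown around the bone by distance
transform. HU values (bone 400, soft −420, background −1000) sit strictly
inside the binarization bands so noiseless phantoms binarize exactly;
optional Gaussian HU noise is off by default. The facial midline x = 0 is
always a grid mid-plane, making the symmetric phantom's mirror comparison
exact.

Asymmetry is applied to the right side only, so the Dev side is known a
priori: `lateral_shift_mm` translates the whole mandible toward the right
relative to the fixed cranial landmarks (misalignment — this is what moves
menton off the MSP), while `right_scale` and `right_yaw_deg` deform the
right ramus and condyle about the right gonion (structural asymmetry). A
right-side-only translation could not displace the midline landmark menton,
which is why misalignment is modelled as a whole-mandible shift.

Synthetic cohorts draw per-subject T1 parameters uniformly (shift
4.5–8 mm, mirroring the > 4 mm inclusion rule; right ramus height scale
0.82–0.94; yaw 2–6°) and set T2 = T1 × reduction (default 0.5,
emulating surgery halving each asymmetry parameter). Because the similarity
index is monotone in each asymmetry parameter, this construction guarantees
the qualitative surgical effect (NOV down, SI up) that the cohort-level
tests verify with paired t tests.

What the phantoms do **not** emulate: real cortical/trabecular intensity
structure, partial-volume effects at bone boundaries, dentition and
artifacts, inter-subject anatomical variation beyond the three asymmetry
parameters, and landmark placement error. Passing phantom tests therefore
validates the geometry, morphology, and statistics of the implementation —
not clinical accuracy on patient scans.

## Problem sizes

Default single-phantom grid is 128 × 128 × 96 at 0.78 mm (full anatomy in
mm, half the reference sampling density); cohort runs default to
96 × 96 × 72 at 1.0 mm so a 20-subject × 2-timepoint pipeline with
radius-10 closing completes in a few minutes on one core. Both are
package choices balancing discretization fidelity against turnaround;
all geometric parameters are in mm and independent of grid resolution.

## Known limitations

* Surface area uses voxel-face counting, which overestimates the area of
  oblique surfaces relative to a mesh (marching-cubes) estimator; no mesh
  mode is provided in this version.
* The `slice_perimeter` surface mode depends on the slicing axis; the
  axial (z) axis is assumed.
* No registration between timepoints: T1 and T2 are analyzed
  independently, each in its own landmark-defined frame.
* Maxillary structures are out of scope, as is landmark-free (voxel-based)
  median-plane estimation; reference planes are strictly landmark-defined,
  and landmarks are inputs (no automatic detection).
* `Con` (condylion, most superior condylar point) is treated as the same
  landmark whether a protocol writes it as Con or Con_sup.
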