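# Methods

## The measurement problem

Total-hip implants can loosen by migrating a few tenths of a millimeter
per year relative to the pelvis — motion far below what plain radiographs
resolve. Marker-based migration measurement implants 1-mm tantalum beads
into the periacetabular bone and into the prosthesis (for a cup, eight
beads in a ring around the liner opening), then compares two CT
examinations of the same patient. `ctmigration` implements the analysis
side of that workflow: bead localization in the volumes, rigid-body
registration, and the six-degree-of-freedom (6-DOF) implant motion with a
full measurement-error report.

## Coordinate and angle conventions

All world coordinates are right-handed LPS (DICOM patient convention) in
millimeters. Rotations are reported as Euler angles in degrees, applied
as *clockwise* turns first about x, then y, then z (clockwise when looking
from the positive axis toward the origin):

    R(rx, ry, rz) = Rz(-rz) · Ry(-ry) · Rx(-rx)

with `Rx, Ry, Rz` the standard counter-clockwise matrices. No sign
convention is canonical in this field; rotation *magnitudes* are
convention-free, and this choice is fixed so numbers are reproducible.
At gimbal lock (|ry| = 90° within 1e-7) the decomposition sets rx := 0,
absorbs the free angle into rz, and flags the result.

## The four-step study analysis

Given a reference and a target examination, `analyze_study` runs exactly:

1. **Bone registration.** Least-squares rigid fit of the target bone
   landmarks onto the reference bone landmarks (correspondence by label
   order). This removes the whole-body repositioning between scans.
2. **Prosthetic transfer.** The target prosthetic landmarks are mapped by
   that bone transform into the reference frame.
3. **Standard orientation.** If anatomical landmarks (left/right anterior
   superior iliac spine, left/right pubic tubercle — the McKibbin coronal
   plane) are supplied, both prosthetic sets are rotated into a standard
   pelvic frame: +x along the right→left inter-ASIS axis, +z along the
   best-fit plane normal (sign fixed so ASIS-above-tubercles completes a
   right-handed frame), y = z × x. Without anatomy the identity is used
   and the result is flagged accordingly.
4. **Implant fit.** A second rigid fit maps the transferred target
   prosthetic set onto the reference prosthetic set. Its Euler angles and
   its translation re-expressed about the centroid of the reference
   prosthetic landmarks (t' = R·c + t − c) are the reported implant
   motion, along with per-landmark displacements.

Because step 1 absorbs the repositioning, the reported 6 DOF are invariant
(to machine precision, noiseless) under arbitrary rigid motion of the
whole target assembly — the property the synthetic null design verifies.

## Rigid fitting, mirror guard, condition number

The fit is the SVD solution of the orthogonal Procrustes problem: center
both sets, decompose the cross-covariance `D₀ᵀS₀ = U Σ Vᵀ`, and take
`R = U diag(1, 1, det(UVᵀ)) Vᵀ`, which enforces det(R) = +1 (a reflection
in the unconstrained optimum is corrected by negating the last singular
direction). Weights are uniform. Residuals are reference − transformed
target, reported per landmark as |Δx|, |Δy|, |Δz|, in-plane error and 3-D
error; the mean 3-D residual is the field's "mean error of rigid body
fitting" (ME).

An eight-bead ring is exactly planar, so a mirrored fit would match it as
well as a proper rotation. `augment_out_of_plane` appends one synthetic
landmark at `centroid + n̂·s`, where `n̂` is the unit cross product of the
first three landmarks in list order and `s` the mean centroid distance.
The construction is deterministic, scale-covariant and rigidly
equivariant, so augmenting both sides of a pair never changes an exact
fit. `analyze_study` applies it automatically when σ₃/σ₁ of a prosthetic
configuration falls below 0.02 — loose enough that localization noise on
a truly planar ring (which lifts σ₃ to the noise scale, ~0.1 mm against
σ₁ ≈ 50 mm) still triggers the guard.

Marker-configuration quality is summarized by the singular values
σ₁ ≥ σ₂ ≥ σ₃ of the centered 3×N coordinate matrix. The reported
condition number is 100/σ₃ (the convention used in radiostereometric
practice); the raw ratio σ₁/σ₃ is emitted alongside, and σ₃ < 1e-6·σ₁
flags a degenerate (coplanar/collinear) set. A collinear *source* in a
fit raises an error naming the condition report, since rotation about the
line is unobservable.

## Bead localization

At clinical CT resolution (defaults 0.72 × 0.72 × 0.5 mm) a 1-mm bead
covers about two voxels; its apparent shape is dominated by the partial
volume effect, and boundary voxels carry intensity proportional to the
voxel fraction inside the bead. `refine_bead_center`:

1. selects the 26-connected supra-threshold component nearest the
   operator seed within `max_radius` (default 2 mm, twice the nominal
   bead diameter);
2. dilates it by one voxel to recapture the partial-volume shell;
3. returns the centroid weighted by background-subtracted intensity
   (background estimated as the median of nearby sub-threshold voxels).

On rasterized phantoms this recovers centers with ~0.01 mm mean error
(max ~0.02 mm over 100 random sub-voxel placements) and is insensitive to
±10% threshold changes, because the estimate rests on the partial-volume
shell rather than on which voxels clear the threshold. A plain
binary-mask centroid is available (`weighting="binary"`) for sensitivity
checks. Note that thresholds must be set relative to *observed* bead
intensities: partial volume attenuates a 1-mm bead's peak voxel value
well below the material intensity (typically 30–95% of it at these voxel
sizes), so half the local peak is a sensible level and the material
midpoint may sit above every bead voxel.

`detect_all_beads` applies the same estimator to every component whose
voxel-count-equivalent diameter falls in a given range (default
0.5–2 mm, which excludes cup-shell components), sorted deterministically
by center (z, y, x). `fit_sphere` (algebraic Coope fit plus one geometric
Gauss–Newton step) serves the femoral-head sphere landmark and
reconstruction of a missing extraction-hole marker from rim points.

## Error statistics

* **Summaries** report n, mean, median, min, max, SD and a Student-t CI
  of the mean (t rather than z because patient groups are small; at
  n = 105 the difference is invisible after rounding).
* **Repeatability limit** for paired repeated trials:
  `r = 1.96·√2·s_w` with within-subject SD `s_w = √(Σd²/2n)` from the
  paired differences. Under a normal error model, |trial₁ − trial₂| of a
  fresh pair falls below r with 95% probability for any error SD — the
  property the tests verify by simulation.
* **Accuracy** against a known truth: `(1.96/√2)·√(bias² + SD²)`. This
  coefficient reproduces the published accuracy table of the phantom
  validation experiment from its published per-trial means and SDs
  (pooled as the mean of the two trial means and of the two trial SDs);
  the plain `1.96·RMSE` variant is available via `variant="rmse"`.
* **ANOVA**: balanced fixed-effects two-way decomposition (trial ×
  tube-voltage with interaction) via an OLS fit, erroring on unbalanced
  layouts; a one-way between-study decomposition is also provided.
* **Normality diagnostics** are numeric only: sample skewness, excess
  kurtosis, Shapiro–Wilk, and a quantile table (the numbers behind a Q-Q
  plot).

## The synthetic phantom

No clinical volumes ship with the package; the generator stands in for
them with known ground truth.

Geometry defaults (all free parameters, fixed once): nine bone beads on a
periacetabular-like shell (pairwise separations ≥ 14 mm, clearly
non-coplanar), eight prosthetic beads equally spaced on a 54-mm-diameter
planar ring (cup-opening scale), bead diameter 1 mm, 28-mm femoral head,
voxel spacing 0.72/0.72/0.5 mm, metal intensity 3000 HU-like over zero
background. Whole-body repositioning between examinations is drawn
uniformly within ±10° per axis and ±20 mm per axis — the scale of lifting
a phantom off the scanner bed and replacing it arbitrarily.

Landmark-level studies add i.i.d. isotropic Gaussian localization noise
to every observed bead position (defaults used in the validation runs:
0.10 mm and 0.13 mm SD for the higher- and lower-dose acquisition
conditions; the published per-landmark registration errors of 0.16 mm and
0.21 mm mean 3-D residual sit at this scale). Repeated trials re-observe
the *same* scans: the error is a scan-level component (shared between
trials) plus a small re-designation component (default one fifth of the
scan noise), which reproduces the observed structure that trial-to-trial
repeatability is an order of magnitude tighter than accuracy.

Voxel-level rasterization renders each bead with analytic partial-volume
weighting, the sphere–voxel overlap fraction computed by 11³ midpoint
subsamples per candidate voxel; the grid is snapped to the spacing
lattice so identical world geometry yields identical voxels. Options:
Gaussian HU noise, a hemispherical cup shell (for merge-artifact tests),
and a "deformed bead" mode that elongates one bead radially, emulating a
beam-hardening/partial-volume artifact on a single marker.

What the generator does **not** emulate: beam hardening and streak
artifacts (beyond the single elongated-bead mode), scanner PSF blur,
anisotropic or spatially correlated localization error, SEMAR
reconstruction behavior, patient soft tissue, or operator mistakes such
as landmark interchange. Passing tests therefore demonstrate the
correctness and numerical behavior of the *analysis*, not the clinical
error level of any particular scanner protocol.

## Numerical and design choices

* Degeneracy tolerances are scale-relative (σ₃ < 1e-6·σ₁), rotation
  matrices validated to 1e-6 at construction and reproduced to 1e-9 in
  round-trip tests.
* The implant-fit rotation point is the centroid of the *original*
  (pre-augmentation) reference prosthetic landmarks; the synthetic
  out-of-plane landmark participates in the fits but not in per-landmark
  outputs.
* Missing-anatomy fallback is the identity rotation with an explicit flag
  in the result, never a silent default.
* Recovery *bias* in the validation suite is estimated with antithetic
  localization-noise pairs (each study's noise is a valid N(0, σ) draw;
  the pair average cancels first-order noise), which pins the systematic
  error (~1e-4°) without the Monte-Carlo fluctuation that independent
  draws of the same size would leave (~0.02°).
* Problem sizes in the shipped validation runs — 15 scan positions
  (105 pairs), 100 antithetic pairs per noise level, 500 fit-optimality
  problems, 100 rasterized beads — were chosen to keep the whole suite in
  tens of seconds on one CPU while leaving every Monte-Carlo margin at
  3σ or better.

## Known limitations

* Only rigid transforms are supported; warping or polynomial fusion is
  out of scope, as is any image-based (non-landmark) registration.
* Euler angles and axis signs are convention-bound; compare magnitudes,
  not signs, across implementations.
* The condition-number normalization (100/σ₃) is one of several published
  conventions; the singular values are exposed so any variant can be
  recomputed.
* DICOM series are read-only and assumed spatially consistent; volumes
  without explicit spacing metadata are rejected rather than defaulted.
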