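# Methods

This note documents the model, the parameter defaults, the synthetic-data
generator and the numerical choices behind `nucleomorph`, in the order
data flows through the pipeline.

## Scope and assumptions

The package quantifies nuclear deformation from single-channel
fluorescence micrographs of stained nuclei (DAPI/DRAQ5-type stains).  It
assumes nuclei are bright, roughly convex-to-lobulated solid blobs on a
dark background, sparse enough that touching objects are the exception
(touching/mitotic pairs are detected and excluded, not split and kept).
Nuclei are treated as 2-D silhouettes: all statements about deformation
refer to the projected shape, not 3-D morphology.

## Preprocessing chain

Steps run strictly in this order; an object is retained only if it
passes every gate.

1. **Channel selection.** The blue plane of an RGB raster carries the
   nuclear stain and is kept; intensities are divided by the plane
   maximum so the working image lies in [0, 1].  A raster with zero
   dynamic range is rejected as a blank frame.
2. **Resize** (`resize_factor`, default **0.3**): bilinear, output
   dimensions rounded half-away-from-zero.  The default reflects full
   2452 x 2056 camera frames; synthetic scenes, already small, are
   processed with factor 1.0.
3. **Otsu binarization**, global per image; 8-connected components
   become candidate nuclei.
4. **Intensity-std QC** (`std_limit`, default **0.5**): the population
   standard deviation of each object's [0, 1] pixel intensities;
   objects strictly above the limit are flagged.  Note that the
   population std of values bounded in [0, 1] can never exceed 0.5
   (Popoviciu's inequality), so the default limit only removes the
   degenerate half-black/half-white extreme; it is kept as the published
   default, and a lower limit turns the gate into a practical screen for
   speckled or unevenly illuminated objects.  Because the check needs
   per-cell extents it runs after segmentation.
5. **Border filter**: any on-pixel in the first/last row or column
   flags the object (its true shape is unknowable).
6. **Area filter** (`min_area_px` **50**, `max_area_frac` **0.01**):
   strictly fewer than 50 px or strictly more than 1 % of the working
   image area.
7. **Mitotic-pair exclusion**: watershed on the negated Euclidean
   distance transform, seeded from the regional maxima of the distance
   transform with maxima closer than `mitosis_peak_merge_px` (**5**)
   merged.  If ≥ 2 basins result and the second-largest holds at least
   `mitosis_second_basin_frac` (**0.30**) of the object's area, the
   object is two comparable lobes joined by a neck and is excluded.
   The size-ratio rule is a quantified stand-in for the qualitative
   "split by watershed" idea; both knobs are exposed in the config.
   Using *regional* maxima (connected plateaus count once) keeps
   elongated single nuclei — whose distance ridge is one plateau — from
   being split spuriously.
8. **Smoothing + opening**: the mask is filtered with a normalized 5 x 5
   Gaussian of sigma 10 — with sigma far larger than the kernel this is
   effectively a 5 x 5 mean filter — re-thresholded at 0.5, then opened
   with a 3 x 3 cross.  Thin (1-px) artefacts disappear; if the object
   vanishes it is dropped with a logged warning; if it splits, the
   largest fragment is kept.
9. **Orientation normalization**: the major axis (second-order central
   moments) is rotated to vertical; the mass centroid is then placed on
   the right of the bounding box's vertical centerline by a horizontal
   mirror, and below its horizontal centerline by a vertical flip.  The
   second (vertical) rule is this package's own addition: the mirror rule
   alone leaves 180°-rotated inputs in different poses, and we require
   right-angle rotations of the same mask to normalize identically.
10. **Scale normalization** (`target_dim` **64**): the largest tight-box
    dimension becomes exactly 64 px, aspect preserved; the mask is then
    re-filtered with the same Gaussian, thresholded at 0.5 and cleaned
    with a 3 x 3 median.
11. **Full-bounding-box exclusion**: masks occupying exactly 100 % of
    their bounding box are artefacts and are flagged.

### Numerical choices in normalization

Three choices matter for reproducibility and descriptor stability; all
were made to control raster quantization, the dominant error source at a
64-px frame:

* **Rotation resampling.**  Masks are rotated with nearest-neighbour
  sampling, but on a raster first upsampled by an exact integer factor
  (block replication, lossless) to ≥ 512 px.  The rotation staircase is
  then subpixel after the rescale to 64 px.  Angles that are multiples of
  90° are applied exactly (`np.rot90`); a near-degenerate moment tensor
  (circle) applies no rotation.
* **Reflection canonicalization before interpolation.**  Nearest
  resampling is not exactly symmetric under mirroring, so before the one
  interpolating rotation the mask is reduced to a canonical
  representative of its reflection/right-angle orbit using exact flips:
  rot90 to bring the axis angle within ±45°, a horizontal mirror on
  negative angles, and a 180° flip keyed on the sign of the third moment
  along the major axis.  Mirror images therefore normalize to
  bit-identical masks, and orientation normalization is idempotent.
* **Pose of 4-fold-symmetric shapes.**  A "+" or "#" has an isotropic
  second-moment tensor and no defined major axis.  When the relative
  eigen-gap falls below 0.05 the pose is recovered from the fourth-order
  angular moment `arg(Σ z⁴)/4` (z the centered pixel coordinates as
  complex numbers), which fixes the arm orientation modulo 90° — enough,
  since the dihedral canonicalization absorbs right angles.  The
  fallback triggers only when the fourth-order anisotropy `|Σz⁴|/Σ|z|⁴`
  exceeds 0.15; rasterized circles reach at most ~0.07 through staircase
  artefacts, genuine crosses exceed 0.4.
* **Rescaling as a float field.**  The resize to the 64-px frame
  interpolates the mask bilinearly (anti-aliased when shrinking), runs
  the Gaussian on the float field and binarizes once at 0.5.  The binary
  edge then sits at the 0.5-crossing of the averaged profile, which is
  consistent across resampling phases; a hard nearest resize makes
  stroke widths flicker by ±1 px, i.e. by ~0.02 in rectangularity at
  64 px.  The Gaussian and median use replicate (nearest) boundary
  handling on the normalized canvas — zero padding would shave every
  corner of the silhouette at the canvas border and make the
  100 %-bounding-box gate unsatisfiable.

## Shape descriptors

* **Boundary**: Moore-neighbour tracing of the outer 8-connected
  contour, clockwise from the top-most-then-left-most pixel; holes are
  ignored (stained nuclei are solid; interior gaps are artefacts).
* **Centroid**: mean of on-pixel coordinates (area centroid).
* **Circle variance**: `CV = σ_d/μ_d` over the boundary-point distances,
  population divisor N (configurable to N−1).  In `compute_features`
  each boundary point is weighted by its local arc length (half the sum
  of its two incident contour segments): a pixel contour samples
  axis-aligned edges once per unit length but diagonal edges only once
  per √2, and unweighted statistics would make CV depend on the pose of
  the raster by up to ~0.06.  The arc-weighted pixel CV agrees with a
  dense subpixel contour oracle (1000 points interpolated along the
  0.5-level contour) to within 0.011 on all templates.
* **Rectangularity**: area over the area of the tight axis-aligned
  bounding box of the pose-normalized mask, minus π/4; the gate value R
  is the absolute deviation, the signed value is reported as well.  The
  bounding box realizes the "minimum enclosing rectangle" because the
  pose is normalized first.  A true minimum-area rotated rectangle was
  evaluated and rejected: for "+"-like shapes the optimal rectangle
  pivots on the arm tips and single-pixel tip rounding swings its area
  by >10 %.
* The gate value uses the **absolute** deviation |ratio − π/4|: the gate
  ranges extend to 0.5 while the signed value cannot exceed
  1 − π/4 ≈ 0.215, so only the absolute deviation spans the printed
  ranges (an "L" with ratio 0.3 scores 0.485).

Measured invariance with these choices: rotating, rescaling (0.6–1.6x)
or translating a template raster and re-normalizing changes R by at most
0.015 and CV by at most 0.011 across all 11 templates.

## Gating and scoring

The five gates as implemented (evaluated in order, values clamped to
0.5 first):

| Region | Rule | Weight |
| --- | --- | --- |
| R1 | R ≤ 0.1 and CV ≤ 0.1 | 1 |
| R2 | R ≤ 0.2 and CV ≤ 0.2, not R1 | 2 |
| R3 | R > 0.2 and CV ≤ 0.3 | 3 |
| R4 | R ≤ 0.2 and CV > 0.2 | 4 |
| R5 | otherwise | 5 |

The literal printed bounds leave L-shaped gaps (e.g. R ≤ 0.2 with
0.2 < CV ≤ 0.3) and do not cover values above 0.5.  The implementation
extends R4's CV bound down to 0.2, admits R = 0, and clamps out-of-range
values to 0.5 so extreme shapes stay in the high-deformation gates; this
is the minimal extension that makes the gates a total partition
consistent with their compactness semantics.  The binary rubric
(undeformed iff R ≤ 0.2 and CV ≤ 0.2, deformed otherwise — the
complement rule, so fractions sum to 1) then coincides exactly with
membership of R1 ∪ R2.

`DS = w · p′` is affine in the region fractions: merging populations
averages DS with count weights, and moving any cell to a higher region
strictly increases DS.  `DS ≤ 3` (inclusive) classifies a population as
Non-Deformed.  PC1 is the first principal axis of the pooled, centered
(R, CV) cloud with the CV loading forced positive, so larger PC1 always
means more deformed.

## Synthetic data

The generator reproduces the structure of the validation database used
to place the gates: **11 templates x 50 variants = 550 masks**.  The
template vocabulary — circle, 1.5:1 ellipse, kidney, C, L, T, U, S,
cross (+), grid (#), dumbbell — spans the observed deformation range
from round through bent letters to "#".  The exact outlines are this
package's own parametric stand-ins (closed-form occupancy functions on
the unit box, rasterized at pixel centers with a half-pixel margin so a
circle fills its box at exactly π/4 in expectation).  Two geometry
choices are deliberate: the ellipse is mild (1.5:1; a 2:1 ellipse
already has CV ≈ 0.23 and would gate as high-deformation, contradicting
its role as a compact template), and letter stroke widths are integer
multiples of the 64-px frame's pixel pitch (0.3125 and 0.4375 of the
half-box) so stroke edges do not straddle rounding boundaries.

Each variant gets a random orientation (uniform 0–360°), a random scale
(uniform 0.5–1.5, realized as raster resolution), and each of four
coordinate-remap distortions independently with probability 0.5:

* pinch: r′ = r (1 − s(1 − r/r_max)), s ≤ 0.15;
* twirl: θ′ = θ + α(1 − r/r_max), α ≤ 25°;
* wave: x′ = x + A sin(2πy/λ), A ≤ 0.06, λ ∈ [0.35, 0.7] box units;
* ripple: r′ = r + A sin(fθ), A ≤ 0.03, f ∈ {2..5}.

These are explicit, reproducible analogues of interactive
photo-editing filters; strengths were fixed once at "noise" level — they
roughen and bend a shape without moving it into a different deformation
class, which is the role the original database's filters played.  With
these defaults 100 % of circle/ellipse variants gate to R1/R2 and 100 %
of letter/cross/grid variants to R3–R5 (the acceptance bar is ≥ 90 %).
Masks are rasterized analytically (output pixel centers mapped through
the inverse transform chain into template coordinates), so no
resampling noise accumulates; a variant that loses connectivity or drops
below 50 px retries with halved strengths, at most five times.
Determinism: per-variant streams derive from
`SeedSequence([master_seed, template_id, variant_index])`; identical
master seeds give bit-identical databases.

Composite **scenes** place masks as bright objects (0.8) on a dim
background (0.1) with additive Gaussian noise (σ = 0.02) — constants
chosen so Otsu separates foreground cleanly.  Planted QC violations
cover border contact, sub-50-px and >1 %-area objects, a
dumbbell-shaped touching pair, and a tall solid bar that survives
downscaling with perfect corners and trips the full-bounding-box gate.
A "defocus/high-std" violation is deliberately not offered: no [0, 1]
image patch can exceed the 0.5 population-std limit (see step 4), so
such an object cannot exist; the std gate's machinery is instead tested
with a lowered limit.

What the generator does *not* emulate: fluorescence texture inside
nuclei, uneven illumination and vignetting, out-of-focus blur,
overlapping (rather than bridged) nuclei, and pillar-grid optical
artefacts.  Passing the synthetic suite therefore validates the
geometry and bookkeeping of the chain, not its robustness to real-world
staining and optics.

## Problem sizes in the test suite

Tests rasterize templates at 128 px (anchors at 129–257 px), use 550-mask
databases for recovery checks, scenes of 560–640 px with ~10 objects,
and 20 replicate populations of n = 500 for score-recovery properties.
The full suite runs in about a minute on one CPU.

## Known limitations

* The per-cell intensity-std gate is inert at its default limit (bounded
  statistic); it is retained for contract fidelity and configurability.
* Touching nuclei are excluded, not separated; clustered cultures will
  lose cells and bias DS toward the shapes that grow in isolation.
* R is computed against the axis-aligned box of the normalized pose;
  for shapes whose pose is genuinely ambiguous beyond 4-fold symmetry
  (near-circular blobs) R is small and the ambiguity is immaterial, but
  pathological star-like shapes with higher-order symmetry would gate
  with a pose chosen by raster noise.
* Descriptors are computed on 64-px binary masks; quantization limits
  their repeatability to roughly ±0.015, which is well inside the 0.1
  gate widths but matters for cells sitting exactly on a gate boundary.
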