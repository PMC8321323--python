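# Methods

This note records the models, conventions and numerical choices behind
`rwniche`, including the places where the design was genuinely open and
what the synthetic validation does and does not demonstrate.

## Coordinate conventions

All geometry is computed in world millimetres; voxel indices never
carry meaning beyond addressing.  A voxel's position is its **center**;
a voxel is the half-open box around its center.  The world position of
index `(i, j, k)` is `origin + direction · (index ∘ spacing)` with an
orthonormal direction matrix taken from the image header.

The cochlear frame is right-handed: `e_z` runs from the basal-turn
landmark toward the apex (apex-up), `e_x` from the midmodiolar axis
toward the RWM landmark, `e_y = e_z × e_x`.  The origin is the
orthogonal projection of the RWM landmark onto the midmodiolar axis,
which puts `z = 0` at membrane level and makes `x` the radial direction
at the round window.  Frames are rejected when the apex–basal distance
is below 0.5 mm or the RWM landmark lies within 0.1 mm of the axis.

Left-sided cases are mirrored to the right before measurement, as a
pure array-axis flip about the volume's world-x center plus landmark
coordinate negation.  No interpolation is involved, so a mirrored case
produces bit-identical scalars — this makes mirror invariance exactly
testable rather than approximately.

## Scala model

The scala tympani/vestibuli stand-in is a logarithmic-spiral tube,

    c(θ) = (a₀ δ^{θ/2π} cos θ,  a₀ δ^{θ/2π} sin θ,  p θ / 2π),

with 2.5 turns, basal radius a₀ = 2.8 mm, radial decay δ = 0.6 per
turn, pitch p = 2 mm per turn (canonical axis height 5 mm), and a
linearly tapering circular cross-section (0.6 → 0.2 mm).  These are
round numbers of human cochlear scale, not a statistical shape model;
the pipeline uses the model only for (a) the entrance direction that
orients membrane classification and (b) QC meshes.  The landmark fit is
a deterministic closed-form similarity: scale from the apex–basal
distance, rotation from the frame axes, translation to the basal
landmark.  Because accuracy requirements on this model are directional
only, the crudeness of the tube is acceptable; anything needing true
scala geometry is out of scope.

## Niche boundary

The open border toward the tympanic cavity is the cylinder about the
midmodiolar axis through the overhang-tip landmark.  Inclusion is
decided at voxel centers with `≤` (a center exactly on the cylinder is
kept); the cylinder is uncapped, the mask itself bounding z.  The
radius is refused below 0.2 mm (tip essentially on the axis).  Clipping
is monotone in the radius and idempotent by construction, and both
properties are tested against an exhaustive per-voxel oracle.

## Morphometrics

* **Volume** is foreground count × voxel volume on the clipped mask.
* **Depth** is the extent (max − min) of foreground voxel centers
  along frame z.  The center-extent convention means a one-voxel slab
  has depth 0; the alternative (+1 voxel) was rejected to keep the
  oracle trivial.  Digitization therefore biases depth slightly low
  (about half a voxel per end when an extreme surface is parallel to
  the grid; much less when it is oblique, the realistic case).
* **Overhang** is `max(0, max_y − tip_y)` over foreground centers in
  frame-y.  The sign of +y is genuinely ambiguous from the quantity's
  verbal definition; we orient it so the tip landmark lies on the +y
  side of the mask centroid.  The anatomical picture: the overhang
  shelf attaches to the niche wall nearest its tip, so the roofed
  recess — the part of the cavity continuing past the tip — lies on
  the tip's side of the centroid.  The alternative orientation (bulk
  of the mask beyond the tip) yields oh on the order of the whole
  niche width (~2–3 mm), irreconcilable with overhang lengths of
  0.04–1.24 mm at niche widths of ~3 mm, so it was rejected.  Whether
  the frame was flipped is recorded per case in the provenance.
* **Membrane interface.**  Every 6-connectivity boundary face of the
  clipped mask is classified by its background neighbor: *bone contact*
  if the neighbor intensity is at or above the bone threshold, *mouth*
  if the neighbor center lies outside the clip cylinder, else *soft*.
  The bone threshold defaults to Otsu's method on the intensities in a
  2-voxel dilation shell around the mask, recomputed per case, because
  CBCT grey values are not HU-calibrated and no fixed number is
  defensible; a numeric override exists.  Soft faces are grouped by
  shared-edge connectivity, and the membrane is the largest component
  whose area-weighted mean outward normal has positive dot product with
  the direction from the niche into the scala entrance.  Two
  scala-facing components within 10% of each other's area raise an
  error rather than guessing, because silent misidentification corrupts
  A.  If no face classifies as bone (threshold above the intensity
  range), classification falls back to all-soft with a warning, and if
  the facing test is then uninformative (a closed all-soft boundary has
  a near-zero mean normal) the largest component is used, again with a
  warning.

### Membrane area estimators

Three estimators are computed and recorded; `corrected` is the default.

* `face_count` sums raw voxel-face areas.  Exact for axis-aligned
  patches; overestimates a plane tilted by angle φ by the factor
  cos φ + sin φ (up to √3 in 3-D), which makes it a useful upper-bound
  oracle.
* `mesh` extracts marching cubes at level 0.5 from a Gaussian-smoothed
  (σ = 1 voxel) crop of the mask and keeps triangles whose nearest
  boundary face belongs to the membrane component.  Good on smooth
  closed patches (hemisphere within ~1%), but at concave junctions
  where the membrane meets bone walls the smoothed surface rounds the
  corner and loses roughly 0.4 σ h per unit junction length — several
  percent for realistic patch perimeter-to-area ratios.  Kept for QC
  and export.
* `corrected` uses the projection identity: a digitized surface's faces
  project exactly onto the true surface, so
  `A = Σ A_face · (n̂_face · ñ)` recovers the true area when ñ is the
  true local normal.  ñ is estimated per face by an area-weighted PCA
  plane fit over the membrane component's own faces within 4 voxels —
  using only the component's faces means adjacent bone walls cannot
  skew the normals.  Measured accuracy on constructed oracles: flat
  patch exact, 15°/30° tilted planes within ~2%, hemisphere within
  ~1%, 45° plane within 5%.

## Synthetic phantoms

The generator builds, in an anatomy frame: a bone block; a spiral
cochlear canal at soft-tissue intensity (kept 0.3 mm clear of the niche
so its wall stays bone); a niche cavity that is a straight prism over a
superellipse cross-section (exponent 4) with a gently tilted roof and
floor; a membrane patch — a superelliptical region of a plane tilted
15° about x, passing through its +y edge at z = 0 so the membrane pit
dips below the surrounding floor and its soft slab is never exposed
sideways; a bone lip roofing the cavity with a small mouth hole into an
air-filled middle-ear space; and Gaussian intensity noise (bone 1800,
soft 300, air 0, σ = 60, arbitrary units — configuration, not claims
about any scanner).

Two digitization realism choices matter for validation and are worth
stating explicitly.  First, no anatomical surface is an exactly
grid-parallel plane (roof and floor carry 4°/2° tilts): a grid-parallel
surface aliases its whole area into one voxel layer and makes volume
recovery a lottery on the grid phase.  Second, the anatomy is rotated
18° about world x and shifted by a random sub-voxel phase before
voxelization — scanner axes never align with the cochlear frame, and an
aligned lattice would quantize every frame-z coordinate to whole
voxels, imposing a systematic half-voxel-per-end deficit on the depth
extent.  Both choices emulate reality; both also make the measurement
problem *harder* in the oblique-surface sense while removing artificial
grid-alignment pathologies.

Ground truth: volume and membrane area are closed-form
(`S ax ay d_top + S bx by δ` and `S bx by / cos φ`, with S the
superellipse area factor); depth and overhang use the same cavity
indicator on a 4×-supersampled grid with the center-extent convention,
i.e. the truth oracle shares the measurement convention but at four
times the resolution, and is independent of the pipeline.

Cohort generation samples per-case targets (Vol, A, oh, d) from
truncated normals with the published cohort mean/std/min/max, solves
the phantom geometry to hit them (a fixed-point iteration because the
roof tilt couples volume and depth), and resamples combinations that
admit no geometry (membrane too large for the floor, cavity height
collapsing, overhang beyond the cavity) up to 100 times.  Resampling
rejects a few percent of draws and shifts the realized moments only
slightly.  Sex (22/50 male), side (16/50 left) and age (uniform 13–92,
mean ≈ 52.5) match the published cohort structure.  Landmark jitter
defaults to 0 so accuracy tests isolate the geometry code; a jitter
option supports sensitivity studies of the manual tip placement.

What phantom validation shows: the measurement chain (frame, clipping,
counting, interface classification, area estimation) is accurate to
≲1% (volume), ≲2–5% (area) and well under a voxel (depth, overhang) on
anatomies of realistic size, orientation and noise.  What it does not
show: robustness to segmentation errors, pseudomembranes or ossified
niches, partial-volume effects of real CBCT point-spread functions,
beam hardening, or landmark misplacement — real-data performance
depends on those.

## Statistics

Sample standard deviations use the n−1 denominator throughout.  The
sex comparison defaults to the pooled-variance Student t-test (the
form implied by the study's analysis software defaults); Welch is a
switch.  On the printed group summaries the Student form reproduces
the printed area p = 0.08 at 2 dp and gives volume p = 0.82 versus the
printed 0.83 — consistent with the 2-dp rounding of the inputs, as is
the pooled area std (0.71 computed vs 0.72 printed).  The
D'Agostino–Pearson omnibus test combines the skewness and kurtosis
z-transforms (k² = z_s² + z_k², χ² with 2 df) and refuses samples
below n = 20 (configurable), the transforms being asymptotic.
Group-summary pooling uses the exact total-sum-of-squares identity and
equals `summarize` on concatenated raw data to machine precision.

## Problem sizes used in validation

Phantom recovery runs a 20-case cohort at 0.08 mm voxels (blocks of
roughly 10×9×7 mm including the cochlea).  Calibration checks use
5000 normal samples of n = 50 for the normality test's type-I error
and 1000 sampled truth tables of n = 50 for the null sex-comparison
uniformity.  These sizes give statistically stable medians and rates
while keeping the whole suite at a few minutes on one CPU.

## Known limitations

* The scala model is directional scaffolding, not anatomy; entrance
  direction errors of tens of degrees are tolerated by design (the
  membrane facing test is a hemisphere test), but a grossly misplaced
  RWM landmark can flip membrane identification and will usually
  surface as the ambiguity or no-membrane error.
* The mouth face class exists only when the clip cylinder is supplied;
  in the default phantom no boundary face lies outside the cylinder,
  so the class is exercised only by dedicated unit tests.
* `mesh` areas under-report near wall junctions (see above); compare
  `corrected` vs `mesh` in the provenance when in doubt.
* Mirroring requires an axis-aligned direction matrix (it is an array
  flip); volumes with oblique direction cosines must be resampled
  upstream if a left case needs mirroring.
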