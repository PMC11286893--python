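# Methods

## Problem and model

Postoperative imaging of directional deep-brain-stimulation (DBS) leads
needs two modalities: a conventional multislice CT showing the whole skull
(anatomical context) and a narrow-field-of-view, highly resolved
flat-detector CT (FDCT, ~0.2 mm isotropic voxels) that resolves the three
segmented contacts of a directional lead.  The two volumes come from
different scanners in different physical frames.  Because the skull and the
implanted lead move as one rigid body between acquisitions, the relation
between the two frames is a 6-parameter rigid transform

    T(p) = R (p - c) + c + t,

with a proper rotation R (three ZYX Euler angles in radians), a translation
t in mm, and a fixed rotation center c.  Neither scaling nor shear is
modelled.

The workflow is semi-automated:

1. **Manual initialization.**  A user identifies three corresponding
   anatomical landmarks (e.g. clivus, semicircular canals, petrous bone)
   in both volumes.  The package fits the rigid transform minimizing the
   sum of squared landmark distances in closed form (SVD of the
   cross-covariance of the centered point sets, with the standard
   determinant correction so a reflection can never be returned).  The
   rotation center is placed at the centroid of the fixed landmarks, which
   keeps the rotation and translation parameters comparably scaled during
   the subsequent refinement.
2. **Mutual-information refinement.**  The six parameters are refined by
   gradient ascent on sampled joint-histogram mutual information over a
   3-level coarse-to-fine pyramid.
3. **Evaluation.**  Accuracy is the target registration error (TRE): the
   Euclidean distance |T(f) - m| at held-out corresponding points that
   played no role in driving the registration.  "Before registration"
   means the identity map between the two native physical frames, which is
   why pre-registration TREs can reach hundreds of mm.  Summaries use the
   arithmetic mean and the sample standard deviation (n-1 denominator,
   defined as 0 for a single point); per-rater figures are unweighted
   means of per-patient means.

## Similarity metric

Mutual information is computed from a 2D joint histogram of intensities in
nats:

    MI = sum_ij p_ij ln( p_ij / (p_i. p_.j) ),   0 ln 0 = 0.

Design choices, in decreasing order of consequence:

- **Hard bin assignment, 50 bins per axis.**  The discrete definition is
  exactly verifiable against an enumeration oracle, which the test suite
  exploits; a Parzen-smoothed variant is a possible extension, not
  implemented.
- **Sampling.**  Fixed-grid voxel centers are drawn uniformly without
  replacement (1% by default), fully determined by the seed; the moving
  intensity at each sample is a trilinear interpolation at the transformed
  position, and samples mapping outside the moving volume are discarded.
- **`min_samples` floor (default 5000).**  At desk scale 1% of a 96x96x48
  grid is ~4400 voxels, of which only ~10% land inside the narrow FDCT
  FOV; the floor keeps the histogram populated.  It never raises the count
  above the number of available voxels and leaves full sampling unchanged.
- **Bin edges** span the per-image min/max of the sampled intensities and
  are recomputed at every evaluation, which makes the metric exactly
  invariant to affine intensity rescaling of either input.
- **Overlap-restricted sampling inside the optimizer.**  The estimate of
  MI from a finite sample carries a positive bias that grows roughly like
  (bins-1)^2 / 2N as the retained sample count N falls.  With the
  discard-outside rule, moving the narrow-FOV image *away* from overlap
  shrinks N and therefore *raises* the biased estimate — ascent then
  rewards losing overlap.  The optimizer-facing objective removes this
  spurious gradient by drawing its (frozen) sample only from fixed voxels
  that map inside the moving volume at the pyramid level's starting
  transform.  The stand-alone `joint_histogram` operation keeps the plain
  uniform-over-the-grid definition.
- **Per-level sample freezing.**  Samples are drawn once per resolution
  level rather than per iteration, so each descent optimizes a fixed,
  deterministic objective.

## Optimizer

Plain gradient ascent, `p <- p + learning_rate * S * g`, with:

- central finite-difference gradient, steps 1e-3 rad (rotations) and
  0.1 mm (translations);
- parameter scales S putting a unit rotation step on the same physical
  footing as a unit translation step (rotations weighted by the inverse
  half-diagonal of the fixed volume, in mm);
- windowed convergence: stop when the spread (max - min) of the objective
  over the last 10 values falls below 1e-6, or after 100 iterations;
- the best-objective iterate is returned, not the last; a step landing on
  a non-finite objective is halved up to 10 times before the run is
  declared failed.

Defaults: learning rate 1.0, 100 iterations, convergence 1e-6, window 10,
histogram bins 50, sampling 1%.  The pyramid uses 3 levels with shrink
factors 4/2/1 and physical-unit Gaussian smoothing of 2/1/0 mm, so the CT
and the much finer FDCT are blurred comparably.  After the finest level the
objective is evaluated at both the initialized and the refined parameters
and the better one is kept — refinement can never certify a solution worse
than the landmark start.

The composition formalism treats the virtual reference domain as identical
to the fixed image domain, so the estimated map is directly the
fixed-to-moving physical transform; either modality may play the fixed
role, and on noise-free phantoms the two directions compose to identity
within 1 mm over the FDCT FOV.

## Synthetic phantom

The generator rasterizes one analytic scene onto both grids:

- ellipsoidal skull shell (semi-axes 34/30/26 mm, 3 mm thick, intensity
  2000) with brain-like interior (1000) and air outside (0);
- an electrode-like capsule (radius 1 mm, intensity 3000) entering near
  the scene center, carrying one contact level with **three** capsule
  contacts (radius 0.5 mm, length 1.5 mm, intensity 4000) at 120 degree
  offsets on a 1.2 mm ring — the directional-lead signature; thresholding
  the FDCT above the shaft intensity at the contact level yields exactly
  three connected components;
- scene boundaries are blended over 0.4 mm so partial-volume gradients
  exist at both resolutions.

Grids: CT 96x96x48 voxels at 1.0x1.0x1.75 mm (wide anisotropic FOV,
96x96x84 mm), FDCT 128^3 at 0.35 mm isotropic with a cylindrical FOV
cut-out (44.8 mm across).  These preserve the clinical ratios — a narrow
isotropic cylinder inside a wide anisotropic box at roughly 5x finer
resolution — at desk-top cost; clinical 512-matrix grids are reachable
through the same spec.  The true transform is drawn uniformly within
±10 degrees per axis and ±15 mm per axis, rotating about the CT center.
The FDCT grid is centered on the transformed scene center, exactly as a
scanner is centered on the anatomy of interest; consequently the FDCT FOV
stays inside the CT FOV (checked explicitly, error otherwise).

Multimodality is emulated by a monotone gamma remap of FDCT intensities
onto a 16-bit-like range, v -> 30000 (v/4000)^0.7, so intensity-difference
metrics cannot align the pair but statistical dependence can.  Independent
Gaussian noise is added per modality (sd 30 CT-units / 300 FDCT-units,
~1% of each dynamic range); volumes are quantized to int16.  Landmarks are
analytic scene points: three initialization loci 12–18 mm from the scene
center, and five held-out targets (electrode tip, the three contact
centers, one deep locus).  Optional Gaussian jitter of the moving-space
initialization copies (sd `landmark_noise_sd_mm`) models inter-rater
variability; evaluation pairs always stay exact, since they are the
measuring stick.

What the phantom does *not* model: beam hardening and metal artifacts,
cone-beam reconstruction physics, anatomy beyond the skull shell, gantry
tilt (non-orthonormal direction matrices are rejected rather than
sheared), and fiducial localization error on evaluation points.  Passing
phantom tests therefore demonstrates correctness of the geometry, metric
and optimization machinery under realistic contrast and noise, not
clinical-grade robustness to artifacts.

## Numerical choices and edge cases

- Physical coordinates are LPS; voxel indices are 0-based with the
  voxel-center convention; `p = origin + direction (spacing * index)`.
- Trilinear interpolation clamps within the half-voxel boundary shell and
  returns a configurable default (0 by default — air) beyond it.
- MetaImage I/O is the single-file, uncompressed dialect
  (`ElementDataFile = LOCAL`), int16/float32/float64 payloads, header keys
  validated with errors naming the missing key.  DICOM series are sorted
  by the projection of ImagePositionPatient onto the slice normal;
  inter-slice gaps must be uniform within 1e-3 mm.
- Checkerboard tiling splits remainder voxels into the leading tiles; the
  cut-out fusion threshold defaults to 0.
- Degenerate inputs (collinear landmarks, <3 pairs, empty histograms,
  degenerate display windows, mixed DICOM series) raise typed errors.

## Problem sizes used in tests

The unit suite runs mostly on half-resolution phantoms (CT 48x48x24 at
2.0x2.0x3.5 mm, FDCT 64^3 at 0.7 mm — same physical FOVs).  Invariants
that live at the millimeter scale (inverse consistency, conjugation
equivariance, the MI peak against ±5 mm / ±5 degree perturbations) are
tested on the full default phantom: at half resolution the sampled-MI
basin is a couple of millimeters wide and flat, and the ascent endpoint
wanders within it, which says nothing about the method at its intended
resolution.

## Known limitations

- The convergence functional (windowed spread) rarely triggers on sampled
  MI, whose value fluctuates at the 1e-3 level between iterations; runs
  typically use the full iteration budget.  The best-iterate rule makes
  this benign.
- Gradient ascent with a fixed learning rate has no step-size control
  beyond the non-finite backtrack; capture range relies on the landmark
  initialization and the pyramid, as in the clinical procedure.
- The conjugation-equivariance of the full pipeline is approximate
  (~0.4 mm on default phantoms): the Euler parameterization and
  finite-difference steps are not exactly equivariant, only the landmark
  initialization is.
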