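# Methods

## Measurement model

The reference standard is deliberately simple: a stone is the set of voxels
with attenuation at or above a fixed threshold inside a kidney mask, and its
volume is the voxel count times the physical voxel volume.  The threshold
default is 130 HU, the conventional cut-off for calcification on
non-contrast CT; the comparison is inclusive (HU ≥ 130), matching common
practice for calcium scoring.  Kidney segmentation itself is out of scope —
masks (0 background, 1 right, 2 left) are inputs, reflecting that any
segmentation tool can supply them without changing the threshold-based
measurement.

Connected components are labelled at 26-connectivity by default: diagonal
adjacency frequently bridges partial-volume-thinned necks of a single
physical stone, so the merging choice is the conservative one for "the
entire volume" of a stone.  6- and 18-connectivity are exposed for
sensitivity analyses.  Component ordering is deterministic (descending
voxel count, ties by smallest lexicographic coordinate) so outputs are
byte-reproducible.

Two plane-restricted maximum diameters are reported per stone: the maximum
pairwise distance between voxel centers after projecting onto the x–z and
y–z coordinate planes (a 2D Feret caliper, computed exactly via the convex
hull of the projected point cloud).  The sub-5 mm exclusion — such stones
usually pass spontaneously and add volumetric noise without clinical
meaning — is applied per stone using the larger of the two plane diameters.
Applying it per stone (rather than per patient at study inclusion) is the
only form usable inside a pipeline; it is a documented divergence from a
per-patient screening rule.

Voxel coordinates are voxel centers, 0-based, converted to mm by the
spacing; the array order is (x, y, z) and volumes are reported in mL to
5 decimals, lengths in mm to 2.

## Change classification

The unit of analysis is the kidney.  Relative change is computed on the
per-kidney *merged-VOI* totals, not on matched stones — no stone-to-stone
correspondence across timepoints is attempted, because fragmentation and
passage make such matching ill-defined.  The band rule:

* |r| < 0.15 → stable; r ≥ 0.15 → increased; r ≤ −0.15 → decreased.
* The boundary r = ±0.15 belongs to "changed", keeping "stable" an open
  interval.  The comparison carries a relative slack of 1e-12 so that
  decimal inputs that land exactly on the boundary (e.g. 1.00 → 1.15 mL)
  are not misclassified by binary rounding.
* Degenerate cases follow clinical semantics: a de-novo stone
  (V_b = 0, V_f > 0) is increased; complete resolution (V_f = 0) is
  decreased (r = −1); no stones at either time is stable.

Patient level: both kidneys stable → stable; any increase without a
decrease → increased (and symmetrically); one of each → mixed.  These four
outcomes partition all nine label pairs.

## Phantom generator

The generator emulates a non-contrast abdominal acquisition: a fat-like
background (−50 HU), two ellipsoidal "kidneys" of parenchymal attenuation
(30 HU), ellipsoidal stones of fixed attenuation (default 400 HU — typical
of calcium oxalate and far above threshold), optional additive Gaussian HU
noise (default SD 15, a realistic soft-reconstruction noise level at which
a 400 HU stone against the 130 HU threshold is unambiguous), and
anisotropic voxels defaulting to 0.7 × 0.7 × 5 mm — the in-plane and slice
spacing typical of the clinical protocol this measurement targets.

Voxel membership is by voxel center (a voxel belongs to a shape iff its
center lies inside it).  That makes the digitized ground-truth volume an
exact integer times the voxel volume, so segmentation can be tested for
*zero voxel error*; partial-volume behaviour enters only through this
digitization at coarse spacing, never through HU blending.  Overlapping
stones in one kidney are rejected so the per-stone ground truth stays
unambiguous.  Follow-up examinations rescale each stone's semi-axes
isotropically by (1 + f)^{1/3}, giving an exact analytic volume change of
f; f = −1 removes the stone.  A single integer seed drives all noise and
reader simulation.

What the phantoms deliberately do not model: anatomy, beam hardening and
streak artifacts, HU blur at stone edges, collecting-system contrast, stone
internal heterogeneity.  Passing tests therefore demonstrate the
correctness of the measurement and evaluation machinery under controlled
digitization and noise — not segmentation performance on real CT, where
partial-volume HU blending is the dominant error source.

Digitization accuracy note: the volume error of a single digitized sphere
oscillates with its alignment to the grid, so convergence under spacing
refinement is asserted on the *mean* relative error over several sphere
placements (5 mm slices → 1 mm → 0.5 mm isotropic), which decreases
strictly; a single placement need not.

## Radiomics

Feature definitions follow the public IBSI-style formulations; vendor
prototypes use fixed, non-modifiable catalogs, so numeric agreement with
any particular commercial implementation is explicitly not a goal — the
implemented features are validated against in-repo brute-force
neighbor-scan oracles instead.

* Discretization: fixed bin width (default 25 HU), minimum-shifted —
  `level = floor((x − min)/w) + 1` — so all texture features are invariant
  to a constant HU offset.
* GLDM: Chebyshev-1 neighborhood, dependence tolerance α = 0 by default;
  out-of-VOI neighbors do not count toward dependence.  Dependence
  Variance and Small Dependence Emphasis are the implemented moments.
* NGTDM: same neighborhood; neighbor means use in-VOI neighbors only, and
  voxels with no valid neighbor are excluded (a single-voxel VOI has
  Complexity 0 by convention).
* Wavelets: single-level, separable, stationary (undecimated) Haar bank
  with orthonormal taps taken from PyWavelets, periodic boundary.  The
  undecimated form keeps every sub-band on the original grid so texture
  matrices remain computable per VOI; the tight-frame adjoint divided by
  2³ reconstructs the input to machine precision.  Sub-band letters name
  the per-axis filters in (x, y, z) order.
* Filtering runs on the VOI bounding box expanded by a one-voxel context
  margin (clipped at the grid edge) so single-slice stones at 5 mm slice
  spacing still have a non-degenerate patch; features are computed over
  VOI voxels only.
* z-score normalization uses the sample SD (ddof = 1); constant columns
  map to zero with a warning.

## Evaluation layer

Cohen's κ is computed from the K×K contingency matrix; weighted schemes use
disagreement weights |i−j|/(K−1) (linear, the default) or its square
(quadratic).  Linear is the default because on the published 475-call
reader table it rounds to the printed value under **both** the as-printed
(decreased, increased, stable) and the ordinal (decreased, stable,
increased) category orders — 0.9584 and 0.9552 respectively — making the
result robust to the ordering ambiguity.  Confidence intervals are
percentile bootstrap over the N paired ratings (default 10,000 resamples,
seeded); the CI construction behind published tables is typically
unstated, so CI endpoints are reported but not treated as exact
reproduction targets.

A categorical reader is scored against the volumetric reference one class
at a time: the reference is binarized on the target class and the reader's
call becomes the 0/1 score "reader said the target class".  ROC AUC then
equals the normalized Mann–Whitney statistic with ties at ½; PRC AUC uses
the step-wise average-precision rule (no trapezoidal interpolation, which
is optimistic on PR curves), under which constant scores yield exactly the
prevalence.

Logistic models are fit by IRLS (maximum likelihood); detected
(quasi-)separation — non-convergence or a diverging linear predictor —
triggers a refit with a tiny L2 ridge (λ = 1e-6, intercept unpenalized).
`best_feature_combination` exhaustively scores all subsets up to size 3 by
in-sample AUC with lexicographic tie-breaks; with in-sample scoring on
many candidate subsets the top AUC is optimistically biased, which is why
the null behaviour (pure-noise features staying near 0.5) is tested
explicitly.  No multiple-testing correction is applied anywhere; this
mirrors common practice in small diagnostic studies and is a known
limitation.

## Problem sizes and numerical choices

The test suite and the acceptance script run phantoms at grid sizes of
roughly 43³–129³ voxels (sphere radius 9–10 mm; 0.5–5 mm spacings) and
reader simulations at n = 20,000–30,000 — sizes at which Monte Carlo
tolerances of ±0.02 on κ and AUC are comfortable and the whole suite
completes in well under a minute of compute.  Texture oracles enumerate
all patches up to 4×4×2 over ≥ 100 randomized draws.  Bootstrap resamples
default to 10,000 for reported CIs and are reduced in tests where only the
point estimate matters.

## Known limitations

* Threshold volumetry at 5 mm slices under-resolves small stones; the
  package quantifies this (digitization error of a few percent for a 10 mm
  stone, worse for smaller ones) but cannot remove it.
* Reader simulation treats calls as conditionally independent given the
  true label — real readers share systematic biases.
* The radiomics catalog is intentionally small (the features that matter
  for burden-change discrimination plus first-order summaries); GLCM/GLRLM/
  GLSZM families and shape features beyond the two plane diameters are
  non-goals.
* In-sample AUC is used for subset ranking; it is a model-selection score,
  not an unbiased performance estimate.
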