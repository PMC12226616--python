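# Methods

## The segmentation model

Visceral adipose tissue (VAT) is segmented by subtractive refinement of the
abdominal cavity rather than by direct classification.  Given a CT volume and
an upstream semantic segmentation (label map) carrying at least the abdominal
cavity, subcutaneous fat (SAT), muscle, the lumbar vertebrae L1–L5, and the
abdominal organs, the pipeline is:

1. **Organ-free cavity.**  The cavity mask minus the union of the configured
   organ labels.  With a single-integer label map the labels are mutually
   exclusive, so this subtraction is usually a no-op; it matters for upstream
   schemas whose cavity label is a superset region.  The organ list is
   configuration (`RunConfig.organ_labels`), not hard-coded, because upstream
   schemas differ in which organs they annotate.
2. **SAT intensity sample.**  SAT annotations commonly include the cutis and
   boundary false positives, whose intensities are not adipose.  The SAT mask
   on the L3 axial slice (median z of the L3 label; lower median on even
   counts, keeping the index integral) is therefore eroded — one 4-connected
   layer per iteration — until its pixel count first falls to ≤ 20% of the
   original.  If an erosion would empty the mask first, the last nonempty
   iterate is used and a warning raised.  The CT values under the eroded mask
   form the sample S = {X₁,…,Xₙ}.
3. **Gaussian KDE.**  p(x) = (1/(n·h)) Σᵢ φ((x−Xᵢ)/h), with φ the standard
   normal density and h = n^(−1/5)·σ̂ (Scott's rule-of-thumb, σ̂ the sample
   standard deviation with ddof = 1).  This form integrates to 1.  A bare
   h = n^(−1/5) (no σ̂ factor) is available via `scale_by_std=False`; on
   hundreds of quantised HU samples it produces a spiky density and is not
   the default.  Since the segmentation uses only density *ranks* at a fixed
   bandwidth, any uniform rescaling of p is immaterial.
4. **Low-density removal.**  p is evaluated at the HU value of every
   organ-free-cavity voxel and exactly ⌊q·m⌋ voxels with the lowest density
   are removed (default q = 0.15).  Removal is rank-based with ties broken by
   (density, HU, flat voxel index), which makes the retained count exact, the
   result deterministic despite heavy HU quantisation ties, and the masks
   nested across percentiles.  q = 0 returns the organ-free cavity.

Because the prediction is carved out of the organ-free cavity, it can never
overlap an organ — the structural advantage over HU-window thresholding,
which picks up organ voxels whose attenuation drifts into the adipose range.
The second advantage is adaptivity: the density is fitted per scan, so
distribution shifts (low-dose noise widening, calibration offsets) move the
model with the data, while a fixed window clips the widened adipose tails.

### Baselines and regions

Five published adipose HU windows ship as presets: (−190, −30), (−195, −45),
(−200, −10), (−200, −20), (−250, −50), applied with inclusive bounds
(configurable) to the full abdominal cavity (cavity label ∪ organ labels),
plus an ablation variant applying (−190, −30) to the organ-free cavity.
Evaluation runs in two regions: the full volume, and the axial interval
[min z, max z] spanned by the lumbar vertebra labels ("vertebral bounds", no
in-plane cropping), which suppresses false positives outside the abdomen.

## Evaluation

* **Dice, precision, recall** from voxel counts; the empty/empty convention
  is Dice = 1 (needed for per-slice tables where VAT may be legitimately
  absent), anything/empty = 0, and empty denominators give NaN, which is
  excluded from aggregates.
* **Normalised surface distance (NSD)**, tolerance τ = 2 mm by default.
  Surface elements are boundary voxel *faces* (faces between mask and
  background; the array exterior is background), located at face centres in
  world mm, honouring anisotropic spacing.  NSD = (|∂A within τ of ∂B| +
  |∂B within τ of ∂A|) / (|∂A| + |∂B|), faces unweighted.  This is one
  concrete, brute-force-checkable reading of surface-distance evaluation;
  per-slice NSD uses the 2D variant with in-plane spacing.
* **Paired comparison.**  Per-slice metrics feed a one-sided Wilcoxon
  signed-rank test (H₁: method A's per-slice Dice exceeds B's).  Zero
  differences are dropped and tied |d| midranked.  The null distribution is
  computed exactly for n ≤ 25 by a generating-function convolution over the
  doubled midranks — exact even under ties — and by a normal approximation
  with tie correction and 0.5 continuity correction above.  Slices with empty
  ground truth are excluded from the comparison and flagged in the tables.
* **Diagnostics**: the fraction of a prediction inside organs, and metrics
  restricted to the first k dilation shells (6-connected) around the organs,
  where under-segmentation of fat is a known failure mode.

## The phantom generator

`PhantomSpec`/`generate_phantom` emulate the geometry and intensity structure
the method relies on: an elliptical, mildly tapered body; a 1-voxel cutis
shell; a 7-voxel SAT ring; a 3-voxel muscle band; an interior cavity holding
a posterior lumbar column (five labelled vertebrae over 40 slices), random
organ ellipsoids, and clumped VAT.  VAT placement thresholds a smoothed
Gaussian random field inside the remaining cavity, giving contiguous,
non-uniform deposits (so surface metrics are meaningful) with an exact voxel
count.  SAT and VAT draw from one adipose distribution, N(−100, 20) HU by
default; organs and the non-VAT cavity residue (a bowel/vessel stand-in) from
N(40, 15); muscle N(50, 15); vertebrae N(400, 100); cutis N(20, 10); air
−1000 HU; plus global N(0, 10) noise.  Everything is driven by one seeded
generator: identical spec + seed is bit-identical.

Defaults and why:

* **Grid 112×112×64 at 1.5 mm isotropic** — matches the pipeline's working
  spacing; large enough that the single-layer eroded SAT ring at L3 retains
  ≥ ~240 pixels (a stable KDE sample), small enough that a full
  generate-fit-evaluate cycle takes about a second.
* **`vat_fraction` = 0.85** of the organ-free, vertebra-free cavity.  The
  removal percentile default of 15% presumes the refined cavity is ~85% fat;
  the generator's default puts the phantom at that operating point.  This is
  a modelling choice about the emulated population, fixed once.
* **Tissue means ≥ 100 HU apart** (adipose vs soft tissue) with sd ≤ 20:
  the separated-mixture regime in which density ranking is near-optimal.

Stress operators: `degrade_labels` (muscle dilation into cavity/SAT — the
upstream over-prediction failure mode; SAT erosion to the point of breaking
the sampler; seeded boundary jitter) and `lowdose_variant` (additive
zero-mean noise widening every tissue distribution).

**What passing on phantoms does and does not show.**  The phantom has
Gaussian tissue intensities, no partial-volume mixing, no beam hardening, no
contrast variation, and geometrically simple organs.  High phantom Dice
(≈ 0.99) therefore validates the *mechanics* — ranking, counting, masking,
metric computation — and the directional claims (adaptivity under noise,
zero organ overlap), not clinical accuracy; on real scans the adipose/soft
separation is narrower and upstream labels imperfect, so absolute scores will
be lower.  With clean, well-separated phantoms the fixed windows also score
≈ 0.99: the density method's advantage appears when distributions shift
(e.g. +30 HU noise sd), where windows offset from the adipose mode clip the
widened tails and lose recall while the scan-specific fit tracks them.

## Numerical and design choices

* **Resampling** (default (1.5, 1.5, 1.5) mm): trilinear for images, nearest
  for label maps (interpolating codes is meaningless).  Implemented by
  sampling cell centres with `scipy.ndimage.map_coordinates`
  (`prefilter=False`, edge replication), so the output spacing equals the
  target exactly and values are bounded by the input range; the voxel→world
  affine is recomposed accordingly.  Resampling at the current spacing is the
  identity, making the operation idempotent.
* **KDE evaluation on volumes** computes the kernel sum once per *unique*
  HU value and broadcasts, exact for quantised inputs; `exact=True` forces
  per-point evaluation.  Kernel sums are blocked to bound peak memory.
* **Erosion element**: 4-connected cross by default ("one iteration peels one
  layer"); 8-connected square selectable.  Multi-component SAT slices are
  eroded as a union, i.e. components shrink independently under one pass.
* **Degenerate inputs**: empty L3 label → error instructing a manual slice
  index; SAT absent on the chosen slice → error suggesting another slice or
  the volumetric fit; zero-spread SAT sample → error (a floor bandwidth can
  be set by constructing `FittedKDE` directly); empty organ-free cavity →
  empty prediction with a warning.
* **Volumetric SAT fit** (`fit_on_volume=True`): every nonempty axial SAT
  slice is eroded to the same fraction and the values pooled.  On phantoms
  with homogeneous SAT the final Dice differs from the single-slice fit by
  < 0.01; the single-slice fit is the default for speed.
* **Label merging across datasets**: a ground-truth map takes priority
  voxel-wise; an auxiliary prediction contributes only a configured subset of
  labels (typically SAT, muscle, abdominal and thoracic cavities), remapped
  into the unified schema.

## Known limitations

* A single global density and percentile per scan: no spatial adaptivity, so
  locally atypical fat (e.g. next to over-segmented muscle) can be removed.
* The removal fraction is fixed, not estimated from the cavity's density
  mixture; scans whose non-adipose cavity content deviates far from 15% will
  be over- or under-pruned.
* Quality is bounded by the upstream label map — organ under-segmentation
  reintroduces organ voxels into the cavity, and SAT over-segmentation
  contaminates the sample (mitigated, not eliminated, by the 20% erosion).
* NSD depends on the chosen surface discretisation; other readings (voxel
  boundaries, distance transforms) give slightly different absolute values.
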