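# kevs — kernel-density visceral fat segmentation for abdominal CT

`kevs` segments **visceral adipose tissue (VAT)** in 3D abdominal CT by
refining an organ-free abdominal-cavity mask with a scan-specific model of
adipose intensity, instead of a fixed Hounsfield-unit window.  It is aimed at
body-composition researchers who already have an upstream semantic
segmentation of the scan (abdominal cavity, subcutaneous fat, muscle, lumbar
vertebrae, organs — from any segmenter) and want a VAT mask that adapts to
each scan's intensity statistics.

## The method

Subcutaneous adipose tissue (SAT) and VAT share an HU distribution within a
scan, so the SAT voxels are a labelled sample of what fat looks like *in this
scan*.  The pipeline:

1. **SAT sampling.** Take the axial slice at the L3 level (median z of the L3
   vertebra label) and erode the SAT mask there, layer by layer, to 20% of its
   original area — stripping the cutis and boundary false positives — giving
   an intensity sample S = {X₁,…,Xₙ}.
2. **Density fit.** Fit a Gaussian kernel density estimate

   p(x) = (1 / n h) Σᵢ φ((x − Xᵢ)/h),   h = n^(−1/5) · σ̂  (Scott's rule),

   with φ the standard normal density and σ̂ the sample standard deviation.
3. **Cavity refinement.** Remove the organ labels from the abdominal-cavity
   mask, evaluate p at the HU value of each remaining cavity voxel
   {y₁,…,y_m}, and remove the ⌊0.15·m⌋ voxels with the lowest probability
   density — those least likely to be adipose.  The rest is the VAT mask.

By construction the prediction never overlaps an organ, and the density model
adapts to scan-specific shifts (e.g. the wider HU distributions of low-dose
CT) that defeat fixed thresholds.  The classical baselines — five published
adipose HU windows, e.g. (−190, −30) — are included, as are the evaluation
metrics (Dice, normalised surface distance at τ = 2 mm, precision, recall),
per-slice tables with a one-sided Wilcoxon signed-rank comparison, and a
synthetic phantom generator so the whole pipeline is testable without scans.

## Worked example

```python
from kevs import KEVSModel, PhantomSpec, generate_phantom

ct, labels, vat_truth, census = generate_phantom(PhantomSpec(seed=1))
res = KEVSModel(ct, labels).fit()
print(res.summary())
print(res.evaluate(vat_truth, region="vertebral_bounds"))
```

prints

```
KDE-refined VAT segmentation
============================================
SAT sample size n                      240
KDE bandwidth h (HU)                8.2090
adipose density mode (HU)           -96.50
organ-free cavity voxels m          203052
PD removal percentile                 0.15
voxels removed (lowest PD)           30457
VAT voxels predicted                172595
============================================
{'dice': 0.9999, 'nsd': 0.9988, 'precision': 0.9999, 'recall': 0.9998}
```

The summary says: 240 eroded-SAT pixels were sampled at the L3 level, the
fitted bandwidth is ≈ 8.2 HU, and the density peaks at −96.5 HU — recovering
the phantom's adipose mean of −100 HU.  Of the 203,052 organ-free cavity
voxels, the 15% with the lowest density were removed, and the remaining mask
matches the phantom's ground-truth VAT almost perfectly (Dice 0.9999 within
the lumbar region).  `res.organ_overlap()` is exactly `0.0`: no predicted VAT
voxel lies inside an organ.

The same pipeline is scriptable from the shell:

```bash
kevs phantom --out-dir case0 --seed 1
kevs predict --ct case0/ct.nii.gz --labels case0/labels.nii.gz --out vat.nii.gz
kevs evaluate --pred vat.nii.gz --truth case0/vat_truth.nii.gz \
              --labels case0/labels.nii.gz --region lumbar
kevs experiment --cases-dir cases/ --out-dir report/   # all methods × regions
```

`kevs predict` writes the mask plus a JSON sidecar (config hash, sample size
n, bandwidth h, removed-voxel count) so every run is reproducible from config
and seed.

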