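# hippofill

Post-processing and evaluation of 3D brain-MRI segmentation masks, built
around the failure modes of volumetric hippocampus segmentation.

Voxel-level segmentation networks applied to small bilateral structures such
as the hippocampus tend to fail in characteristic ways: the predicted
structure is split into fragments (*discontinuous segmentation*), contains
spurious interior holes (*hollow segmentation*), or is accompanied by
scattered false-positive clusters. `hippofill` provides

* a **slice-wise filling technique** that repairs these predictions: within
  each axial slice, two regions with points P₁=(x₁,y₁) and P₂=(x₂,y₂) are
  connected whenever |x₂−x₁| + |y₂−y₁| ≤ θ−1 (with θ=1 nothing is bridged;
  with θ=3 a one-voxel gap is closed), then enclosed background is filled,
  and finally only the largest connected components are kept (two by default,
  because the hippocampus is bilateral);
* the **six standard evaluation indices**: Dice = 2TP/(R_s+T_s),
  IoU = TP/(TP+FP+FN), oversegmentation ratio OSR = FP/(R_s+T_s),
  undersegmentation ratio USR = FN/(R_s+T_s), average surface distance (ASD)
  and Hausdorff distance (HD), the distances Euclidean in millimetres between
  surface voxel sets;
* **training-support procedures**: intensity windowing to [0, 500], elastic
  augmentation from a coarse grid of random control vectors (one every 32
  voxels, cubic B-spline interpolated), rotation/scale/grey-value
  augmentation, and a weighted cross-entropy loss;
* **sliding-window tiling** (default window 96³) with exact round-trip
  stitching;
* a **phantom generator** producing bilateral hippocampus-like volumes and
  corrupted predictions, so the whole pipeline is testable without patient
  data;
* **cohort evaluation** with mean ± std summaries and the paired two-sided
  Wilcoxon signed-rank test (exact for n ≤ 12, normal approximation with tie
  and continuity corrections beyond).

## Worked example

```python
from hippofill import (FillingParams, ablation_report, generate_cohort)

cohort = generate_cohort(n=25, shape=(64, 64, 64),
                         modes=("hollow", "discontinuous", "noise_clusters"),
                         seed=42)
report = ablation_report(cohort, FillingParams(theta=3), n_keep=2)
raw, fixed = report.raw.summary, report.repaired.summary
print(f"dice: {raw.loc['dice','mean']:.4f} -> {fixed.loc['dice','mean']:.4f}")
print(f"hd:   {raw.loc['hd','mean']:.4f} -> {fixed.loc['hd','mean']:.4f} mm")
print(f"osr:  {raw.loc['osr','mean']:.4f} -> {fixed.loc['osr','mean']:.4f}")
print(f"wilcoxon p (dice): {report.comparisons['dice'].pvalue:.2e}")
```

prints

```
dice: 0.7397 -> 0.9820
hd:   22.7003 -> 1.4376 mm
osr:  0.0133 -> 0.0059
wilcoxon p (dice): 1.31e-05
```

i.e. on 25 phantoms corrupted with all three failure modes, the repair raises
mean Dice from 0.74 to 0.98, collapses the mean Hausdorff distance from ~24 mm
(driven by distant noise clusters) to ~1.4 mm, and reduces oversegmentation,
with the per-case Dice improvement significant under the paired signed-rank
test.

The same workflow is available from the shell:

```bash
hippofill phantom --n 25 --shape 64 --seed 42 --out-dir cohort/
hippofill postprocess --in pred.nii.gz --out fixed.nii.gz --theta 3
hippofill evaluate --gt gt.nii.gz --pred fixed.nii.gz
hippofill compare --cohort cohort/ --theta 3 --out report/
```

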