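# Methods

## Scope and data model

The package operates on pairs of 3D binary masks (ground truth, prediction)
with physical voxel spacing in millimetres, optionally alongside grey-level
volumes. The array convention is axis 0 = slice (axial) axis, axes 1–2 =
in-plane rows and columns; slice-wise operations default to axis 0 and accept
an override, since hippocampal delineation practice is axial-slice based.
Masks are binarized on read at 0.5 (mask encodings on disk vary; anything
above 0.5 is foreground), and NIfTI is the on-disk format for volumes, CSV
for cohort tables. Multi-label masks and DICOM/RT-STRUCT inputs are out of
scope.

## The repair procedure

Predictions of small, low-contrast bilateral structures fail in three
characteristic ways: fragmentation, interior holes, and scattered
false-positive clusters. The repair runs three steps, in this order:

1. **Slice-wise region bridging.** Within each 2D slice, two connected
   regions are considered parts of one structure when some point pair
   P₁=(x₁,y₁), P₂=(x₂,y₂), one point per region, satisfies

       |x₂ − x₁| + |y₂ − y₁| ≤ θ − 1.

   The threshold θ counts the voxels of the connecting bridge including its
   endpoints: θ = 1 bridges nothing beyond regions that already touch, θ = 3
   closes a one-voxel gap (closest-point Manhattan distance 2). The raw form
   of the criterion is monotone in θ, so the number of components after
   bridging is non-increasing in θ. Merging is the transitive closure of the
   pairwise criterion over all region pairs. A connecting path is drawn for
   *every* point pair satisfying the criterion — not only the single closest
   pair — so that a narrow cut through a structure is closed along its whole
   length; this matters when a cut crosses a ring-shaped cross-section in two
   places, where a single bridge would leave the ring open and defeat the
   subsequent hole filling. Paths are shortest 8-connected routes found by
   BFS through cells that are either the merged group's own foreground or
   background not 8-adjacent to any other group, which guarantees that
   drawing paths never merges regions the criterion alone would not merge
   (the implementation falls back to a straight Bresenham line in the rare
   case no such route exists).

2. **Slice-wise hole filling.** Background regions of a slice with no
   4-connected route to the slice border become foreground. Filling is 2D,
   per slice, deliberately: a hollow shell that is open at its axial ends is
   still repaired slice by slice, whereas 3D cavity filling would ignore it.

3. **Component noise filter.** Connected-component labelling (26-connectivity
   in 3D, 8 in 2D by default; the neighbourhood is configurable) keeps the
   `n_keep` largest components, with ties broken toward the component whose
   first raster-order voxel comes earliest, making the operation
   deterministic. The classic maximum-connected-region filter is `n_keep=1`;
   the pipeline default is `n_keep=2` because the hippocampus is bilateral
   and a single-component filter would delete one hemisphere's structure
   outright. Bridging and filling run *before* the component filter so that
   genuine fragments of a split structure are reunited rather than discarded;
   the opposite order is exposed behind a flag.

Steps 1–2 are iterated per slice to a fixed point, which makes the combined
filling technique idempotent; every step except the component filter only
adds foreground, and the filter only removes it.

## Evaluation indices

With TP/FP/FN the voxel confusion counts, R_s = TP + FN the ground-truth
foreground and T_s = TP + FP the predicted foreground:

* Dice = 2·TP/(R_s + T_s); IoU = TP/(TP + FP + FN);
* OSR = FP/(R_s + T_s); USR = FN/(R_s + T_s), so OSR + USR = 1 − Dice holds
  as an exact algebraic identity, as does Dice = 2·IoU/(1 + IoU);
* ASD(A,B) = (Σ_{s∈S(A)} d(s, S(B)) + Σ_{s∈S(B)} d(s, S(A))) / (|S(A)|+|S(B)|);
* HD(A,B) = max(h(A,B), h(B,A)) with h(A,B) = max_{a∈S(A)} min_{b∈S(B)} ‖a−b‖.

A surface voxel is a foreground voxel with at least one face-adjacent
(6-connected) background neighbour, the volume border counting as background;
a single isolated voxel is its own surface. Surface distances are Euclidean
in physical coordinates (index × spacing), hence reported in millimetres and
exactly linear in uniform spacing changes. Nearest-surface distances are
computed with a k-d tree, which matches the brute-force double-loop
definition exactly (it is not an approximation).

Degenerate conventions are total: both masks empty gives Dice = IoU = 1 and
OSR = USR = 0; exactly one empty mask gives Dice = IoU = 0 with OSR/USR still
defined by the counts; ASD and HD are NaN whenever either mask is empty, the
case is flagged, and flagged cases are excluded from cohort distance
summaries with the exclusion count reported.

## Training-support procedures

* **Intensity windowing** maps grey values to [0, 500] by an affine min–max
  rescale (a clipping variant is exposed behind a flag); a constant volume
  maps to the lower bound. The transform is monotone and idempotent on
  already-windowed full-range volumes.
* **Elastic deformation**: random 3-vectors are drawn i.i.d. from N(0, σ²) on
  a coarse control grid with one point every 32 voxels per direction
  (default; ceil((dim−1)/32)+1 points per axis so the grid covers the
  volume), then interpolated to a dense per-voxel displacement field with
  cubic B-splines. The dense field reproduces the control vectors at the
  control points; σ = 0 yields the exact identity. Default σ = 4 voxels —
  a visible but anatomy-preserving warp at 1 mm voxels.
* **Warping** applies output-to-input resampling: trilinear interpolation for
  images, nearest-neighbour for labels (labels stay strictly binary);
  samples displaced outside the volume take background value 0.
* **Combined augmentation** draws per-axis rotations and an isotropic scale
  uniformly from configured ranges, composes them about the volume centre
  with the elastic field in a single resampling pass (no compounding of
  interpolation error), and applies grey shift/scale to the image only. All
  randomness is a pure function of the seed. Right-angle rotations are
  snapped to exact matrix entries so a 90° rotation equals the corresponding
  exact array rotation.
* **Weighted cross-entropy**: −(Σ_fg w_fg·log p + Σ_bg w_bg·log(1−p))/N with
  probabilities clamped to [ε, 1−ε], ε = 10⁻⁷. Defaults w_bg = 0.1,
  w_fg = 1.0 are a documented example of down-weighting the overwhelming
  background class; they are not calibrated values.

## Sliding-window tiling

Patch origins are planned lexicographically with the window (default 96³)
stepped by the stride (default = window, i.e. no overlap); the last patch per
axis is clamped to end at the volume edge, and volumes smaller than the
window are zero-padded and cropped back after stitching. Overlapping
contributions are combined by mean (default) or max. The mean accumulator
uses extended precision so that stitching the crops of a volume reproduces it
bit-exactly for any overlap count, not only powers of two.

## Phantom generator

Each case contains a ground truth of two arc-bent ellipsoids ("bananas":
semi-axes ~0.21·0.085·0.075 of the volume per axis, quadratic in-plane bend,
mirrored about the mid-column plane), a grey image (smooth random background
+ 40–70 units of foreground contrast + N(0, 5) noise, emulating a
low-contrast T1 appearance), and a corrupted prediction. Foreground occupies
~1% of a 64³ volume, comfortably below the 5% bound typical of a small
structure in a head scan. Corruptions: *hollow* removes the 3D 2-step
erosion interior, leaving a shell; *discontinuous* deletes a 1-voxel-wide
in-plane slab of rows through each component, so every axial slice through it
splits with a Manhattan-distance-2 gap — exactly the geometry the default
θ = 3 bridges; *noise_clusters* places ~3 small balls (radius 1–2) at least 6
dilation steps away from the structures; *boundary_jitter* toggles a fraction
of surface voxels. Cohorts derive per-case generators from one seed sequence
and are fully reproducible.

What the phantoms do **not** emulate: real MR physics (bias fields, partial
volume, anisotropic acquisition), anatomically accurate hippocampal shape,
and realistic inter-rater boundary variability. Passing tests therefore
demonstrate that the repair corrects the targeted topological failure modes
and that the metrics are computed correctly — not that any particular Dice
level would be reached on clinical data.

## Cohort statistics

Summaries report per-metric mean and *sample* standard deviation (n−1
denominator; 0 for a single case). The paired Wilcoxon signed-rank test is
two-sided; zero differences are dropped, |differences| are ranked with
mid-ranks for ties, and W = min(W⁺, W⁻). For n ≤ 12 remaining pairs the
p-value is exact: the distribution of W over all 2ⁿ sign assignments of the
observed ranks is built by dynamic-programming convolution (ranks doubled to
stay integral under mid-ranks). Beyond that the normal approximation is used
with the tie correction Σ(t³−t)/48 subtracted from the variance and a 0.5
continuity correction. All-zero differences return p = 1 with a flag rather
than an error.

## Problem sizes

The test suite and the acceptance script use 64³ phantom volumes and 25-case
cohorts, 10³-voxel volumes for brute-force oracle comparisons, and 32² slices
for bridging-closure checks; at these sizes the full suite runs in well under
a minute of CPU time while still exercising every code path at the cohort
scale the package is designed for.

## Known limitations

* Bridging thresholds are in voxels, not millimetres: strongly anisotropic
  spacings change the physical meaning of θ.
* The bridging criterion is evaluated between all component pairs
  (all-pairs transitive closure), which on slices with very many fragments is
  quadratic in the fragment count.
* Hole filling is strictly 2D; a cavity visible only as 3D topology (never
  enclosed within any single slice) is not filled.
* The network itself (architecture, training loop, optimisation) is out of
  scope; the training-support procedures are standalone, testable components.
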