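# Methods

## The segmentation model

`segma` assigns a tissue/structure label to every brain voxel of a target
3D MR image using a *window-local* multi-class random forest.  The target
grid is tiled into cubic windows (default 5×5×5 voxels).  For each window a
dedicated forest is trained on the feature vectors of the voxels at the
*same grid locations* in k co-registered, labeled atlas images — k·w
training rows for a window of w voxels — and then classifies all w target
voxels of that window at once.  Two properties follow:

1. **Locality.** A window typically contains only the two or three classes
   actually present there, so each classifier solves a small, locally
   calibrated problem.  Smooth intensity inhomogeneity (bias) and poor
   global contrast harm it far less than a single whole-brain classifier,
   because within a window the bias is approximately constant.
2. **Batching.** Classifying w voxels per invocation cuts the number of
   classifier calls by a factor w relative to voxel-wise classification
   (125 for the default window) — this is what makes per-window *training*
   affordable at all.

The method assumes all images live on one voxel grid: inputs must be
brain-extracted, bias-corrected and linearly registered to a common space
before they reach the package.  The package enforces grid compatibility
(identical shapes, spacings equal within 1e-4 mm) but never performs
registration, brain extraction or bias correction itself.

### Features

Each voxel carries a ten-dimensional vector

    f_v = [ I, |Ix|, |Iy|, |Iz|, r, θ, φ, |Ixx|, |Iyy|, |Izz| ]

with I the standardized intensity; Ix, Iy, Iz central differences with the
kernel (−1, 0, 1); Ixx, Iyy, Izz second differences with (−1, 2, −1);
r = √(Ix²+Iy²+Iz²) the gradient magnitude; θ = atan2(Iy, Ix) wrapped to
[0, 2π) the azimuth; φ = arccos(Iz/r) ∈ [0, π] the zenith.  Signed
derivatives are used for the angles; the vector stores their norms.
Numerical conventions:

- θ is computed with the quadrant-aware two-argument arctangent: a
  single-argument arctangent cannot reach the full [0, 2π) range that the
  azimuth must cover.
- At r = 0 both angles are set to 0, keeping features deterministic at
  perfectly flat voxels.
- Derivatives are taken in voxel units; `spacing_scaled=True` divides by
  2·spacing and spacing² for strongly anisotropic grids (off by default —
  the kernels are defined on the voxel lattice).
- Boundaries replicate the edge voxel, avoiding artificial gradients where
  the mask touches the volume edge.
- Out-of-mask voxels carry zero vectors and are excluded from testing;
  in training they enter as background (label 0) rows so near-boundary
  windows can predict background inside a loose mask.
- No per-feature rescaling is applied: trees are invariant to monotone
  per-feature transformations.

### Random forests

Per window: 10 trees (accuracy saturates near 10 on this task and in the
tradition this method comes from), maximum depth 20, minimum 1 sample per
leaf, 4 = ⌈√10⌉ candidate features per split, bootstrap sampling.  A window
whose training labels are all identical short-circuits to that label
without fitting.  Prediction is a hard majority vote over trees with ties
broken toward the lowest label value — deterministic, and shared verbatim
with the global-forest baseline so the two routes are interchangeable when
the window spans the whole grid.  Each window derives its own seed from
(global seed, window linear index) via NumPy's `SeedSequence`, so results
are independent of iteration order and reproducible across platforms.
We checked leaf sizes 2–8 and 6–10 candidate features per split on the
default phantom suite; none changed mean Dice by more than ±0.2, so the
defaults stand.

The sliding window is realized as a **non-overlapping tiling** (stride =
window side): each voxel is classified exactly once, which is the only
reading consistent with a w-fold reduction in classifier invocations.  An
optional smaller stride produces overlapping windows fused by per-voxel
majority vote; it is off by default and roughly multiplies cost by
(w_side/stride)³.  Edge windows are clipped, not padded, so training and
test locations always correspond exactly.

### Intensity standardization

Histogram-landmark standardization (Nyul–Udupa style): landmarks are the
within-mask min, deciles 10–90, and max.  The standard scale is the mean of
the landmark values over a training population; each image is then mapped
piecewise-linearly so its own landmarks meet the standard ones, with linear
extrapolation beyond the end landmarks and strictly-increasing landmark
enforcement by epsilon separation.  The cited landmark configuration is not
uniquely standard; deciles are the common variant and are a documented
assumption.  The scale is fitted on the atlas pool and applied to atlases
and target alike, before atlas selection and feature extraction.

### Atlas selection

Candidates are embedded by PCA of vectorized in-mask intensities (common
mask = intersection), keeping the smallest number of components explaining
95% of variance (capped at pool size − 1), with a deterministic sign
convention (largest-magnitude loading positive).  Selection is greedy
farthest-point: first the candidate closest to the pool centroid, then
repeatedly the candidate maximizing its minimum distance to the selected
set; ties break toward the lowest index.  "Uniformly spread in the
low-dimensional space" is operationalized this way because the max–min rule
is deterministic, testable against an exhaustive oracle, and needs no
target image — one selection serves a whole cohort.  The embedding and
distance (Euclidean) are design choices, flagged here because the upstream
selection literature admits variants.

### Evaluation protocol

Leave-one-out cross-validation: each subject in turn is the target, the
standardization scale and the PCA embedding are fitted on the remaining
pool only, k atlases are selected, and the prediction is scored against the
held-out ground truth with the Dice coefficient per class,
DC = 2|A∩M|/(|A|+|M|) × 100.  Conventions: background is excluded from
Dice reporting; classes are equally weighted in means; a class empty in
both maps is *missing* (0/0), never 0 or 100.  Method comparisons
(majority-vote fusion; global random forest with full features and with
intensity only, 100,000 sampled voxels per atlas) and the drop-one-group
feature ablation reuse identical folds, atlas selections and seeds, so all
contrasts are paired.

## The synthetic phantom population

Real cohorts cannot ship with the package; every experiment runs on
generated 3D phantoms that keep the properties the method depends on and
omit the rest.

**Geometry.** One base anatomy of four nested classes: a normalized
ellipsoidal radius field (semi-axes 0.42/0.45/0.40 of the grid), modulated
by a smooth random bump field (8% amplitude), thresholded at shell radii
(1.0, 0.88, 0.62, 0.40) — a thin outer CSF-like shell, a cortical-GM-like
ribbon, a thick WM-like compartment, and a compact deep-GM-like core.
Classes number 1–4 outward-in; 0 is background.

**Intensity.** Class means (10, 40, 100, 70) follow adult T1w contrast:
CSF darkest, cortical GM intermediate, WM brightest, deep GM *between* GM
and WM — deliberately non-monotone with depth, as in real T1 images.  The
image is the per-class mean times (1 + bias) plus Gaussian noise
(SD 10).  The smallest pairwise mean gap is 30, so the default
contrast-to-noise ratio is 3 — chosen so that a global intensity rule is
visibly imperfect while window-local classification succeeds, which is the
regime the method is designed for.  The bias field is a Gaussian-smoothed
random field scaled to ±20% peak amplitude.

**Inter-subject variability.** Each subject warps the base anatomy by an
independent band-limited random displacement field (component SD 0.5
voxels, Gaussian smoothing 4 voxels), rejected and redrawn if its Jacobian
determinant is anywhere non-positive (at most 5 attempts).  Images resample
trilinearly, labels by nearest neighbour, so each subject's image and
labels stay mutually consistent while boundary voxels acquire realistic
partial-volume intensities.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: MR acquisition physics (Rician noise, motion,
ghosting), tissue texture (intensities are piecewise constant up to bias
and noise), real cortical folding and topology, sub-voxel partial-volume
mixtures beyond the warp interpolation, and multi-site intensity
distribution shifts.  In particular, because intensities are piecewise
constant, the first-derivative norms |Ix|, |Iy|, |Iz| are an exact function
of (r, θ, φ) and carry no independent information on the phantom; on real
images texture breaks this redundancy.  Consequently the drop-one-group
ablation on the phantom shows intensity as by far the most important group
(mean Dice falls from ≈91 to ≈73 when dropped) and the second-derivative
group as clearly useful (≈−0.9), but dropping the redundant
first-derivative group changes mean Dice only at the ±0.2 noise level of
forest construction — on phantoms this small systematic redundancy effect
can favour the reduced feature set, unlike the strict all-features-best
ordering observed on real cohorts.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| grid | 48³ voxels, 1 mm iso | smallest grid with brain-like shell proportions |
| classes | 4 (+ background) | CSF/GM/WM/deep-GM-style nesting |
| class means | (10, 40, 100, 70) | adult T1w ordering, min gap 30 |
| noise SD | 10 | CNR = 3 |
| bias amplitude | 0.2 | typical post-correction residual would be smaller; stresses the global baseline |
| warp SD | 0.5 voxels (smoothing 4) | visible anatomical variability without degenerate folds |
| subjects / k | 8 / 5 | pool large enough for selection to matter |
| window | 5³ | method default |
| trees / depth / leaf / mtry | 10 / 20 / 1 / 4 | see forests above |

The evaluation drivers and the acceptance script run at exactly these
sizes; unit tests use 20³–32³ variants of the same generator.  On one CPU
the default-suite LOOCV takes about a minute; the full method comparison
plus ablation about seven minutes.

## Known limitations

- Per-voxel features only: no neighbourhood context beyond what the local
  training set induces, so accuracy at CNR 3 is Bayes-limited near
  boundaries (the dominant error source on the phantom).
- The non-overlapping tiling can produce visible block boundaries in
  low-confidence regions; the overlapping-stride option trades time for
  smoothness.
- Standardization assumes roughly comparable intensity distributions
  within the mask; it is fitted on the atlas pool, so a target far outside
  the pool's intensity range relies on linear extrapolation.
- STAPLE-style fusion and deformable-registration baselines are out of
  scope; majority vote is the only fusion baseline, applied directly in
  the common space.
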