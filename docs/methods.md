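# Methods

## Model

`elasticgrade` grades a microscopy image in four stages.

1. **Tiling.** The image (`W × H`) is cut into `w × h` patches at stride
   `s`, anchored at the top-left pixel. Per-axis patch counts are
   `1 + ⌊(W−w)/s⌋` and `1 + ⌊(H−h)/s⌋`; any right/bottom margin narrower
   than one stride step is discarded. This floor-and-drop convention is the
   one consistent with the canonical grid sizes the package reproduces
   (20 patches at 1280×960/s=224, a 3×4 grid at 896×672/s=224, 6 cells at
   448×336/s=112). Coordinates are 0-based with half-open patch intervals.

2. **Per-patch features.** Each patch is mapped to a feature map. The
   default extractor is deterministic and training-free: the patch is split
   into a 2×2 cell grid and each cell is summarized by channel-wise mean
   and standard deviation plus mean Sobel edge energy of the gray-scale
   patch (7 features per cell for RGB). Any callable `patch -> feature map`
   with a uniform output shape can replace it; a convolutional extractor is
   the intended production choice. A suitable image-wise network topology,
   for users who wire in a deep backend: a series of 3×3 convolutions with
   stride-2 2×2 down-sampling convolutions, batch-norm + ReLU after each
   layer, a 1×1 convolution for spatial averaging, then three fully
   connected layers and a log-softmax head, trained with categorical
   cross-entropy against image-level labels. The core package deliberately
   does not implement or depend on it.

3. **Contextual members.** Feature maps form a grid congruent with the
   patch grid. Ensemble members consume rectangular windows of neighboring
   maps, concatenated while preserving their 2-D arrangement. By default
   one member is created per *distinct window shape* (height ≤ n_rows,
   width ≤ n_cols, filtered by `min_level` = minimum number of combined
   maps): 12 shapes for a 3×4 grid, 6 for a 2×3 grid. An explicit shape
   list can be supplied instead when a specific member census is wanted.
   At inference a member is applied to **every placement** of its shape
   and the per-placement distributions are averaged; this was a genuinely
   open design point (a single fixed placement per member is equally
   defensible) and averaging was chosen so that every member sees the
   whole image and results carry no arbitrary placement choice. The
   default trainable member is a standardized multinomial logistic
   regression on the flattened contextual map — the simplest model that
   honors the softmax-output contract.

4. **Entropy gate and aggregation.** Member outputs are probability
   vectors (entries ≥ 0, sum 1 ± 1e−6). Uncertainty is Shannon entropy in
   bits with the exact `0·log 0 = 0` convention (no epsilon flooring, so
   one-hot outputs have exactly H = 0). Members with `H < β` (strict
   comparison) are selected; their distributions are soft-voted
   (arithmetic mean, renormalized). Majority voting over member argmaxes is
   a conceivable alternative aggregation; soft voting was chosen because
   the pipeline's contract is a final class *distribution*, not only a
   label. Argmax ties break to the lowest class index. An empty selection
   is an abstention (`ABSTAIN = -1`), not an error; abstained images are
   listed in `referrals.csv` for manual review. A failing member is
   logged and treated as unselected by default (`on_member_error="raise"`
   for strict runs).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `beta` | 0.5 bits | entropy gate; (0, log₂ c] is the informative range, β > log₂ c disables abstention. The historical operating range is 1e−8…2 for c = 3. |
| `patch_width/height`, `stride` | 56 px / 56 px | grid geometry; stride = patch side gives disjoint tiles, smaller strides overlap |
| `min_level` | 1 | smallest contextual level auto-enumerated into the ensemble |
| `member_C` | 1.0 | inverse regularization of logistic members |
| `jitter_delta` | 0.05 (off in tests) | per-channel multiplicative color jitter half-width for augmentation |

Entropies and β are always log₂-based. Cross-validation is stratified by
grade with a fixed seed; folds fall back to unstratified (with a warning)
when a class has fewer images than folds.

## Synthetic data: what it does and does not emulate

`SyntheticConfig` generates H&E-like rasters: an eosin-pink Gaussian-noise
background with hematoxylin-purple elliptical blobs. Per grade, blob count
is Poisson with mean `density · image_area / area_unit` and radii are
uniform in a per-grade range. Defaults (densities 4/9/16 per patch area,
radii 3–5/3.5–6/4–7 px) make both nuclear density and size grow with grade
— mirroring the rising cellularity and nuclear enlargement the grades
encode — so expected blob coverage increases strictly with grade and the
classes are separable from texture alone. Default geometry is 224×168 with
56-px patches: the same 3×4 grid as the large-image layout at 1/16 area.

The generator does **not** emulate staining physics, nuclear morphology,
tissue architecture, or inter-lab stain variation. Passing tests therefore
demonstrate the correctness of the grid/gating/metric machinery and the
qualitative coverage–accuracy behavior, not clinical-grade performance on
real slides. Stain normalization is assumed to have happened upstream; the
only color augmentation is seeded multiplicative jitter.

Mock members stand in for trained image-wise models where only the
*statistics* of member outputs matter. Each has a `target_accuracy` (the
probability its output mode is the true class — enforced exactly by a
mode swap after sampling) and a `concentration` knob: the output is a
Dirichlet draw with parameter `base` on every class plus `concentration`
on the mode, so expected entropy decreases monotonically in concentration
(≈ one-hot as concentration → ∞; ≈ uniform as concentration → 0 for
`base` ≫ 1). One knob thus maps directly onto the entropy axis the gate
operates on.

## Numerical choices and degenerate inputs

- Probability-vector tolerance 1e−6 on the sum; entropy oracle agreement
  tested to 1e−12.
- `WAA` is undefined (error) only when *every* fold excluded *all* images;
  fully excluded individual folds contribute nothing.
- `AP` validates Σ(dᵢ + Rᵢ) = DS before reporting.
- The β-sweep re-gates cached member predictions rather than re-running
  members, and asserts the non-increasing-AP invariant on its own output.
- Per-class metrics come from a one-vs-rest confusion-matrix reading; the
  "Total" row is an unweighted macro average by default (`average=
  "weighted"` available). Zero divisions report 0 with a warning.
- Down-sampling between image scales is bilinear, exposed as an option
  rather than hard-wired.

## Problem sizes

Tests and the demo run at desk scale by design: 84–168 px images, 28–56 px
patches, tens of images, logistic members. These sizes exercise every code
path (including the 3×4 grid the shape census depends on) while keeping
the whole suite in seconds. The acceptance script synthesizes images at
the full published resolutions (up to 1280×960) since tiling is cheap.

## Known limitations

- Members gate on raw output entropy; no probability calibration
  (e.g. temperature scaling) is applied, so β values are comparable only
  across members trained the same way.
- Non-rectangular (L-shaped) context groupings are not generated.
- No whole-slide pyramidal formats; plain PNG/TIFF rasters only.
- The CLI's `grade` command runs mock-backend registries; trainable
  members are fitted and used through the Python API
  (`ElasticEnsembleClassifier` or `LogisticContextMember`).
- `score()` on the sklearn estimator counts abstentions as errors; use
  `decision_details` plus the WAA/AP helpers for coverage-aware numbers.
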