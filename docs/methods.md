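# Methods

## The segmentation model

`lamseg` segments c anatomical structures in a z-ordered stack of 2D
grayscale slices S by combining sparse manual annotation with a learned
patch classifier and a vote-density reconstruction. The method assumes:

* structures are distinguishable by **local texture** at the native pixel
  scale (for Nissl-stained tissue: the density and size of stained somata),
  not only by mean intensity or global shape;
* structure cross-sections **change slowly along z**, so the foreground of
  an annotated slice is a usable spatial prior for its neighbors;
* annotated slices are **exactly correct** (they pass through to the final
  volume verbatim and train the classifier).

### Stage 1 — initial localization

Slices 0, n, 2n, ... are the training set TC; the rest are the predicting
set PC. Each annotated slice's label map is binarized and dilated with a
disc structuring element (radius configurable). Each predicting slice
copies the foreground of its nearest annotated slice; the midpoint tie for
even gaps goes to the earlier (lower-z) slice, and slices outside the
annotated range copy the nearest end. Nearest-neighbor copying — never
blending — keeps every interpolated mask a genuine annotation-derived mask.

### Stage 2 — the patch classifier

Training patches (side p) are drawn uniformly with replacement from the
*undilated* labeled pixels of annotated slices and labeled by their center
pixel; the dilated foreground is used only at prediction time. Patches are
area-downsampled to d × d and normalized by the mean/sd of all downsampled
training patches (the stats are frozen into the model). 70% of the patches
train, 30% validate.

The default backbone (`lightweight`) is a multilayer perceptron:
flattened d² inputs → ReLU hidden layers (256, 64 at phantom scale) →
dropout (0.5) → c-way softmax. Training uses Adam on cross-entropy with
batch size 100, at most 50 epochs, the learning rate halved every 5
epochs, and early stopping once validation loss has not improved for 5
epochs (the best-validation weights are kept). The classifier sits behind
a single `PatchClassifier` interface, so the pipeline is
backbone-agnostic; `CenterLabelOracle` (a stub that returns the
ground-truth center label) plugs into the same interface to test the
reconstruction stages in isolation.

There is deliberately **no background class**: every sampled training
center carries a structure label, and reconstruction decides "background"
from vote density, not from the classifier.

### Stage 3 — sparse-to-dense reconstruction

For each predicting slice, m patch centers are drawn uniformly from the
initial foreground. Each one-hot prediction is deposited at its center in
a c-channel sparse map SM (collisions accumulate). The signal density of
channel t at (x, y) is the sum of SM_t over the w × w window centered
there (w = 51 by default; odd so the window has a unique center). Window
sums are used directly as confidence: dividing by the constant window area
cannot change the per-pixel argmax. Foreground pixels take
1 + argmax_t D_t (ties to the lowest channel); pixels with zero density in
all channels, or outside the foreground, become background — absence of
evidence is not evidence of membership.

Post-processing runs once per slice: for each structure, any 8-connected
component smaller than `min_component_fraction` (default 0.05) of that
structure's largest component is relabeled to the neighboring label
sharing the longest 8-connected boundary with it, ties to the lowest
structure id, background winning only when it is the only neighbor.
Boundary length was preferred over centroid distance because thin laminae
make centroids meaningless. All reassignments are decided on the input
labeling and applied together, so the pass is order-independent.

### Evaluation

Per structure and slice: DSC = 2|A∩B|/(|A|+|B|), precision |A∩B|/|A|,
recall |A∩B|/|B|. When both masks are empty all three score 1 (and the row
is flagged), so a structure legitimately absent from a slice does not
poison aggregates. Aggregation is mean ± sample sd over slices within a
structure, then the unweighted mean of structure means.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `slice_interval_n` | 100 | annotate every n-th slice (100 μm at 1 μm/slice) |
| `patch_size_p` | 800 px | receptive field; large enough to capture texture plus neighborhood context |
| `input_downsample_d` | 100 | classifier input side after area downsampling |
| `train_patches_total` | 220,000 | labeled patches across all annotated slices |
| `predict_patches_per_slice` | 100,000 | votes per reconstructed slice; DSC saturates here while cost grows linearly |
| `density_window_w` | 51 px | vote-pooling window, matched to the narrowest laminae worth resolving |
| `dilation_radius` | 50 px | foreground margin; must exceed the between-annotation drift of structure boundaries |
| `min_component_fraction` | 0.05 | component cleanup threshold, relative to each structure's largest component |

Defaults describe the full-scale operating point (≈ 10⁴ × 10⁴ px coronal
slices at 1 μm). The **phantom-scale** configuration
(`phantom_scale_config`) scales geometry-linked values to the 512 × 512
phantoms: interval 5, p = 64, d = 32, 30,000 training patches (6 slices ×
5,000), 20,000 prediction patches per slice, dilation 10 px (the phantom's
layer boundaries drift ≤ ~8 px between annotated slices). The density
window stays 51 px because the phantom reproduces laminar widths in
absolute pixels. The MLP trains with Adam base rate 1e-3 at this scale:
trained from scratch, it is under-converged within the 50-epoch cap at the
1e-4 default, which suits fine-tuning-scale CNN backbones.

## The phantom generator

Real reference volumes of this kind are not redistributable, so the
package generates its own study objects: concentric elliptical laminae
(outermost first, strictly nested radii) whose radius profiles morph
smoothly along z, each layer textured by a Poisson point process of
dark discs (soma analogue) with layer-specific density, radius and
contrast, over a shared background intensity, plus clipped additive
Gaussian noise. Dots may cross layer boundaries, as real somata do.
Layer identity is therefore carried by texture statistics, not by mean
tissue brightness per se — though dot coverage does shift local mean
intensity, exactly as soma density does in Nissl stains.

Presets: `easy` has thick layers and widely separated dot coverages
(≈ 2/30/12/55/80% of tissue area covered by dots, going inward); `hard`
compresses the coverage gaps and inserts a ~20 px lamina, thinner than
half the density window, which bounds its achievable DSC — by design.

What the phantom does **not** emulate: anisotropic PSF, vasculature,
staining gradients, tears/artifacts, non-elliptical geometry. Passing the
phantom studies therefore demonstrates that the pipeline recovers
texture-defined nested structures from sparse annotations under its own
assumptions; it does not certify performance on any particular real
histology volume.

## Numerical choices

* Windowed sums use an integral image and are bit-exact against the naive
  double-loop sum (tested on random instances).
* Argmax ties (classifier output, density channels, boundary-length
  neighbors) always break toward the lowest index/id — deterministic and
  documented.
* Patch standardization guards sd = 0 (constant input → all-zero features).
* Area downsampling is an exact block mean when p is a multiple of d, and
  anti-aliased resampling otherwise.
* All randomness flows from one master seed; per-purpose and per-slice
  streams are derived as `default_rng([seed, stage, slice])`, so slices can
  be reconstructed in any order, in parallel, or selectively, with
  identical results. Training is deterministic on a fixed BLAS.
* Reflect padding completes patches at slice borders, keeping thin
  peripheral layers sampleable without bias.
* Degenerate inputs: m = 0 prediction patches yields an all-background
  slice with a warning; an empty foreground or an all-background annotated
  slice is an error naming the slice.

## Study sizes

End-to-end studies run on 512 × 512 × 30 volumes with 5 structures —
large enough that the innermost structure still spans several density
windows, small enough for a laptop CPU. The prediction patch-number trend
is measured at m = 2,000 / 20,000 / 50,000 on every 4th predicted slice.
The full-scale defaults (interval 100, p = 800, 100,000 patches/slice) are
exposed but not exercised by the test suite.

## Known limitations

* The classifier sees each patch independently; no spatial regularization
  links neighboring predictions beyond the density window, and no 3D
  smoothing links neighboring slices — axial continuity relies on dense
  slice coverage.
* Center-pixel labeling is ambiguous within ~p/2 of a structure boundary;
  the density vote absorbs most, but not all, of that noise, so validation
  accuracy plateaus below 1 even when reconstruction is near-perfect.
* Structures thinner than about half the density window are systematically
  eroded (see the `hard` preset's thin lamina). Similarly, windowed
  majority voting erodes convex structures by roughly w²/(16R) pixels at a
  boundary of curvature radius R: a disc whose radius matches the window
  side loses several boundary pixels even under a perfect classifier. The
  `easy` preset keeps every structure's extent well above the window side
  for this reason.
* The dilated foreground ring around the outermost structure has no
  background class to claim it; over-segmentation of the outermost
  structure by up to the dilation radius is inherent to the method.
* The `lightweight` MLP backbone is adequate for strongly textured laminae;
  problems needing translation-equivariant features at full 800 → 100
  scale would warrant a convolutional backbone behind the same interface.
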