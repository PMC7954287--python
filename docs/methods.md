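# Methods

This note documents the models, numerical choices and synthetic data
behind `dlseg`, and what the test suite does and does not demonstrate.

## Pipeline and assumptions

The package implements the standard three-stage segmentation workflow:
*preprocessing* (pairing images with integer ground-truth masks, random
train/validation splitting at whole-item granularity, optional chopping of
a single large volume into subvolumes so one can serve as validation),
*training* (patch-based minibatch optimization with geometric
augmentation), and *prediction* (tiled whole-image inference with
stitching, followed by evaluation against ground truth).

Assumptions: semantic (per-voxel, multi-class) segmentation with class 0 =
background; masks are dense and spatially congruent with their images;
axis order is `(z, y, x, c)` everywhere with `z = 1` for 2D data; all
tile/crop coordinates are 0-based half-open intervals. Instance separation
and proofreading are out of scope.

## Architectures

Four families are generated from a single symbolic layer plan (the same
plan drives network construction, shape propagation, and parameter
counting, so the three can never disagree):

* `unet2d`, `unet3d`: two 3×3(×3) convolutions per level (stride 1),
  optional batch normalization, ReLU, 2× max-pooling; bridge; decoder with
  2× upsampling, center-crop skip concatenation and two convolutions;
  1×1(×1) classifier + softmax. Filter counts double per level from
  `n_first_filters`.
* `unet3d_aniso`: identical except the level-1 encoder convolutions and
  pool are 2D (pool acts on y, x only; z untouched), and the last decoder
  level mirrors the swap (2D upsample + 2D convolutions). All deeper
  levels are 3D. Intended for ≈1:1:2 (x:y:z) voxel aspect: the z spacing
  at full resolution already matches the *pooled* in-plane spacing, so the
  first pooling step should not coarsen z further. Because level-1 kernels
  are 1×3×3 instead of 3×3×3, the variant always has strictly fewer
  parameters than its isotropic twin.
* `segnet2d`: symmetric encoder–decoder; each decoder level unpools with
  the max-pooling indices recorded by its encoder twin and has no skip
  concatenation; `same` padding only (index unpooling requires aligned
  pool geometry).

### Upsampling

Decoder upsampling is 2× nearest-neighbour resize followed by a 1×1
projection convolution. A stride-2 transposed convolution — the other
common choice — has four independent kernel taps per output block and
therefore imprints a period-2 checkerboard even on spatially constant
input; that would break the contract that constant inputs produce constant
score maps (the observable criterion behind seam-free tiling). The resize
convolution is constant-preserving by construction, has identical shape
arithmetic (exact 2× per axis), and is the standard checkerboard-free
alternative.

### Shape arithmetic and the valid-padding feasibility rules

`same` padding preserves spatial size; the validator requires each pooled
axis to be divisible by `2^D` (for the anisotropic family, z only by
`2^(D−1)`). `valid` padding shrinks every axis by `12·2^D − 8` for the
isotropic U-Nets (each of the `2(D+1)` encoder/bridge convolutions and
`2D` decoder convolutions removes 2 voxels at its resolution); the
anisotropic family shrinks z only at 3D levels. Feasibility is checked by
layer-by-layer propagation with two junction rules in valid mode: the size
entering every 2× pool and the size entering every 2× upsampling must be
even. The second rule is stricter than pure mechanics requires (an odd
bridge could be upsampled and center-cropped), but it keeps the
encoder/decoder feature grids exactly registered: with an odd junction the
skip crop becomes asymmetric and the concatenated features are offset by
half a voxel. Valid 2D patches at depth 2 must therefore satisfy
`size ≡ 4 (mod 8)` (100 → 60 works; 64 and 128 are rejected). Skip crops,
when needed, are centered; an odd crop removes the extra voxel from the
high-index side. Argmax ties in `scores_to_labels` and in max-pooling
resolve to the lowest index.

Weights are He-uniform initialized (seeded); activation is ReLU; batch
normalization after each convolution is on by default (momentum 0.1,
eps 1e-5, running statistics used at inference) and can be disabled per
spec. All tensors are float32.

## Training

* Loss: voxelwise softmax cross-entropy, computed from logits for
  stability; optional class weighting (`inverse_frequency`: weights
  proportional to inverse class frequency over the training masks,
  normalized so the weighted mean over present classes is 1; the weighted
  loss divides by the total voxel weight so uniform weights reduce to the
  plain mean).
* Optimizer: Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e-8), learning rate from
  the config (default 1e-3). No schedule, no early stopping.
* One epoch samples `patches_per_image` (default 16) uniform-random
  aligned crops from every training item, augments each, shuffles, and
  iterates minibatches of `batch_size` (default 4); with valid padding the
  target mask is center-cropped to the network output. Defaults:
  `max_epochs` 50, `validation_fraction` 0.1 (within the conventional
  80–90 % training share; the validation count is round-half-up of
  `fraction × N`, and fraction 0 disables validation monitoring entirely).
  Input normalization (default `zscore`) pools per-channel statistics over
  all training voxels; `zscore`/`rescale01` refuse constant channels.
* Validation each epoch runs full tiled prediction on the held-out items
  and reports loss and per-class Jaccard.

### Determinism and checkpointing

All randomness flows through `numpy` generators seeded from the training
config: one stream for weight initialization, one shared stream for patch
sampling + augmentation + shuffling. A checkpoint stores weights, batch
norm running statistics, Adam state, both the current stream state and the
state at the start of the current epoch, iteration/epoch counters, the
loss history and the generating configs (arrays in one `.npz`, metadata in
a JSON sidecar). Resuming restores all of it and continues the identical
operation sequence, so resumed runs are bit-for-bit equal to uninterrupted
ones; a mid-epoch checkpoint is resumed by regenerating the epoch's patch
stream from the epoch-start state and skipping the consumed minibatches.
Checkpoint cadence is a parameter (`checkpoint_every_n_iterations`;
0 = only at the end); per-iteration cadence reproduces the densest
setting at the cost of I/O. Execution is single-threaded deterministic
throughout; no non-reproducible fast path is provided (the CLI's
`--reference-mode` flag is accepted for interface stability).

## Augmentation

Per-patch geometric augmentation draws, in a fixed order: reflections
(per axis, probability `p_reflect`; z may flip in 3D), one in-plane
rotation angle (±`rotation_range`°), an isotropic scale
(`scale_range`), and a shear angle (±`shear_range`°). Rotations are about
the z axis only — full 3D rotations would mix anisotropic z into x/y.
Defaults (`p_reflect` 0.5, rotation ±90°, scale 0.8–1.2, shear ±10°) are
conventional. The identical spatial map is applied to image (linear
interpolation) and mask (nearest-neighbour, so labels stay valid class
indices); the transform acts about the patch center, output size equals
input size, and out-of-bounds samples are filled by reflection so no fake
background rim appears. Elastic distortion (per-axis uniform displacement
fields in [−1, 1], Gaussian-smoothed at scale `sigma`, scaled by `alpha`
voxels; `alpha` = 0 is the identity) is exposed as a dataset-expansion
step (`dlseg distort` writes distorted copies next to the originals)
rather than inside the per-iteration augmenter.

## Prediction and stitching

Images are normalized with the training-time statistics, reflect-padded,
tiled, and each tile's network output contributes only an interior *emit*
region; emit regions partition the image exactly, making stitching
deterministic and order-independent (averaging of overlaps is a possible
alternative, not implemented). In valid mode the tile stride equals the
output size and the padding is half the total shrink per side, so tiled
prediction equals a single whole-image pass wherever both are defined. In
same mode the stride is `patch − overlap` and each seam is cut at the
midpoint of the neighbouring tiles' overlap (a margin of ⌊overlap/2⌋ is
discarded, except at image borders); the default overlap is 25 % of the
patch per axis. Same-mode zero-overlap tiling is supported but prone to
seam artefacts near tile borders, which is precisely what the overlap
option suppresses.

## Synthetic fixtures

The generators emulate the *structure* of four common segmentation tasks,
not microscope appearance: `membranes2d` (Voronoi cells with dark
2-voxel boundaries — thin-structure EM-style segmentation), `nuclei2d`
(elliptical nuclei with a 2-voxel rim per instance; rim voxels claimed by
≥ 2 instances form an explicit *interface* class, computed exactly from
the retained instance map, with one touching doublet always planted so the
class is never empty), `blobs3d_iso` (ellipsoids), and
`blobs3d_aniso_2ch` (z-squashed ellipsoids per the 1:1:`z_aspect` voxel
aspect, default 2; channel 1 = cytoplasm, channel 2 = nucleus subregion;
classes background/cytoplasm/nucleus). Images are few-level intensity
functions of the noiseless geometry plus Gaussian noise (σ = 0.05 by
default against class contrasts of ≳ 0.3), so every fixture is separable
by a small network and a short training run — by design. Passing the
learning tests therefore demonstrates that the pipeline's mechanics
(sampling, augmentation, optimization, tiling, scoring) work end to end;
it says nothing about accuracy on real EM/LM data, whose texture, class
imbalance and annotation noise the fixtures deliberately omit.

## Problem sizes used by the tests

Unit tests use networks of 2–8 first-level filters on patches between 8²
and 44² (3D: up to 24³) so the whole suite runs in minutes on one CPU.
The learning check trains a depth-2 `unet2d` (16 first-level filters,
64² patches, batch 4, 16 patches/image) for 20 epochs on 10 membranes
images of 128² with a 0.2 validation split — about two minutes — and
requires held-out membrane Jaccard ≥ 0.9; the run typically reaches
≥ 0.99. Gradient correctness is verified against central finite
differences on float64 instances of all four families, and the
convolution forward pass against `scipy.ndimage.correlate`.

## Known limitations

* No GPU or parallel execution; throughput is numpy-bound. Practical for
  the fixture scale and small real crops, not for large production
  volumes.
* Only PNG/TIFF input; no proprietary microscopy containers, no
  out-of-core loading.
* Patch sampling is uniform; class-balanced sampling is a possible
  extension. A fixed patch-grid mode (instead of random sampling) is not
  implemented.
* SegNet uses a depth-parameterized symmetric encoder, not a fixed
  VGG-style encoder.
* No learning-rate schedules, early stopping, mixed precision,
  test-time augmentation or ensembling.
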