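# Methods

## Problem and model

`hepaseg` segments three structures in contrast-enhanced micro-CT stacks of
mouse livers bearing pancreatic-cancer metastases: the healthy liver (HL),
the whole metastatic liver area (MLA), and the individual liver metastases
(LM). One specialized network is trained per task. The contrast agent is
taken up by hepatic macrophages, so healthy parenchyma appears bright,
metastatic lesions appear as darker regions inside it, and bright
confounders (the spine with its darker marrow channel, the polystyrene
support cradle) lie outside the organ.

Each network is a U-net: a contracting path alternating a convolutional
block with 2×2 stride-2 max pooling, a bottleneck block, and an expanding
path of 2×2 up-convolutions, skip concatenations with the same-level
contracting output, and another block. The head is a 1×1 convolution with a
sigmoid, so every pixel receives a probability; every other activation is a
leaky ReLU (negative slope 0.3, configurable). The blocks are inception
style: five parallel branches concatenated along channels. Writing conv(k)
for a k×k convolution + batch normalization + leaky ReLU, the branches are

* variant 1: conv(1) | conv(3) | conv(1) | conv(1) | pool→conv(1)
* variant 2: conv(1) | conv(3)→conv(3) | conv(1)→conv(3) | conv(1) | pool→conv(1)
* variant 3: conv(1) | conv(3)→conv(3) | conv(1)→conv(3)→conv(3) | conv(1) | pool→conv(1)

The in-block 2×2 max pool runs at stride 1 with edge padding so its branch
stays concatenable with the others (its 1×1 convolution has a leaky ReLU
but no batch norm); the between-block 2×2 pooling is stride 2. With f
filters per branch a block emits 5f channels.

Predicted probability maps are binarized at the fixed threshold τ = 5/255
(kept as the exact rational on the probability scale), with a *strict*
inequality: a pixel is positive iff p > τ. MLA and LM predictions are merged
into one label map (0 background, 1 metastatic liver only, 2 metastasis)
with lesion precedence where both are positive.

## Design choices where the layout was open

* **Decoder symmetry.** The printed layer table lists six contracting
  blocks (five poolings) but only four up-convolution stages, which cannot
  restore a 512×512 input. The default (`symmetric_decoder=True`) mirrors
  all five levels; `symmetric_decoder=False` reproduces the four-stage
  layout and restores the input size with a final exact bilinear upsampling
  (implemented as two separable linear maps so its gradient is the exact
  adjoint). Probability maps must be comparable pixelwise with full-size
  ground truth, hence the symmetric default.
* **Filter scaling.** A single per-task "number of filters" is interpreted
  as the per-branch count of the shallowest block, doubled per contracting
  level and capped at 16× (standard U-net scaling); both the base and the
  cap are in `NetworkSpec`.
* **Conv→BN→activation** ordering within a pair; Glorot-uniform weights,
  zero biases, "same" zero padding, stride 1.
* **Optimizer.** The training protocol fixes epochs, batch size, steps per
  epoch, filters and learning rate but not the optimizer; Adam is used
  (β₁ 0.9, β₂ 0.999, ε 1e-7). The MLA learning rate of 1e-1 is kept as
  specified but flagged in the logs as unusually high for Adam.
* **Under-sampling epochs.** Steps-per-epoch × batch may be smaller than
  the training set (e.g. 35×8 = 280 < 592); each epoch draws random
  augmented batches rather than sweeping the set.
* **Augmentation.** Width *and* height shift of fraction 0.1, horizontal and
  vertical flips, zoom in [0.9, 1.1]; one affine with linear interpolation
  and constant-zero fill, applied identically to image and mask; the mask is
  re-binarized at 0.5. Flips are exact index reversals. Validation images
  are never augmented.
* **Median "2 pixels"** is read as radius 2 (a 5×5 window), per-slice, with
  edge replication. **Gaussian blur** uses σ = kernel/5 (σ = 1.0 for the
  default 5×5), truncated at the kernel bounds — the grid size is fixed by
  the protocol, σ is a package choice exposed in `PreprocessConfig`. The
  blur is applied after padding (the chain order is downsample → median →
  single-channel → pad → blur → optional cleaning).
* **Intensity normalization** divides by the dtype maximum (255, 65535),
  never per-image min–max, which would break cross-slice comparability of
  the contrast-enhanced signal.
* **Masks through preprocessing** follow only the geometric operations
  (axial stride, padding); they are never median-filtered or blurred.

## Numerical core

No deep-learning framework is used: the layers (convolution, batch norm,
pooling at both strides, transposed convolution, bilinear resampling) carry
hand-written forward and backward passes on float32 NCHW arrays, validated
against central finite differences in float64 in the test suite (worst
relative error ~1e-5 at step 1e-6). Convolutions loop over the k² taps with
one batched matmul each, keeping peak memory at one activation copy.
Training losses are computed from logits with the stable
log1p formulation; `bce_loss` on probabilities clips to [1e-7, 1-1e-7].

Batch normalization (momentum 0.99, ε 1e-3) trains on batch statistics and
infers from exponential moving averages. The averages are stored
zero-initialized with an update counter and read back debiased by
1 − momentum^t (the correction Adam applies to its moments). This matters:
after a few hundred updates the raw averages are still far from the batch
statistics, and inference with them inflates background probabilities —
which the very low τ = 5/255 then converts into large false-positive areas.

Metrics with a zero denominator (e.g. precision when nothing is predicted
positive — a real occurrence on distal slices for the lesion task) are
reported as explicit `None`/"undefined", never 0 or 1. Validation metrics
are pixel-pooled (micro-averaged): confusion counts are summed over all
slices before ratios are taken.

## Synthetic phantoms

The phantom generator emulates the geometry and contrast of the real
stacks: the liver is a union of 2–4 overlapping ellipsoids whose indicator
is Gaussian-smoothed and re-thresholded (one connected, irregular, bright
organ, mean intensity 0.75 against a 0.05 background); lesions are
ellipsoids with ≤30 % per-axis jitter placed fully inside the liver by
rejection sampling (bounded retries, explicit `PlacementError` on failure),
darker by a fractional contrast of 0.5; the spine is a bright cylinder
(0.9) with a darker marrow channel (0.35) near the top edge; the cradle is
a moderate-intensity arc band at the bottom boundary. Additive Gaussian
noise (σ 0.02) is applied last and the result clipped to [0, 1]. All draws
come from one `numpy.random.Generator`, so output is bit-reproducible per
seed.

What the phantoms do **not** model: projection/reconstruction physics,
beam hardening, Poisson noise, Hounsfield calibration, contrast kinetics,
anatomical texture, or the intensity overlap between liver tissue and
metastases that makes real central slices hard even for human operators.
Passing the end-to-end tests therefore shows that the pipeline is wired
correctly and can learn bright-organ/dark-lesion geometry — not that it
reaches any particular accuracy on animal scans.

## Problem sizes in tests and the acceptance script

The end-to-end run uses one phantom of 80×56×56 voxels, downsampled 1:2
axially and padded to 40 slices of 64×64; networks are built at depth 2 and
trained for 10 epochs of 10 batches of 8 (Adam, 1e-3), split 80/20. These
sizes are the package's chosen smoke-scale study conditions; the full-size
512×512 depth-5 architecture is exercised forward-only in the contract
tests. Under these conditions all three variants reach validation Dice
≥ 0.9 on the liver task at τ = 5/255, and zeroing the confounder mask
before lesion prediction strictly reduces pooled false positives.

## Known limitations

* Recomputing metrics from *rounded* percentage rates cannot always land
  within 0.2 pp of metrics computed from unrounded counts when the
  denominator is small: for the cleaned-LM column (tp 1.8 %, fn 8.3 %,
  fp 0.1 %) the reconstructed Recall and IoU deviate by 0.22 and 0.35 pp.
  The `reproduce_tables` report carries the deviations explicitly.
* Training is single-device, single-threaded deterministic; bit-identity
  across BLAS builds is not promised.
* The CPU engine is for moderate problem sizes; full-size 512×512 training
  at the printed step counts is possible but slow (no GPU path).
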