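# Methods

This note records what `pointcell` computes, the assumptions behind it,
and the design choices made where more than one reasonable option existed.

## Problem setting

Extended-depth-of-field cervical cytology images show translucent cells
whose cytoplasm regions overlap inside clumps. Ground truth is therefore a
*set* of per-cell binary masks over the same pixel grid — masks may share
pixels, and a pixel can be foreground for one instance and background for
another. The package implements the full loop: synthetic scene generation,
a two-stage segmentation network with point-based boundary refinement,
and the challenge evaluation protocol for overlapping cytology.

## Synthetic scenes (`pointcell.synth`)

The generator emulates how the public synthetic cytology benchmarks were
built from isolated cells: each scene composites 2–10 cell templates onto
a bright background with minor brightness variation, and scenes span mean
overlap rates from 0 to 0.5.

* **Cell shape.** The cytoplasm outline is an ellipse (semi-axes a
  fraction 0.10–0.18 of the image side, random orientation and aspect
  0.7–1.0) modulated in polar form by low-order Fourier harmonics
  (k = 2..4, total amplitude ≤ 0.08). This keeps contours simple
  (non-self-intersecting) while breaking perfect symmetry. The nucleus is
  a scaled (0.22–0.35), slightly offset copy of the ellipse, constructed
  to lie strictly inside the cytoplasm.
* **Rendering.** Overlap is rendered by multiplicative translucent
  blending: the background (level ≈ 0.92 with per-image jitter) is
  multiplied by each cell's attenuation layer (cytoplasm ≈ 0.72–0.88,
  nucleus ≈ 0.35–0.55), so clump interiors are darker the more cells
  stack — the appearance translucent cytoplasm has in extended-depth-of-
  field micrographs. Mild Gaussian noise is added last.
* **Overlap rate** is *defined* here (the benchmarks publish the number
  but not the formula) as the mean over cells of the fraction of the
  cell's pixels shared with at least one other cell. Placement bisects a
  single clump-contraction factor against the measured rate; the achieved
  value is recorded in scene metadata rather than forced, and a warning is
  issued if it misses the target by more than 0.1.
* **Rasterization** uses the pixel-centre convention package-wide: a pixel
  belongs to a mask iff its centre lies inside the contour.
* **Augmentation** applies one randomly selected subset of {90°
  rotations, horizontal/vertical flip, bounded rescale 0.85–1.15×}
  identically to image and masks; instances emptied by a transform are
  dropped with a warning.
* **What it does not emulate:** stain variability, mucus/debris, blur
  gradients, annotation noise (an optional `ignore_mask` models unlabeled
  pixels but defaults to off), and real cytoplasm texture. Passing tests
  on these scenes demonstrates the *pipeline* (geometry, learning
  dynamics, protocol), not clinical-grade accuracy on real smears.

## Network (`pointcell.model`, `pointcell.nn`)

The model follows the two-stage Mask R-CNN meta-architecture with a
point-refinement module:

* backbone + FPN producing `P2..P5` at strides 4/8/16/32;
* RoI align (mean of 2×2 bilinear samples per output cell, 7×7 output,
  no quantization);
* mask branch: two 3×3 convs, transposed convolutions 7→14→28 (kernel 2,
  stride 2), 1×1 projection to one logit grid;
* box/category branch on the flattened RoI feature (hidden width 128;
  smooth-L1 on standard box deltas, binary cross-entropy foreground vs
  background with one sampled background box per image);
* point head: `α ∈ {2,3,4}` layers × 256 channels applied per point (a
  1×1 convolution over the point axis and a shared fully connected layer
  are the same operation), final linear to one logit, no activation after
  the last layer. Inputs are `F_fine ⊕ F_coarse`, sampled bilinearly from
  `P2` (configurable) and from the 7×7 RoI feature respectively.

Training minimises `L = L_mask + L_point + L_box + L_cls` — an unweighted
sum, no tunable λs — with SGD (lr 0.002, momentum 0.9, weight decay 0,
constant schedule, batch 2 images, gradients accumulated per batch).
During training `β = 196` points per RoI are drawn by biased random
sampling (3× oversampling, keeping the 75% most uncertain, rest uniform);
at inference the `β = 784` most uncertain points are taken
deterministically (top-k, row-major tie-break).

Mask targets are the ground-truth mask RoI-aligned into the proposal box
at 28×28 and thresholded at 0.5; point labels use nearest-pixel lookup
(bilinear-then-threshold available). Proposals default to teacher-forced
ground-truth boxes with ≤10% side jitter (`gt_boxes`); a single-anchor
RPN (`learned_rpn`) is provided behind the same interface, its
objectness/regression terms folded into the cls/box components so the
four-term identity holds. The teacher-forced default reflects that the
method's contribution is boundary refinement, not proposal learning.

The engine underneath is a small reverse-mode autodiff on numpy arrays
written for this package (convolutions via im2col windows, differentiable
bilinear gathering for RoI align and point sampling); gradients are
verified against central differences in the test suite. The tested
backbone is deliberately tiny (widths 16/32/64/128, FPN width 32, or
8/16/32/64 in the CI configuration) — the reference-scale choice in this
field is a pretrained ResNet-101, which is out of reach of a CPU-only
test cycle; a wider `resnet_like` preset exists behind the same config.

## Refinement (`pointcell.refine`)

At inference the coarse 28×28 probability grid is bilinearly doubled per
pass; after each doubling the `β` most uncertain pixels (probability
closest to 0.5) are re-predicted by the point head and overwritten, all
other pixels keeping their interpolated values exactly. The default is
two passes (28→56→112, reaching box resolution); `passes=1` reproduces a
literal single-pass reading, `passes=0` or disabling the point head
degenerates to plain bilinear upsampling (the ablation baseline). The
refined grid is pasted into the box footprint at image resolution
(bilinear, zero outside, threshold 0.5); empty pasted masks drop the
detection. Detections are never made mutually exclusive: two cells may
claim the same pixel.

## Evaluation (`pointcell.evaluation`)

* **DSC matching**: greedy on the full gt×pred DSC matrix in descending
  order, each side used once, pairs below the threshold rejected, ties
  broken by lower indices (a Hungarian option exists). "Above the
  threshold" is read as ≥; a strict-> flag is provided.
* **Pixel metrics**: per matched pair, `TP = |gt ∩ det|`,
  `FN = |gt − det|`, `FP = |det − gt|`, `TN` the full-image complement of
  the union; `TPRp = TP/(TP+FN)`, `FPRp = FP/(FP+TN)`. The exclusion rule
  applies: a ground-truth cell with no match contributes to no pixel
  metric, only to `FNRo = unmatched / total`.
* **Aggregation**: mean ± std over matched cells pooled across the
  dataset; a per-image breakdown and (cell count × overlap-rate bin)
  strata (bin width 0.1 over [0, 0.5]) are also emitted, with empty
  strata absent rather than zero-filled. Whether μ ± σ should be over
  cells or images is genuinely ambiguous in the protocol; both views are
  available.
* **AP**: COCO-style mask AP (greedy score-ordered per-image matching per
  IoU threshold 0.50:0.05:0.95, dataset-pooled 101-point interpolated
  precision), cross-checked in the tests against an independent naive
  implementation.
* Two empty masks have DSC 0 by convention (with a warning); `ignore_mask`
  pixels are excluded from all four pixel counts.

## Numerical conventions

One convention package-wide: feature node (i, j) of a stride-s grid sits
at image point ((j+0.5)s, (i+0.5)s); boxes are half-open; continuous
sampling clamps to the border (align-corners-false semantics). Bilinear
weights are the standard convex form — nonnegative, summing to one,
exact on functions a+bx+cy+dxy — asserted in tests to machine precision.
Top-k selection breaks ties by row-major index so inference is bit-for-bit
reproducible; every stochastic component (synthesis, init, point
sampling, augmentation, jitter) draws from a seeded generator, and
(config, seed) determines outputs exactly.

## Problem sizes

The CI and acceptance configuration — 64×64 scenes, 2–6 cells, overlap
targets up to 0.3, 48 training / 16 held-out scenes, 40 epochs, the
8/16/32/64 backbone — is the package's desk-scale default: large enough
for the trained model to reach mean held-out DSC ≳ 0.9 with FNRo 0, small
enough that the full loop (and the 7-cell ablation grid at 12 epochs)
runs in minutes on one CPU. The synthetic-benchmark-sized configuration
(512×512, 2–10 cells, overlap to 0.5) is the library default for
`SynthConfig` and works unchanged, just slower.

## Known limitations

* The tiny backbone and teacher-forced proposals measure the refinement
  machinery, not detection quality from scratch; the single-anchor RPN is
  functional but not tuned.
* Synthetic appearance is far simpler than real smears; absolute metric
  values here do not transfer to real data.
* The point head refines per-instance masks independently; no cross-
  instance consistency (e.g. shared-boundary reasoning) is attempted.
* Mask AP on heavily overlapping instances inherits the usual COCO
  greedy-matching caveats.
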