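# Methods

## Problem and model

The task is binary semantic segmentation of colorectal polyps: given an
RGB colonoscopy frame `x`, predict a per-pixel foreground probability
`ŷ ∈ [0, 1]` whose 0.5-threshold is the polyp mask. The architecture is a
U-shaped encoder–decoder that combines four ideas:

1. **Dense encoder.** Within a dense block, layer `t` receives the channel
   concatenation of the block input and all previous layer outputs
   (`x_t = H_t([x₀, …, x_{t−1}])`). Each layer is a bottleneck pair —
   BN, `1×1` conv to `4k` channels, ReLU, BN, `3×3` dilated conv to `k`
   channels, ReLU — so block output width is exactly `c_in + n·k`.
   Between blocks a transition (`1×1` conv to `⌊θ·c⌋`, `2×2` stride-2
   average pool) compresses and downsamples. Defaults: growth rate
   `k = 48`, layer counts `[6, 12, 36, 24]`, `θ = 0.5`, depth `s = 5`
   (stem level + one level per block), stem `7×7`, 96 filters, stride 2
   followed by `3×3` stride-2 max pooling. For a 224 input the level
   sides are `[112, 56, 28, 14, 7]` and pre-transition widths
   `[96, 384, 768, 2112, 2208]`.
2. **Atrous (dilated) convolution.** `(F *_l k)(p) = Σ_{s+lt=p} F(s)k(t)`:
   kernel taps spaced `l` apart, equivalent to convolving with the kernel
   zero-inflated by `l−1` zeros between taps. Every `3×3` convolution in
   the network uses rate `l = 2` by default (per-block overrides are
   configurable). `adenseunet.atrous.atrous_convolve` is a plain-NumPy
   executable definition of the operator, kept independent of the network
   layers so the test suite can cross-check both against
   zero-inflated `scipy.signal` convolution.
3. **Nested, attention-gated decoder.** Decoder nodes form a grid
   indexed by (level, column); node (i, j) consumes all same-level
   predecessors (the encoder feature at column 0 plus earlier decoder
   nodes) and the node one level deeper / one column earlier. The deeper
   features drive an additive attention gate (1×1 projections of skip and
   gate to a common width, sum, ReLU, 1×1 to one channel, sigmoid) whose
   coefficients multiply the skip features; the deeper features themselves
   are upsampled by a 2×2 stride-2 transposed convolution and concatenated
   with the gated skip. A residual refinement block (two dilated 3×3
   conv+BN stages and a 1×1-projected shortcut, summed without a trailing
   activation) produces the node output. Setting
   `use_dense_decoder_links=False` collapses the grid to an ordinary
   single-column U-Net decoder.
4. **Deep supervision.** Every top-row node is projected by a `1×1`
   convolution to a common width (32), upsampled ×2 to full resolution by
   a transposed convolution, averaged across columns, and passed through a
   final `1×1` convolution and sigmoid — so the output is bounded in
   `[0, 1]` by construction for any real input.

When dilation is enabled, a **multi-rate atrous pyramid** sits at the
encoder bottleneck: parallel dilated `3×3` convolutions at rates
`[1, 2, 4]` (branch width `max(c/8, 8)`), concatenated and fused by a
`1×1` convolution back to the input width. It supplies multi-scale context
at the coarsest level, and it ties the dilation ablation to a concrete
parameter budget: `use_dilation=False` removes the pyramid and resets
every dilation rate to 1, so each of the three ablation flags
(`no_attention`, `no_dilation`, `no_dense_links`) strictly reduces the
parameter count while preserving the output-shape contract.

## Numerical backend

The network runs on `adenseunet.nn`, a compact reverse-mode autodiff
engine over NumPy arrays (NCHW): a `Tensor` tape with iterative
topological-order backpropagation, convolution as im2col + a single GEMM
(with a pointwise fast path for `1×1` kernels), exact ×2 transposed
convolution, SAME zero-padding everywhere (so dilated `3×3` kernels —
effective `5×5`, padding 2 — preserve spatial size and the level-side
table holds), max/average pooling, batch normalisation with running
statistics, and Adam. Parameters are float32, He-normal initialised from
one seeded generator recorded in the config. Every operator's gradient is
verified against central differences in the test suite. Inference runs
under a `no_grad` context so no tape is retained.

## Training protocol

Adam, initial lr 0.01; the lr is multiplied by 0.1 once the monitored
loss (validation loss when a validation set is given, else training loss)
fails to improve by at least `1e−4` for more than 5 consecutive epochs.
Early stopping (default patience 15, configurable) halts training and the
best-monitored parameter state (including BN running statistics) is
restored. Batch size 10, 100 epochs, BCE loss by default; soft Dice, soft
Jaccard and MSE are selectable alternatives. The BCE sum is averaged over
pixels and batch so the lr is independent of image size. `max_steps`
bounds the total number of optimizer steps for smoke runs. A non-finite
loss aborts with a diagnostic rather than training through NaNs.

## Metrics

All metrics derive from an explicit confusion tally of binarized
predictions (threshold 0.5, boundary inclusive): recall `TP/(TP+FN)`,
precision `TP/(TP+FP)`, IoU `TP/(TP+FP+FN)`, Dice `2TP/(2TP+FP+FN)`;
for a single pooled tally `Dice = 2·IoU/(1+IoU)`. Degenerate
denominators: a metric is 1 when both masks are empty and 0 when exactly
one is — the standard convention that keeps per-image averaging defined.
Dataset aggregation defaults to the per-image mean (the norm in the
segmentation-benchmark literature); globally pooled counts are available.
Predictions are clipped at `1e−7` before logarithms in the BCE.

## Augmentation

Each training image is first resized with its aspect ratio retained
(shorter side to the target, random square crop), then each of
`multiplier − 1` variants applies an independent random sub-chain (each
technique with probability 0.5) of: rotation with angle uniform in
[0°, 90°] (bilinear image / nearest mask, reflect padding); horizontal
and/or vertical reflection; elastic deformation from a fixed 10×10 grid
of i.i.d. uniform displacement vectors (default magnitude 6 px)
interpolated to a dense field, bicubic for the image and nearest for the
mask; and random gamma in [0.7, 1.5] on the image only. Image and mask
always receive the identical geometric transform and masks remain strictly
binary. With multiplier 10, 800 inputs yield exactly 8000 outputs
(originals included), bytewise reproducible from the seed: each output is
generated from an independent child seed of (seed, sample index, variant),
so the streaming iterator and the materialised list agree element-wise and
memory use stays flat.

## Synthetic phantoms

`adenseunet.phantom` renders colonoscopy-like pairs: a pink-brown
low-frequency mucosa texture (Gaussian-filtered noise, correlation length
`texture_scale`), one or two elliptical polyps (axes 8–25 % of the side)
with their own texture, dome shading and smoothed borders, 2–6 saturated
specular spots, and radial vignetting. The mask is the exact union of the
generating ellipse interiors, computed from the geometry before any
smoothing — ground truth is never re-segmented from the rendered image.
Foreground fractions fall in roughly 2–30 % of pixels. The phantoms
exercise the full pipeline (polyps brighter than mucosa, confounding
highlights, exact masks) but deliberately lack real-data difficulties:
no motion blur, fluid, occlusion, flat/sessile morphology, camera
distortion or annotation noise. Passing tests on phantoms therefore
demonstrates that the architecture, gradients, protocol and I/O are
correct — not that the model reaches any particular accuracy on real
colonoscopy data.

## Problem sizes used in tests and the acceptance script

The default 224-input network (~81 M parameters) is built and run forward
once to verify the layout and output contract. Training checks use a
reduced configuration — 96-px input, `k = 8`, blocks `[2, 2, 2, 2]`,
stem 32, decoder cap 32, head width 16 (~0.5 M parameters) — trained for
150 Adam steps at batch 4 on eight phantoms, which the net memorises to
Dice 1.0; a luminance-threshold baseline on the same phantoms provides the
sanity separation. The augmentation protocol is exercised at full scale
(800 × 10) via the streaming iterator.

## Design decisions where the design was open

* Dense-layer op order follows the stated `BN → conv → ReLU` (the classic
  DenseNet `BN → ReLU → conv` is available via `dense_layer_order`).
* Transition compression `θ = 0.5` keeps deep-level widths sane given
  `k = 48`.
* Decoder widths follow `min(64·2^(i−1), cap)` per level
  (`decoder_channel_rule="halve-per-up"`); matching encoder widths is the
  alternative rule.
* The attention gate multiplies into the skip path, with the deeper
  node's pre-upsample features as the gating signal; the gate is
  upsampled (nearest) to the skip resolution inside the block.
* Mask binarization at the 8-bit midpoint (> 127) tolerates compression
  artefacts in nominally binary masks.
* Split rounding: train `⌊0.8n⌋`, validation `⌊0.1n⌋`, test the
  remainder.
* "Patience exceeds 5" is read as: reduce the lr after 5 epochs without
  improvement; early-stop patience (not quantified by the protocol)
  defaults to 15.

## Known limitations

* CPU-only by design; the default network takes seconds per forward pass,
  so full-scale training on real datasets is out of reach here.
* The deep-supervision average upsamples from the stem level (112) to
  full resolution with a learned ×2 transposed convolution; very fine
  boundary detail is limited by that final upsampling.
* The nested-grid wiring of the decoder and the attention-gate internals
  are one concrete interpretation of the design; both are isolated behind
  `build_decoder_node` / `build_attention_gate` and config flags so
  alternatives can be swapped in.
* Parameter counts are reported, not matched to any external reference.
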