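# Methods

## Problem and model family

The package classifies facial micro-expressions into three emotion
classes (positive / negative / surprise) from dense optical-flow images:
per-pixel displacement fields computed between a micro-expression's
onset and apex frames, resized to 75 × 75. Input channels default to 3 —
horizontal flow *u*, vertical flow *v*, and the flow magnitude — the
common composite in this literature; 2-channel (*u*, *v*) input is
supported.

The base classifier is a compact CNN (five convolutions, three pools,
three dense layers). The layer table is fixed:

| stage | op | kernel | stride | effective padding | out |
|---|---|---|---|---|---|
| Conv1 | conv + ReLU | 7 | 1 | 0 | 96 × 69 × 69 |
| Conv2 | conv + ReLU | 5 | 1 | 0 | 256 × 65 × 65 |
| Conv3 | conv + ReLU | 3 | 1 | 1 | 512 × 65 × 65 |
| Pool3 | max pool | 3 | 2 | 0 | 512 × 32 × 32 |
| Conv4 | conv + ReLU | 3 | 1 | 1 | 512 × 32 × 32 |
| Pool4 | max pool | 3 | 2 | 1 | 512 × 16 × 16 |
| Conv5 | conv + ReLU | 3 | 1 | 1 | 512 × 16 × 16 |
| Pool5 | max pool | 3 | 2 | 1 | 512 × 8 × 8 |
| FC1/FC2 | dense + ReLU | | | | 128 |
| FC3 | dense + softmax | | | | 3 |

The effective paddings are the unique per-layer values that reproduce
this output chain under floor arithmetic; construction verifies the
chain and raises on mismatch. The trunk pools are max pooling (average
pooling appears only inside SPP branches); batch normalization appears
only inside multi-scale branches; flattening between Pool5 and FC1 is
channel-major raster order, fixed so checkpoints are portable.

## Multi-scale blocks

A block of *n* parallel branches is inserted after Conv1 or Conv2; its
outputs are bilinearly resized to the block input size and concatenated
with a skip copy of the input, so output channels are
`in + n · branch_channels`, and the next convolution is simply widened
to accept them (no 1 × 1 fusion projection). Both branch kinds use a
3 × 3 branch convolution with 64 filters by default; since average
pooling adds no parameters, the SPP branch (conv → avg-pool → BN →
ReLU) and the ASPP branch (3 × 3 atrous conv at rate *r*, same padding
→ BN → ReLU) carry identical weight tensors, which makes the
direct-flow SPP and ASPP networks parameter-count-identical — a
property the suite asserts.

Flows: **direct** feeds every branch the block input; **waterfall**
feeds branch *i* the post-ReLU, pre-resize output of branch *i − 1*,
cascading fields of view. Waterfall SPP with the flow pool set
(4, 6, 8, 10) is geometrically infeasible when chained on raw pooled
maps (65 → 16 → 2, and 2 < 8), so the builder validates geometry at
assembly time and rejects such configurations rather than clamping; the
`WSPP` preset instead chains each branch from the previous branch's
*resized* output (`chain_resized=True`), the only feasible reading of a
four-stage pooled waterfall at this resolution. Waterfall ASPP needs no
such care: same-padded atrous convolutions preserve spatial size at
every rate.

Numerical conventions: bilinear resize uses half-pixel centers without
corner alignment and is implemented as two explicit linear maps, so its
backward pass is the exact transpose; average pooling is
non-overlapping (stride = kernel) with floor truncation; weights are
He-uniform with zero biases, drawn from the model seed; all tensors are
channels-first float32.

## Training and evaluation protocol

Leave-one-subject-out: one fold per subject (lexicographic order), all
of that subject's samples held out, the rest trained on. Per fold a
fresh model is initialized with seed = global seed + fold index (no
warm-start leakage), and inputs are standardized per channel with
statistics from that fold's training portion only. The optimizer is
Adam on categorical cross-entropy; defaults are learning rate 1e-4 and
batch size 32. Epochs default to 50 with no early stopping — the epoch
budget is exposed because no canonical value exists for it. Headline
metrics are computed on predictions pooled across folds; per-fold
reports are retained. Macro-averaged F1 is the headline aggregate
(matching the community's unweighted-F1 convention) and micro-averaged
values are always reported alongside, since published tables rarely
state which rule they used. A 0/0 precision, recall or F1 resolves to 0
with a warning.

## Synthetic data generator

The generator emulates the structure of onset→apex flow fields, not
their photometric realism: each class has a fixed template of 2–3
Gaussian displacement blobs on a schematic face (positive: bilateral
mouth-corner loci with outward vectors; negative: central brow plus
mouth loci with inward vectors; surprise: brow loci with upward vectors
plus a jaw-drop locus). Each subject draws one scale factor from
`subject_scale_range`, fixed for all its samples; blob radius and peak
displacement scale linearly with it. This reproduces the
subject-anatomy-driven multi-scale challenge that motivates the
architecture family. Small center/amplitude jitter and per-pixel
Gaussian noise (default σ = 0.05) keep the task non-trivial;
displacement components live in [−1, 1] before noise. Default
conditions are 10 subjects × 12 samples with scale range (0.6, 1.6);
`emulate_combined_profile()` instead mirrors the combined three-corpus
benchmark (74 subjects; class mix (109, 250, 82)/441).

What the generator does **not** emulate: facial appearance and
identity texture, head-pose and illumination nuisance motion,
apex-annotation noise, and the long-tailed intra-class diversity of
real corpora. Tests passing on synthetic data therefore demonstrate
that the architectures, gradients and protocol are correct and that
the networks can exploit multi-scale structure — not that real-corpus
accuracy figures are reproduced.

## Desk-scale configuration

Full-scale networks (~10⁷ parameters) are impractical to train inside
a CPU-only test run, so every channel and dense width scales by a
`width` multiplier (floors of 4 channels / 16 units; `width=1` is the
full model, and spatial geometry — hence the shape chain — is
width-invariant). The package's standard desk-scale study uses width
1/32 (≈ 2.5 × 10⁴ parameters), learning rate 1e-3, batch 16 and 8
epochs: the larger step size suits the small parameter count, and
training converges within a few epochs on the synthetic task. Under
these conditions the waterfall-ASPP preset exceeds 0.70 pooled LOSO
accuracy while label-shuffled controls remain at chance (1/3 ± 0.08);
both properties are asserted in the test suite.

## Known limitations and open choices

* Published parameter totals for this model family (~8.1–8.4 M) cannot
  be reconciled with the layer table above (FC1 alone holds
  512·8·8·128 ≈ 4.2 M weights); the package therefore asserts the
  relative properties (direct SPP = direct ASPP; base < every variant)
  and makes no claim about absolute counts. By the same construction
  our two waterfall presets also count equally, although published
  totals for them differ.
* The branch convolution size and branch width are not fixed by the
  source material; 3 × 3 and 64 filters are the package's choices.
* Whether the four flow networks sit after Conv1 or Conv2 is not
  printed; `after_conv2` (the stronger placement in the grid
  experiments) is the default, and both are configurable.
* Real-corpus ingestion is manifest-driven only; corpora lacking apex
  annotations should record their frame-selection strategy in the
  manifest's `frame_strategy` column. The dense-flow preprocessor uses
  the iterative Lucas–Kanade solver with parameters recorded in
  `wasppnet.io.FLOW_ALGORITHM`.
* Eval-mode outputs are batch-size invariant up to float32 BLAS
  accumulation order (≤ 1e-5), not bit-identical.
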