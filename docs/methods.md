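# Methods

`spikedet` implements a family of lightweight anchor-based detectors for
wheat spikes — the grain-bearing heads whose count per unit area drives
yield estimates — together with the evaluation and model-selection
machinery needed to compare family members, and a synthetic scene
generator that lets the whole pipeline run and be tested without any
field imagery.

## Detector architecture

**Backbone.** A ShuffleNetV2-style extractor: a 3×3 stride-2 stem to 24
channels followed by a 2×2 max pool, then three stages of channel-split
units (widths 48/96/192, repeats 4/8/4 by default). Each unit splits its
channels in half, passes one half through a 1×1 → depthwise 3×3 → 1×1
stack, concatenates, and applies the channel-shuffle permutation; stage
entries use a stride-2 twin-branch unit. Two feature taps feed the head:
the stride-16 output of the second ("transition") stage and the stride-32
output of the third ("output") stage. The default input is a 352×352 RGB
frame; any square size divisible by 32 works, and the smoke benchmark uses
160 px (see *Problem sizes* below).

**Attention insertion.** Two optional insertion points: after the
foundation stage (stem + first stage; variant suffix `1`) and after the
output stage (suffix `2`). Three operators are available, all
shape-preserving multiplicative gates, so insertion never changes tap
shapes:

* **ECA** — global average pooling to a per-channel descriptor, a 1-D
  convolution across channels whose kernel size adapts to the channel
  count (nearest odd value of |log₂C + b|/γ with γ=2, b=1: 3 taps at 64
  channels, 5 at 256), then a sigmoid gate. Adds only the k kernel
  weights.
* **LSKA** — a large k×k depthwise kernel (default k=23) decomposed into
  cascaded 1-D depthwise convolutions: a dense (2d−1)-tap horizontal +
  vertical pair, then a dilated pair of m taps with dilation d (default
  d=3) chosen so (2d−1) + (m−1)d = k, closed by a 1×1 mixing convolution.
  Parameter cost grows linearly in k (≈2k + 2(2d−1) per channel plus the
  1×1) instead of quadratically.
* **EMA** — channels fold into g groups (default 8) treated as batch
  entries; a 1×1 branch gates each group by sigmoid-activated height- and
  width-wise pooled descriptors followed by a group norm, a 3×3 branch
  adds local context, and the two branches exchange information through
  softmax-normalised globally pooled descriptors multiplied against the
  other branch's flattened map, yielding a sigmoid spatial gate.

**Head.** Two detection scales (stride 16 and 32). The deep tap enters a
1×1 block; its ×2 nearest-neighbour upsampling is concatenated with the
mid tap and mixed by another 1×1 block; each scale then runs a depthwise
5×5 + pointwise 1×1 stack. Three 1×1 branches per scale produce box
offsets (4 per anchor), objectness (1 per anchor) and class logits — the
class convolution is one module applied at both scales (shared storage).
`fpn_kind="simlight"` builds every block in the fusion path as a
**SimConv**: conv + batch norm + ReLU with an exact inference-time folding
of the batch norm into the convolution (w′ = wγ/√(σ²+ε),
b′ = β + (b−μ)γ/√(σ²+ε)), so the fused path computes ReLU(conv′(x))
only. Folding is algebraically exact; in float32 the two evaluation orders
agree to ≈10⁻⁵ relative, and the equivalence test draws float64 inputs so
the 10⁻⁵ absolute tolerance is meaningful at any magnitude.

**Decode.** Per cell and anchor: center = (cell + 2σ(t) − 0.5)·stride,
size = anchor·(2σ(t))² (bounded in (0, 4·anchor)), score =
σ(obj)·σ(cls); boxes below the confidence threshold are dropped and
survivors are clipped to the frame, then greedily NMS-suppressed.
The power-form decode was chosen over an exponential decode because the
matching training-time assignment gates anchors at a finite ratio, and the
bounded form cannot diverge.

## Training (harness)

No training recipe is published for this detector family, so the
harness's choices are its own and are fully config-exposed:

* **Assignment** — a ground truth is assigned, per scale, to every anchor
  whose width and height ratios to the box lie strictly inside [1/4, 4],
  in the center cell plus the two nearest neighbour cells (the cross-cell
  reach matches the decode's (−0.5, 1.5) center range).
* **Loss** — box: mean (1 − CIoU) over positives (CIoU = IoU − center
  distance over enclosing-diagonal² − aspect-ratio penalty); objectness:
  BCE over every cell/anchor against labels equal to the clipped,
  detached predicted IoU at positives and 0 elsewhere; class: BCE at
  positives. Default weights 0.5 / 1.0 / 0.5. A box weight an order of
  magnitude smaller (as common in GPU-scale recipes with 10⁵ steps) leaves
  localization under-trained within this package's short CPU budgets, so
  the default favours the box term.
* **Optimisation** — Adam, lr 8·10⁻³ with 20 warmup steps and cosine decay
  to 10% of peak, batch 8, 30 epochs. All randomness (scene seeds, shuffle
  order, weight init) derives from explicit seeds; runs are bit-reproducible
  on one machine.
* **Anchors** — defaults come from plain k-means over the synthetic box
  distribution (`kmeans_anchors`), sorted by area and split across the two
  scales; any six (w, h) pairs can be supplied in the head config.

The numerical engine behind all of this is a small reverse-mode autodiff
library on numpy (`spikedet.nn`): float32 tensors (float64 preserved when
given), grouped/dilated im2col convolution, batch/group norm, 2×2 max
pool, nearest upsampling, and Adam/SGD. Parameter counts are exact sums of
trainable scalars; MAC counts come from a counter armed during a real
forward pass, so they reflect the executed graph rather than a static
table.

## Evaluation

Single-class protocol. Detections are matched greedily in descending
confidence to the highest-IoU unmatched ground truth of the same class
(ties on IoU break by ground-truth index). Precision = TP/(TP+FP) and
recall = TP/n_gt accumulate down the score-sorted list; AP is the area
under the monotone precision envelope over all recall steps
(all-points interpolation — an 11-point variant is available behind a
flag); F1 = 2PR/(P+R). mAP@0.5 averages AP over classes at IoU 0.5
(equal to AP here); mAP@.5:.95 averages over the ten thresholds
0.50, 0.55, …, 0.95. Results are percentages; a split with no ground
truths yields a defined all-zero result with a warning record instead of
an exception, to keep batch evaluation total. The operating P/R point is
reported at a configurable confidence (default 0.25); published P/R
tables for this detector family used an unstated threshold, so their
reproduction is not claimed.

## Composite ranking (GPI)

Given one row per model — mAP@0.5, mAP@.5:.95 (percent), GFLOPs, params
(millions) — each column is min-max normalized to [0, 1] over the model
set and aggregated with weights 0.7, 0.2, −0.05, −0.05. A model at the
column minimum everywhere scores exactly 0; the best attainable score is
0.9. Scores are kept at full precision and rounded to 2 d.p. only for
display; ranking uses the unrounded values (display ties are therefore
resolved), with exact ties broken by fewer parameters, then name order.

The published formula for this index describes subtracting column
*medians* from the raw metrics. Applied literally, that arithmetic does
not reproduce the published score column (the all-minimum baseline would
score ≈ −2.9, not 0.00), while min-max normalization reproduces all 14
scores and the printed rank order exactly, including the unrounded
separation of the two 0.84 entries. `minmax` is therefore the default
mode; a literal `median` mode ships for comparison. Which form the
original authors intended cannot be settled from the text alone — both
are provided and documented rather than silently merged.

## Synthetic scenes

The generator emulates the statistical features that make wheat-spike
detection hard — many small elongated objects, partial occlusion, mixed
maturity colouring, variable illumination — not the visual appearance of
real fields. A scene is a smoothed low-frequency colour field plus pixel
grain (soil/canopy), onto which ellipses are painted with orientation,
semi-axes and a green-to-gold palette colour drawn per spike; awn-like
brightness stripes run along the major axis; the whole frame is scaled by
a per-scene illumination gain and a mild directional gradient. Placement
respects an overlap cap (`occlusion_fraction`); when a requested density
cannot be placed, the scene carries fewer spikes and a warning, never an
exception. The default density (mean ≈ 43 spikes per 352-px frame,
negative-binomial with dispersion 20) mirrors the per-image box density of
the real public wheat corpora whose summary statistics ship in
`spikedet/data/wheat_corpus_stats.json`; the `EASY_PRESET` (5 large,
unoccluded spikes at 160 px) defines the regime of the pipeline benchmark.

Because the generator is parametric and texture-free at the object level,
passing tests demonstrate that the pipeline (rendering → assignment →
optimisation → decode → metrics) is wired correctly and can learn this
controlled distribution; they say nothing about accuracy on real field
photographs, which vary in ways the generator does not model (genotype,
blur, canopy structure, sensor differences).

**Splits.** The 8:1:1 partition uses floors for train and validation and
gives the remainder to test — the unique rule that maps 11,451 items to
the canonical 9,160/1,145/1,146 — over a seeded shuffle.

## Problem sizes

The pipeline benchmark (`run_smoke_benchmark`; the `spikedet generate`
and `spikedet train` shell commands expose the same machinery piecewise)
uses 200 easy scenes at 160 px, 30 epochs, batch 8 —
about 750 optimiser steps, a few minutes on one CPU core — and reaches
held-out mAP@0.5 ≈ 95% against a 50% functional floor. Structural tests
use thinner backbones (stage widths 16/32/64, repeats 2/2/2) because
every structural property under test (stride arithmetic, shape
preservation, permutation invariants) is width-independent.

## Known limitations

* No GPU path and no mixed precision; throughput is numpy-bound.
* Two detection scales only; objects far outside the anchor range
  (ratio ≥ 4) are invisible to training by design.
* The evaluator's operating P/R depends on the configurable confidence
  threshold; only AP/mAP are threshold-free.
* Checkpoints are `.npz` weight containers tied to the config that built
  the model; no cross-version migration is attempted.
* Scene realism is deliberately statistical, not photometric (see above).
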