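# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical and design choices made where the design was genuinely
open.

## Detector architecture

The baseline detector is the standard *n*-scale one-stage layout: a 3×3/2
stem (16 channels), four downsampling stages with C2f blocks (widths
32/64/128/256 after the 0.25 width multiple, repeats 1/2/2/1 after the 0.33
depth multiple), SPPF (kernel 5) closing the backbone, a top-down plus
bottom-up feature-pyramid neck with four C2f blocks, and a decoupled
anchor-free head at strides 8/16/32. The head's box branch predicts
`4 × reg_max` logits per location (`reg_max = 16` distance bins per side,
hidden width `max(16, w/4, 4·reg_max) = 64`), the class branch `nc = 4`
logits (hidden width 64). Every convolution is conv + batch norm
(eps 1e-3, momentum 0.03) + SiLU. At these settings the assembled baseline
has 3,011,612 trainable parameters.

### Lightweight bottlenecks

The three variants replace the C2f bottleneck (two 3×3 convolutions plus
residual) with lighter constructions, keeping the C2f dataflow
(split → n bottlenecks, all intermediates concatenated → fusing 1×1):

* **GC-BottleNeck** (GNCA; backbone of GSCA): Ghost module → channel
  attention → Ghost module, with the residual kept. A Ghost module's
  pointwise "intrinsic" convolution produces `ceil(c/ratio)` channels
  (ratio 2) and cheap depthwise 3×3 ops produce the rest.
* **SC-BottleNeck** (SNCA; neck of GSCA): GSConv → channel attention →
  GSConv. A GSConv produces half its output with a dense convolution and
  half with a 5×5 depthwise convolution on that dense half, then interleaves
  the halves with a perfect channel shuffle. The first GSConv in the
  bottleneck keeps the 3×3 dense kernel of the convolution it replaces; the
  second is pointwise. The 5×5 depthwise kernel is the original GSConv
  construction, and it is also what reproduces the published sizes of these
  variants; a 3×3 depthwise kernel lands about 0.03 M parameters short.

Channel attention inside the bottleneck is squeeze-excitation gating with
reduction 2 — the hidden widths are small (16–128 channels), so the usual
reduction 16 would collapse them to 1–8 gate units. The named variants add
CBAM (reduction 16: shared avg/max-pooled MLP channel gate, then a 7×7
spatial gate) on the concatenated features entering each of the four neck
C2f blocks; applying attention at the fusion point is both a natural reading
of "attention in the feature pyramid" and the placement consistent with the
parameter increments the attention ablation implies. `se`, `ca` (channel
attention) and embedded-Gaussian `nonlocal` blocks are available behind the
same interface.

Resulting sizes (nc = 4): GNCA 2,226,184; SNCA 2,446,088; GSCA 2,333,192 —
each within 1 % of the corresponding published count, and in the same
order (GNCA < GSCA < SNCA < baseline).

## Numerical engine

No deep-learning framework is used: `goatvision.nn` is a tape-based
reverse-mode autodiff engine on numpy arrays providing exactly the operators
the detector needs (grouped convolution via patch extraction and batched
matmul, batch norm with gradients through the batch statistics, max pooling,
nearest upsampling, softmax/log-softmax, reductions, gathers) plus Adam with
L2 weight decay. Gradients of every operator are verified against central
finite differences in the test suite, and the convolution forward against
scipy's correlation.

## Letterboxing, decoding, NMS

Inference letterboxes the frame aspect-preservingly onto a square canvas
(gray value 114), so a 1280×720 frame becomes 640×360 content with 140-px
bands. Box decode is the expected-bin-value convention: softmax over the 16
bins per side, expectation × stride = distance from the anchor center.
Detections are filtered at the confidence threshold (default 0.001, the
evaluation protocol) and pruned with class-wise greedy NMS at IoU 0.5, ties
broken by lower box index; the survivors are mapped back to source
coordinates. mAP is computed per class by confidence-ordered greedy matching
at IoU ≥ 0.5 (each truth matched once) with 101-point interpolation of the
PR curve; classes absent from the ground truth are excluded from the mean
with a warning.

## Losses

The regression family shares one geometry: IoU; squared center gap ρ² over
squared enclosing-box diagonal c²; aspect term
v = (4/π²)(atan(w_t/h_t) − atan(w_p/h_p))² with trade-off
α_c = v/((1−IoU)+v) treated as a constant during backprop (the standard
practice). EIoU replaces the aspect term with width/height gap terms over
the enclosing box's width/height; SIoU follows the original angle / distance
/ shape decomposition (the angle cost is computed as 2x√(1−x²), avoiding an
arcsine); Alpha-CIoU raises each CIoU term to the power a (default 3, the
published default). All are zero at coincidence up to the ε = 1e-9
regularizers (≤ 1e-8 in practice) and invariant to joint translation and
scaling. The distribution regression loss is cross-entropy against the two
integer bins bracketing the continuous target distance; classification is
mean binary cross-entropy with logits. Component weights default to
box 7.5 / dfl 1.5 / cls 0.5, the detector family's convention.

Degenerate (zero-area) boxes get IoU 0 with a warning; targets outside the
bin range are clamped with a warning; for fractional Alpha-CIoU exponents
(a < 1) the aspect product is floored at ε to keep the power differentiable,
which introduces an ε^a floor in the loss value.

## Training (smoke scale)

`fit_smoke` demonstrates end-to-end optimization, not farm accuracy: a fixed
batch of ≥ 8 annotated synthetic images letterboxed to a 64×64 canvas,
Adam (lr 1e-3, weight decay 1e-5), Mixup (probability 0.5 per image,
λ ~ Beta(0.2, 0.2), pixel blend with label union), and a task-aligned top-k
assigner (candidates are anchors whose center lies inside the truth box,
ranked by score^0.5 · IoU^6, k = 10; conflicts go to the best-aligned box).
200 steps take on the order of a minute on one CPU; on the 10-image fixture
the total loss falls from ≈ 12 to ≈ 4 and training-fixture mAP rises from
0 to ≈ 0.9. The 64×64 canvas and 10-image fixture are the package's chosen
smoke scale: large enough that the ~30-px goat blobs span several stride-8
anchors, small enough to iterate quickly.

## Night enhancement

CLAHE is implemented directly (no installed library exposes the standard
clip-limit dialect): per-tile 256-bin histograms on a 16×16 grid (edge
padding to full tiles), clipping at `clip_limit × tile_pixels / 256` counts
with uniform redistribution of the excess, CDF mappings scaled to [0, 255],
and bilinear blending between the four surrounding tile mappings. Color
images are processed on the BT.601 luminance only, applying the luminance
gain to all channels (avoids hue shifts); a per-channel mode exists behind a
flag. A flat image stays flat, but its level moves to the histogram's CDF
position — the standard behavior of this construction.

The two quality metrics are discrete entropy (Shannon entropy of the
gray-level histogram, bits, ≤ 8 for 8-bit images) and EBCM, the edge-based
contrast measure: the mean over interior pixels of |x − e|/(x + e), where e
is the 8-neighborhood mean weighted by Sobel gradient magnitudes (0 where
the denominator vanishes). EBCM's ratio form makes it invariant to positive
rescaling before quantization. The paired study computes both metrics before
and after CLAHE and tests the increase with a one-sided Wilcoxon signed-rank
test (deltas are not assumed normal); all-zero deltas report p = 1.

## Synthetic scenes and video

The generator emulates the geometry of overhead pen footage at a fixed 60
px/m: textured ground, a trough strip along the top edge, a water point in
the bottom-right corner, and one oriented ellipse cluster per goat whose
pose encodes the class — lying is a low-aspect blob; standing adds a head
disk and a cast shadow; eating is a standing pose placed against the trough
with the head inside it; drinking likewise at the water point. Stocking
density sets the minimum center spacing (√(2 m²)·60 px at high density,
√(3 m²)·60 at low), relaxed by the occlusion level; placement is rejection
sampling (300 tries per goat, conceding half the spacing after 150) and
raises a placement error when the pen genuinely cannot hold the request.
Later goats are drawn over earlier ones; ground-truth boxes default to full
(amodal) extents, with a visible-extent option. The default class mix is the
annotated farm data's label proportions (lying 0.524, standing 0.341,
drinking 0.013, eating 0.121). Night lighting applies gamma compression
(γ = 2.2) plus Gaussian sensor noise (σ = 3), which darkens frames and — at
σ = 0 — provably cannot increase discrete entropy.

Video generation keeps a per-goat state; each second every goat switches
behavior with the configured probability (resampling class and a compatible
position), and the per-second ground-truth record stream is derived from the
state, so class counts always sum to the herd size.

What this emulates: geometry, counting, occlusion ordering, class placement
zones, day/night statistics. What it does not: goat appearance and gait,
camera distortion, real shadows and bedding clutter, inter-frame motion
blur. Tests passing on these scenes therefore validate bookkeeping,
geometry, optimization and statistics — not recognition accuracy on real
footage, which requires the original farm data.

## Monitoring pipeline

"One record per second" is implemented as one representative frame per
second — the first frame whose timestamp falls in that second; counts within
a second are not averaged. Records persist as CSV with the fixed column
order Date,Time,Standing,Drinking,LyingDown,Feeding. Time budgets are
Σ count × period per behavior (goat-seconds). Budget comparison reports
100·(system − manual)/manual per behavior plus the pooled feeding+standing
difference, the reconciliation check for goats that stand at the trough
without eating; behaviors with zero manual time are reported as undefined
rather than a number. The operation modes map fast → SNCA,
balanced → GNCA, precise → GSCA. Frame sources are ordered image
directories or multi-frame image files; timestamps are frame index / fps,
and the first sampled frame is index 0.

## File-format conventions

Boxes are stored internally as 0-based, half-open float intervals. VOC XML
is written with 1-based inclusive integer corners and read back with the
inverse mapping, so a write/read round-trip moves a coordinate by at most
0.5 px (the tolerance also absorbs annotation tools that disagree on 0- vs
1-based corners). YOLO lines are `class_index cx cy w h` normalized to
[0, 1]. Class names are normalized case-insensitively over the common
spelling variants ("lying down", "standing", "feeding"/"eating").

## Known limitations

* Trained accuracy claims are out of reach by design: the smoke trainer
  shows the objective optimizes, nothing more.
* The numpy engine is single-device and eager; it is sized for desk-scale
  inputs (640-px inference, 64-px training), not throughput.
* Video codecs (MP4/AVI) are not read; monitoring runs on frame directories
  or multi-frame image files.
* Non-local attention materializes an L×L affinity (L = positions per neck
  level), so it is practical only at small input sizes.
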