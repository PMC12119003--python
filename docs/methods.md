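# Methods

## Problem and scope

`lesiondet` implements, at desk scale, a lightweight single-stage detector
family for plant-lesion detection: a YOLOv8n-style baseline (anchor-free,
decoupled head, CSP backbone, PAN neck) extended with three bespoke blocks —
a median-enhanced channel/spatial attention module (MECS), a softmax-gated
two-stream fusion module (BFM), and a GSConv-based lightweight CSP block
(GSC2f). The package's verifiable claims are architectural (parameter and
FLOP budgets, block-level algebraic invariants, metric definitions) plus a
seeded overfit demonstration; it does not attempt to reproduce detection
accuracy on external field imagery, which requires long GPU training on data
that is not redistributable.

Everything runs on a small reverse-mode autodiff core over numpy
(`lesiondet.nn`): tensor ops with custom backward rules for convolution
(im2col/col2im), max pooling (argmax routing) and global median pooling
(gradient split across the middle order statistics). This keeps the package
self-contained and the numerics inspectable; the cost is speed, which the
desk-scale defaults below are chosen around.

## Blocks

**GSConv / GSBottleneck / GSC2f.** GSConv computes half its output channels
with a dense convolution and derives the other half with a depthwise pass
over the first, then interleaves the two groups with the deterministic
reshape-(2, C/2)-transpose-flatten channel shuffle. Its cost is roughly half
a dense convolution's. GSBottleneck chains GSConv(C→C/2, 3×3) and
GSConv(C/2→C, 3×3) with an identity shortcut when shapes match — the layout
is our choice (the source architecture does not dimension it); we picked the
channel-halving form because it is channel-preserving, residual-friendly,
and genuinely light. GSC2f keeps the C2f topology (1×1 projection to 2c,
split, n sequential bottlenecks on one half, concat of all intermediates,
final 1×1 projection) with two substitutions: GSBottleneck for the dense
bottleneck and a 1×1 GSConv for the input projection. GSC2f replaces the
neck C2f blocks only; the backbone keeps standard C2f.

Note one bookkeeping subtlety: increasing n grows the final projection's
input by one c-wide slab, so the parameter delta per extra stage is one
GSBottleneck *plus* that projection growth (the tests pin the exact
decomposition).

`complexity_bounds` reproduces the published closed-form complexity triple
for SC/DSC/GSConv verbatim, including its idiosyncrasies (the SC term omits
K_w, the GSConv term omits C2); it is an ordering indicator, not a FLOP
count — the profiler owns FLOPs.

**MECS.** Channel stage: global average, max and median pooling (median of
all H·W values per channel; even counts average the two middle values — our
convention, the source is silent), one shared bottleneck MLP (1×1 conv
C→C/r, ReLU, 1×1 conv r→C), a sigmoid per branch, and the three sigmoided
branches *summed* — the gate therefore lies strictly in (0, 3). We follow
the printed sum-of-sigmoids even though CBAM-style blocks sum pre-sigmoid;
with the median branch and spatial stage disabled the block degrades to a
CBAM-style gate in (0, 2), which the tests use as a structural check that
the median branch is wired. Spatial stage: a 5×5 depthwise base conv, n = 3
separable strip branches (1×7→7×1, 1×11→11×1, 1×21→21×1; the source names
"1×11, 1×7, and others"), elementwise sum of base and branch outputs, a 1×1
projection, and multiplication onto the channel-gated features. The
projection has no squashing nonlinearity (as printed), which makes the block
quadratic in its input; we initialize it transparent (zero weights, unit
bias) so stacked untrained blocks do not compound activation magnitude —
training moves it freely.

**BFM.** Fuses two same-shape streams. Each input passes a *shared*
multi-scale extractor (3×3, 5×5, 7×7 depthwise-separable convolutions,
summed). Channel logits: four global statistics per channel (avg, max,
population std, min) → 1×1 conv 4C→C → ReLU → two-grouped 1×1 conv C→C.
Spatial logits: the same four statistics pooled across channels → 7×7 conv
4→16 → ReLU → 7×7 conv 16→1. Both logit pairs are softmax-normalized across
the *input* axis, so channel weights sum to 1 per channel and spatial
weights to 1 per pixel; the fused output is w_c1·w_s1·t1 + w_c2·w_s2·t2.
Sharing every weight path across the two inputs is what makes the symmetry
exact: swapping inputs swaps weights, identical inputs get ½ everywhere, and
the output is bounded elementwise by max(|t1|, |t2|). In this single-image
detector the two streams at each neck fusion node are the top-down
(upsampled or downsampled, width-matched by a 1×1 lateral or a widened 3×3/2
downsample conv) feature and the lateral feature; BFM replaces all four
concat nodes.

## Budget pinning

Several widths are not dimensioned in the source architecture; following its
ablation table we pinned them against the printed Params/GFLOPs budgets
(all counts exact, FLOPs by the `2HW(Cin·K²+1)·Cout + (2I−1)·O` convention
at 640×640; normalization/activation layers cost zero FLOPs; depthwise
convs count Cin = 1 per group; shared layers are charged once per
application; tables round half-up to one decimal):

* MECS reduction r = 4, insertions after the stem, all four backbone stage
  outputs, and the SPPF (six blocks) → 3.327 M / 9.175 G ("+MECS" budget
  3.3 / 9.2).
* BFM channel/spatial path widths as above → 3.994 M / 10.084 G ("+BFM"
  budget 4.0 / 10.1).
* Baseline: 3,013,757 parameters (3.0 M) and 8.13 G. The printed baseline
  pair (3.0 M, 8.6 G) is internally inconsistent — a 15-class head that
  yields 3.0 M parameters yields ~8.1 G under any standard convention — so
  the FLOPs row cannot be matched while the parameter row is.
* The ablation table is not additive: the published standalone GSC2f delta
  (−0.9 G / −0.4 M) and its near-zero delta in combination rows cannot both
  arise from one architecture whose flags toggle fixed modules. We kept
  GSC2f light (its scientific point); the MECS+GSC2f variant lands at
  2.89 M / 8.24 G (printed 2.9 / 8.3) and the full model at 3.91 M / 10.33 G
  (printed 4.1 / 10.9). The mismatches are reported, not tuned away.

## Synthetic scenes

The generator emulates the statistics the detector is meant for: 640×640
default canvases (tests use 64–160 px), leaf-textured backgrounds built from
layered low-frequency noise, soil/weed clutter ellipses controlled by
`clutter_level`, a global brightness factor (±35%), Poisson-distributed
lesion counts (mean 2, truncated at 8), ~15 classes drawn with imbalanced
weights ramping 300→800 image-equivalents, and box areas uniform on
[200, 8000] px² with a 5% over-8000 tail. Lesions render as superellipse
blobs inscribed in their sampled box (so the tight box equals the sampled
box by construction) with a class-specific hue and speckle/ring texture.
Everything derives from one `numpy` generator seeded per scene, so scenes
are byte-reproducible.

What this does *not* emulate: real lesion morphology and co-occurrence,
leaf venation and specular lighting, camera noise, inter-class visual
similarity structure, or the long-tailed instance counts of field data.
Passing tests therefore certify the pipeline's mechanics (geometry, I/O,
metric arithmetic, optimization), not field accuracy.

Splits use floor(0.7n)/floor(0.2n)/remainder under a seeded permutation,
which reproduces the published 4088/1168/585 partition of 5841 images.

## Training harness

Loss = 0.5·BCE(class logits) + 7.5·CIoU(decoded boxes) + 1.5·DFL(distance
distributions), the family-standard composition. Positives come from a
simplified task-aligned assigner: candidate cells have their center inside
a ground-truth box (any scale), are ranked by cls^0.5 · IoU^6 against the
current predictions, and the top 10 per ground truth are kept (ties to the
higher score; a ground truth with no interior cell falls back to its
nearest cell so nothing goes unsupervised). Boxes decode from the
expectation of the softmaxed 16-bin distance distribution per side, scaled
by stride; inference applies per-class greedy NMS at IoU 0.45 and
confidence 0.25 (our defaults; the source is silent on inference
thresholds).

Reference defaults follow the published recipe — 300 epochs, batch 16, SGD
at lr 1e-4, 640 px, training from scratch. The test suite exercises a
seeded desk-scale profile instead: 8 synthetic 64 px scenes, full-batch SGD
at lr 0.02 (the printed 1e-4 is far too small to move a from-scratch model
in 120 steps), 120 iterations. Under that profile the total loss falls to
well under half its initial value and train-set mAP50 rises from 0.0
(untrained) to ~0.7. Problem sizes throughout the tests (64–160 px scenes,
≤1000 generator draws, single profiling passes at 640) are the package's
desk-scale choices.

## Numerical conventions and edge cases

* Precision/recall with an empty denominator are defined as 1.0.
* AP uses 101-point interpolation of the precision envelope (an all-point
  variant is exposed); classes with no ground truth are excluded from mAP.
* Confusion-matrix matching is class-agnostic so cross-class confusions
  appear off-diagonal; rows are predictions (+background), columns truth.
* Population (divide-by-N) convention for std pooling, computed two-pass to
  avoid cancellation on constant inputs.
* Channel shuffle requires g | C and is inverted by shuffling with C/g.
* Even-count medians average the two middle values; the gradient splits
  half-and-half between them.
* BatchNorm uses batch statistics in training and running estimates in
  eval (momentum 0.03, eps 1e-3).
* Checkpoints are single-file `.npz` archives carrying the variant
  metadata next to the weights.

## Known limitations

Pure-numpy training is slow (roughly 1 s per iteration at 64 px, batch 8,
one core), so the harness is for verification and small experiments, not
production training. Eval-mode forward passes of untrained models rely on
the transparent attention initialization for numerical stability. The
assigner is a simplification of full task-aligned assignment (no
soft-label targets). FPS/latency is out of scope.
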