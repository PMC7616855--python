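# Methods

`erfscope` probes *where* a convolutional classifier's evidence comes from:
from local appearance statistics, or from the spatial arrangement of parts.
It does so with three instruments — effective-receptive-field (ERF) control,
spatial feature scrambling, and minimal-recognizable-configuration (MIRC)
search — plus representational similarity analysis (RSA) to compare what
different architectures learn.

## Architectures and receptive-field arithmetic

The architecture family is a bottleneck residual network: a 3×3 stride-1
stem, then four blocks of 2/3/3/2 residual units with unit output widths
128/256/512/1024 and block strides 2/2/2/1.  Each unit is
1×1 → k×k → 1×1 with the k×k layer at a quarter of the unit's output width
and an identity shortcut (a strided 1×1 projection where stride or width
change).  Only the middle kernels k vary between variants; the five
canonical configurations give last-convolutional-layer ERFs of 11, 23, 47,
95 and 227 pixels at any input size.

The ERF is computed by standard receptive-field arithmetic in forward
order along the main path: `erf += (k-1)·jump; jump *= stride`, with
"same" padding everywhere so grid sizes depend on strides only.  Two
conventions are load-bearing and fixed throughout the package: the stem is
a 3×3 stride-1 convolution, and each block's stride sits on the *first
1×1* of the block's first unit (before the k×k layer).  Under these
conventions the five variants reproduce 11/23/47/95/227 exactly, and the
smallest variant composed with the aggregating follow-up network reaches
235; shortcut projections are 1×1 and never extend the field.  The
arithmetic is cross-checked in the test suite against an independent
empirical oracle: the bounding box of non-zero input-gradient support of a
centred last-layer unit in a bare (linear, unnormalized) instantiation of
the same stack, which must agree to the integer.

Unspecified conventions we fixed: batch normalization after every
convolution; ReLU activations; a 64-channel stem; He-uniform seeded
initialization; global average pooling (GAP) followed by a single dense
softmax layer as the classifier head.  None of these affects any ERF or
grid size.  A `width_multiplier` scales all widths (rounded to integers)
for width-matched controls; strongly down-scaled instantiations floor the
stem at 8 channels and the bottleneck (k×k) layers at 4, because a 1–2
channel layer is an information choke point whose usefulness depends on
initialization luck — the floors never bind at multiplier 1.0.  The
closed-form parameter count (convolution weights, batch-norm affine
pairs, classifier weights and biases) matches the built network's
enumeration exactly and supports finding a multiplier that matches the
largest variant's count to within 1%.

## The network backend

No deep-learning framework ships with the package's dependency set, so the
networks run on a compact numpy backend (`erfscope.nn`): convolution as a
sum over kernel offsets of strided-slice tensor contractions, batch
normalization with running statistics, ReLU, GAP, a dense head, softmax
cross-entropy, and SGD with classical momentum.  Forward and backward
passes are hand-written and verified against numeric differentiation in
the test suite.  Tensors are float32 NCHW.  This backend is the package's
own component, sized for desk-scale experiments (inputs ≤ 224 px, widths
scaled down by the width multiplier); it is deliberately minimal rather
than general.

## Base/follow-up composition and scrambling

A trained classifier is frozen and its head detached; the activation grid
of its last convolutional layer feeds a trainable follow-up network (four
bottleneck units + GAP + softmax).  The *aggregating* follow-up uses 3×3
middle kernels with strides (2,2,1,1) — its units integrate across the
grid, and the composed ERF covers the whole input (235 px for the smallest
base at 224).  The *pointwise* follow-up uses only 1×1 convolutions without
down-sampling; together with GAP this makes its predictions provably
invariant to any spatial permutation of its input, which the tests assert
to |Δlogit| < 1e-4.  Follow-up width defaults to the base output width;
the follow-up unit structure (stride on the first 1×1) is the same
convention as in the base blocks, which is what makes the composed ERF
come out at 235.

Scrambling permutes whole feature columns (all channels of one spatial
position move together).  *Global* scrambling draws a uniform bijection
over all positions; *local* scrambling permutes independently inside
non-overlapping square tiles (default window 2, remainder tiles at edges
permuted among themselves), so no feature moves farther than
(window−1)·jump input pixels.  "Neighboring locations" is not otherwise
defined; non-overlapping tiles are the minimal-displacement reading and
keep the map a bijection.  At training time a single fixed permutation is
used for every step; at test time a fresh permutation is drawn per image
from a seeded stream and results are averaged — the redraw policy is a
package choice, made so that test-time variance is averaged out rather
than frozen into one draw.

## Training protocol

SGD with momentum 0.9, initial learning rate 0.01 (configurable), constant
for the first 10 epochs, then per-epoch exponential decay (default factor
0.94/epoch — the decay rate, batch size and weight decay are free
parameters with conservative defaults).  The full-size image pipeline
crops the central square, resizes to 256², randomly flips and randomly
crops 224² during training; evaluation resizes and takes the central 224²
crop deterministically.  Desk-scale synthetic images (64²) are fed at
native size; the augmentation analog is a random integer translation of up
to ±4 px per batch (zero-filled), standing in for random cropping.
Composed models update only the follow-up; the tests assert that base
weights are bit-identical before and after composed training.

Per-class evaluation is one-vs-rest precision/recall/F1 from top-1
predictions.  The scrambling ratio of a class is F1-after / F1-before,
computed only for classes with F1-before > 0.75; a class whose F1
collapses to zero has ratio 0.  Classes are ranked ascending by ratio
(most scrambling-sensitive first), and rankings across models are compared
by top-k intersection counts.

## RSA

A layer's representational dissimilarity matrix (RDM) holds
1 − Pearson(activation_i, activation_j) over stimuli, with spatial grids
flattened per stimulus.  Twelve layers are analysed per model: each of the
10 residual-unit outputs, GAP, and softmax; across the five variants this
yields 60 layer RDMs and a 60×60 second-order RDM of correlation distances
between vectorized upper triangles.  Agreement between two RDMs is R², the
squared Pearson correlation of upper triangles (Spearman would be a
defensible alternative; Pearson is fixed here).  Metric
(stress-minimizing) MDS with classical-MDS initialization embeds the
second-order RDM for visualization.  RDMs from repeated training runs are
averaged element-wise, which preserves symmetry, zero diagonal and range.
The class-conditioned sensitivity contrast resamples images per condition
(default 20 images × up to 20 classes, 100 repetitions), computes
R²(small-ERF model vs. large) per condition and reports the distribution
of differences.

## MIRC search

From a correctly classified image, four descendants are carved per patch —
75% of height and width, anchored at the four corners (floor rounding,
clamped to ≥ 1 px) — upsampled bilinearly to the model input size, and
re-classified (top-1, no probability threshold).  Correct patches recurse;
a correct patch whose four descendants all fail is a MIRC.  Recursion is
capped at level 10 (configurable) and capped leaves are flagged
separately; a descendant identical to its parent (1-px degenerate case)
also stops.  Identical bounding boxes are evaluated once via memoization.
The per-image statistic is the deepest MIRC level; for visualization the
highest-probability MIRC among the deepest is reported.  MIRC crops can be
clustered by k-means (default k=5) on their GAP representations, reporting
per cluster the 8 nearest-to-centre members from distinct source images.
The search logic is tested against closed-form oracles ("correct iff the
patch side is at least T"), for which level and count are analytic.

## Synthetic data: what it emulates and what it does not

The generator builds the two cue regimes whose contrast the scrambling
analyses measure, at a scale where CPU training takes minutes:

* **Texture classes** are oriented sinusoidal gratings (wavelength 8 px,
  per-image random phase, Gaussian pixel noise).  Any patch of at least a
  wavelength is class-diagnostic, which makes these classes insensitive to
  spatial scrambling by construction.
* **Arrangement classes** share a single part inventory — a filled disk, a
  hollow ring, a horizontal bar and a vertical bar, each in a 14-px box —
  placed at four anchor slots on a centred square (≈26 px apart).  A class
  is a distinct *cyclic order* (necklace) of the parts around the slots,
  and each image applies a uniformly random rotation of that order.  The
  rotation randomization makes the marginal distribution of (part, slot)
  pairs identical across classes: no single location, and no bag of local
  features, carries any class information — only relations between parts
  do.  Images additionally receive a continuous global translation jitter
  (±4 px), a small continuous per-part jitter (±0.5 px) and pixel noise.

Several generator choices were calibrated so that the *unscrambled*
composed model can learn the arrangement task at all at this scale — a
precondition for any scrambling contrast to be meaningful — while keeping
the regime's defining invariants intact: the four parts are
distinguishable by coarse, phase-robust local statistics (fill fraction,
hollowness, orientation energy) rather than fine stroke geometry; glyph
edges have a soft Gaussian profile (σ = 1 px) so that feature responses
vary smoothly under sub-pixel displacement; the per-part jitter is small
and continuous; and the translation jitter is continuous rather than
integer-valued, so that no finite set of pixel-phase templates can be
memorized — in particular a follow-up trained on *fixed-scrambled*
features cannot succeed by binding phase-specific feature codes to
absolute positions.  Slot separation exceeds the smallest base ERF, so no
feature column ever sees two parts at once.

Two baseline oracles certify the cue separation on every generated
dataset: a nearest-centroid classifier on per-tile orientation-energy
(structure-tensor) statistics, which must exceed 95% on texture classes;
and a bag-of-parts classifier on template-match detection counts with
positions discarded, which must sit at chance (within a 99% binomial band)
on arrangement classes, since all classes contain the same part multiset.

What the generator does *not* emulate: natural image statistics, clutter
and occlusion, within-class part variability, more than a handful of
classes, or photometric variation.  Passing the desk-scale study shows the
pipeline measures what it claims to measure on controlled cues; it does
not certify magnitudes on natural datasets.

The sketch rendering binarizes Sobel edges (black contours on white),
removing all surface fill while preserving part layout — the contour-only
regime of line-drawing datasets.

## The desk-scale scrambling study

The study trains, per seed (3 seeds) and cue regime: the smallest-ERF base
(width multiplier 1/16, 6 epochs), an aggregating follow-up on the frozen
base, the same follow-up with a fixed global train-time scramble, and
evaluates the unscrambled model under per-image global and local
(window 2) test-time scrambling.  Four classes, 200 images per class,
80/20 train/test split.  The 64-px images are fed at 2× bilinear
upsampling (network input 128, feature grid 16×16) — the analog of the
resize-before-crop protocol used at full scale — because on the native
8×8 grid a window-2 local scramble displaces features by about a third of
the slot separation, conflating "local" with "global" disruption; at
16×16 the displacement is ~15% of the separation and the local/global
distinction is meaningful.  Follow-up training uses batch 32, learning
rate 0.02 constant for half the epochs then decayed; the arrangement
regime gets 50 epochs (the relational task is optimization-hard at this
scale) and the texture regime 20 (it converges early) — dataset-specific
epoch budgets, as at full scale.  The protocol is identical between the
scrambled and unscrambled follow-up conditions of a regime.  Directional
claims — not reference magnitudes — are asserted on seed-averaged
accuracies: global test-time scrambling sends arrangement classes to
chance while texture classes keep ≥80% of their unscrambled accuracy;
train-time scrambling restores texture classes fully and is expected to
leave arrangement recovery clearly incomplete; and local scrambling
degrades arrangement accuracy strictly less than global.  The first and
third claims hold robustly.  The second does not reproduce cleanly at
this scale: a four-unit follow-up facing only four classes can learn the
task through a *fixed* global permutation nearly as well as without it
(seed-averaged recovery ratio ≈ 0.85, with the sign varying by seed), so
the corresponding test documents an expectation this desk-scale analog
does not meet — itself an informative scale effect, since a fixed
permutation removes no information and only convolutional locality makes
it costly, a cost that evidently needs many classes or rich features to
become prohibitive.  Problem sizes keep the whole study around twenty
minutes on one CPU core.

## Numerical choices and degenerate inputs

Correlation distances are clipped to [0, 2] and symmetrized against
floating-point asymmetry; zero-variance activation vectors raise with the
stimulus named.  F1 is 0 when precision and recall are both 0.  A
scrambling window larger than the grid falls back to global with a
warning; window 1 is the identity.  k is reduced with a warning when there
are fewer MIRCs than clusters.  Checkpoints are compressed `.npz` archives
with the architecture spec embedded as JSON.  All randomness flows through
`numpy.random.default_rng` seeds carried in specs and configs; every
experiment writes a manifest (config echo, hash, seeds) beside its
results.

## Known limitations

The numpy backend is single-threaded per operation, so wall-clock scales
with problem size; the canonical full-width 224-px architectures build and
run but are not practical to *train* here.  The empirical ERF oracle uses
the linear instantiation — with ReLU, realized receptive fields are
subsets of the theoretical ERF.  The desk-scale study's absolute
accuracies depend on the tiny-network optimization budget and should be
read only through the directional contrasts; the arrangement regime in
particular sits near the edge of what a four-unit follow-up can learn from
640 training images, which is itself a finding about the sample-efficiency
of relational learning in small CNNs.
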