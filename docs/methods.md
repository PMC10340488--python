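# Methods

## Handcrafted segmentation model

The handcrafted pipeline assumes Romanowsky-type staining: leukocyte nuclei
are purple (simultaneously high CMYK Magenta and HSV Saturation), red cells
and background are pink/yellow (low on at least one of the two). Stages and
the choices behind them:

**Color constancy.** Each channel is multiplied by
`gray_mean / channel_mean`, so every channel's mean equals the grayscale
mean before clipping; this homogenizes stain and illumination differences
between acquisition setups. "Grayscale" is not uniquely defined, so we use
ITU-R BT.601 luma weights (0.299, 0.587, 0.114), configurable in
`SegConfig.grayscale_weights`. Outputs can exceed 255, so the result is
clamped to [0, 255] and rounded half-up back to uint8. A channel with zero
mean makes the weight undefined and raises an error naming the channel.

**Color channels.** CMYK has no single standard transform; we use the naive
device conversion (`K = 1 − max(r,g,b)`, `M = (1−g−K)/(1−K)`, M = 0 at
K = 1) without ICC profiles, and HSV saturation `S = (max−min)/max` (0 at
black). The Hadamard product `M ⊙ S` is the nucleus-evidence map; it is
pointwise dominated by both factors, so anything low in either channel is
suppressed.

**Bilateral filter.** Edge-preserving smoothing of the product map before
thresholding. Defaults: window 9 px, range sigma 0.1 (of the [0, 1] scale),
spatial sigma 5 px — chosen to suppress pixel noise at typical smear
magnifications without moving nucleus boundaries (the test suite checks a
step edge moves < 1 px). The borders are padded symmetrically; zero padding
would darken image edges and bias the threshold.

**Otsu threshold.** Global Otsu on the 256-bin histogram of the smoothed
map, foreground = pixels above the threshold, ties broken toward the lowest
maximizing bin. A tiled/local ("adaptive") variant is deliberately not
implemented: the pipeline contract is a single whole-image threshold. A
constant map has no two classes to separate; we return an empty mask with a
warning rather than guessing.

**Refinement.** Morphological closing with a disk (radius 3 px default),
hole filling (background components not connected to the border, using
8-connectivity throughout), then removal of components smaller than
`min_area`. The default `min_area` is relative — 0.1 % of the image's
pixels — so behavior is stable across image sizes from 120×120 to 640×480.

## U-Net and loss

The deep segmenter is a five-level encoder–decoder with skip connections:
channels (32, 64, 128, 256, 512), downsampling by strided 3×3 convolutions
(stride 1, then 2 at each deeper level; bottleneck at 1/16 resolution),
instance normalization, dropout 0.5 and Mish activations; the decoder uses
nearest-neighbor upsampling, concatenation with the encoder skip, and two
conv–norm–Mish blocks per level. The head is a 1×1 convolution with a
sigmoid: one foreground channel, so the loss's class sum runs over the
foreground and background soft counts (C = 2).

The Unified Focal Loss is
`λ·mean(δ(1−p)^e·BCE) + (1−λ)·Σ_c(1−mTI_c)^γ` with
`mTI = TP/(TP + δFN + (1−δ)FP)` on soft counts, where `p` is the predicted
probability of the true class per pixel. The focal exponent `e` is
implemented as `1−γ` (switchable to the conventional `γ` via
`LossParams.printed_exponent=False`; at the default γ = 0.5 the two
coincide). Defaults δ = 0.6, γ = 0.5, λ = 0.5 follow the loss's original
recommendation for mild class imbalance. An ε = 1e−12 guards logs, power
bases and Tversky denominators; an empty class is scored as perfectly
predicted (mTI = 1) rather than undefined.

The network runs on a package-internal reverse-mode autodiff engine over
NumPy arrays (im2col convolution, broadcast-aware arithmetic, float64
throughout). All gradients are verified against central finite differences
in the test suite. This keeps the package dependency-light and fully
CPU-reproducible; the trade-off is scale — training is sized for
experiments of order 10² images at ≤ 256² resolution, not clinical corpora.

**Training harness.** Adam (lr 1e−3 default; the learnability tests use
3e−3 for faster convergence at tiny scale), ReduceLROnPlateau (halve after
10 stale epochs), 10-fold cross-validation (shuffled near-equal partition,
sizes differ by ≤ 1), and on-the-fly augmentation: vertical/horizontal
flip, 90° rotation and transpose each with p = 0.5; random gamma
(0.8–1.2), CLAHE and Gaussian noise (variance ≤ 10 on the 0–255 scale)
each with p = 0.2; and an always-applied resize (256×256 by default,
configurable — the test suite trains at 64×64). Validation samples get
only the resize. One seed drives fold assignment, weight init, shuffling,
augmentation draws and dropout, so runs are exactly repeatable.

## Ensemble fusion

The two masks are combined by pixelwise logical AND, then an area opening.
The fused mask is a subset of both inputs, so for any ground truth its
false-positive count is bounded by the smaller of the two inputs' counts —
that bound, not a learned combination, is the design rationale. The dual
consequence is accepted as designed behavior: AND can only lower recall.
`open_min_area` defaults to the handcrafted stage's `min_area`-equivalent
(0 disables it).

## Cluster separability

Test-set logits (L1, L2, L3) are centered and projected onto the top two
principal components (sample covariance, divisor n−1; component signs fixed
by making the largest-magnitude loading positive so repeated runs produce
identical plots). Per true class: centroid, and spread
`sd_c = sqrt(SD_PC1² + SD_PC2²)` with sample SDs (ddof = 1). Totals:
`dist_total` = sum of the three pairwise centroid distances,
`sd_total = sqrt(Σ_c sd_c²)`, and the headline statistic
`ratio = 3 · dist_total / sd_total` (a 3:1 weighting of separation against
spread). Root-sum-of-squares was chosen as the SD combiner because it is
the natural Euclidean combination of orthogonal component spreads and
reconstructs published per-cluster/total tabulations consistently; the
mean-of-SDs alternative does not. Distances are measured after projection,
matching the visualization the statistic accompanies. All statistics are
invariant to rigid motions and to uniform scaling of the logit cloud
(scaling cancels in the ratio).

## Synthetic data

`make_smear` emulates the appearance that drives the color pipeline: a
pinkish background, anti-aliased pink disks with paler centers for red
cells, and purple nucleus blobs drawn last, whose exact union is the
ground-truth mask. Nucleus outlines are ellipses modulated by low-order
radial harmonics (frequencies 2, 3, 5; amplitudes 3–10 %), so closing and
hole filling have nontrivial work. Per-object color jitter (SD 8), Gaussian
pixel noise (SD 3) and seed-determined geometry complete the image; the
generator is a pure function of its parameter struct. Default canvas
128×128 with 1–2 nuclei of radius 10–18 px keeps the full test suite fast.
A `hard_mode` preset lowers nucleus saturation to imitate near-translucent
nuclei.

What the generator does **not** emulate: chromatin texture, cytoplasm,
overlapping/touching cells, focus gradients, and real stain variability
beyond Gaussian jitter. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the stated color model, not clinical
performance on real smears.

`make_logits` samples three isotropic Gaussian clouds in logit space with
controllable centroid separation and spread; with the default 6σ
separation the Dist/SD ratio is high, and shrinking the separation at fixed
spread lowers it monotonically (tested).

## Problem sizes and numerical choices

The learnability checks train (8, 16, 32, 64, 128)-channel networks on
eight 64×64 smears for 100 epochs — the smallest configuration at which
the network saturates (train Dice > 0.99) while the whole experiment stays
around a minute on one CPU; the full 32→512 architecture is exercised for
its shape/width contracts. Otsu equivalence is verified against exhaustive
search on 200 random images up to 32×32; fusion monotonicity on 10⁵ random
3×3 mask triples; metric identities on 10³ random mask pairs.

Degenerate inputs have explicit conventions: zero-denominator metrics
report 0 with an `undefined` flag; constant images yield empty Otsu masks
with a warning; zero-spread clusters and identical logit clouds raise
rather than return infinities.

## Known limitations

- The NumPy U-Net is CPU-bound; wall-clock scales roughly linearly in
  pixels × channels², so full-width training at 256×256 is slow.
- The handcrafted pipeline presumes purple-on-pink staining; other stains
  (or grayscale micrographs) defeat the Magenta×Saturation premise.
- With multiple nuclei of unequal brightness in one image, the single
  global Otsu threshold can drop a washed-out nucleus whose evidence falls
  below the split (the synthetic generator's color jitter occasionally
  produces this, visible as a low-IoU outlier among otherwise ~0.95 scores).
- AND-fusion trades recall for precision by construction.
- The Dist/SD ratio depends on the PCA projection; clusters separated only
  along the third principal axis would be under-reported.
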