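# Methods

`segqc` predicts the quality of a glottal-area segmentation — the IoU it
would score against an expert mask — without access to that expert mask,
and puts the prediction in context by quantifying how much experts
themselves disagree. This note documents the models, the synthetic data
they are exercised on, the numerical choices, and the limits of what the
tests show.

## Overlap metrics

Two binary masks A, B are compared with the Jaccard index
IoU(A, B) = |A∩B| / |A∪B|; the Dice score is the monotone transform
d = 2·IoU/(1 + IoU), and both conversions are exposed. When *both* masks
are empty the IoU is defined as 1.0: two annotators who both mark a frame
as closed-glottis are in perfect agreement. Closed frames are routine in
vocal-fold videos, so returning NaN here would contaminate every
reliability average downstream; the convention is overridable
(`iou(..., empty_value=...)`).

The IoU range [0, 1] is partitioned into 20 bins of width 0.05 for
dataset balancing. Bins are half-open [k·w, (k+1)·w) except the last,
which is closed, so every score — including exactly 1.0 — maps to exactly
one bin.

## Mask corruption

Training a quality regressor needs (mask, IoU) pairs covering the whole
quality range. Ground-truth masks are degraded by four stochastic
operators, each emulating a real failure mode of segmentation networks:

1. **Uniform scaling** — binary erosion or dilation (fair coin) with a
   3×3 cross element, 1–5 iterations: global over-/under-segmentation.
2. **Border fuzz** — the Sobel gradient magnitude is binarized at 0.3
   (on a 0/1 mask the true contour responds at ≥0.55, the diagonal halo
   at 0.25), dilated once, and every band pixel is independently set to
   foreground with probability 0.5: boundary uncertainty.
3. **Small artifacts** — 1–5 discs of radius 1–3 px, centred within a
   10-px dilation of the mask (the mask itself excluded): speckle false
   positives near the glottis.
4. **Large artifacts** — classic lattice-gradient (Perlin) noise with
   2–8 periods per axis, thresholded at a quantile drawn from
   [0.90, 1.0], unioned onto the mask: large spurious blobs such as
   reflections. An XOR mode exists for users who want noise that can
   also delete area, but union is the default because spurious *extra*
   area is the typical large-artifact failure.

Each step fires independently with its configured probability, in a
fixed order (scaling → fuzz → small → large). When corruption is
requested, the Bernoulli draws are redone until at least one step fires,
otherwise identity samples would dominate the top IoU bin. Every
degraded sample stores its applied recipe and its exact IoU against the
untouched input; samples are bit-reproducible from (config, seed).

With every step forced on, 1,000 seeded degradations of the default
phantoms spread their true IoU over 16 of the 20 bins; the remaining top
bins are reached by the gentler configurations the dataset builder uses.

## Balanced dataset construction

Raw corruption produces IoUs that pile up in the mid/low range, so the
builder rejection-samples into the 20 bins until each holds `per_bin`
samples (canonically 1,200 → 24,000 total). Candidates are drawn with a
config *annealed* toward the currently neediest bin — deep erosion and
generous Perlin area for low bins, mostly a lone small artifact for the
top bins — but a candidate landing in any unfilled bin is kept, so easy
bins fill as a side effect. A bin that stays empty after a configurable
attempt budget raises an error naming the bin. The manifest records
(source id, seed, targeted bin, true IoU, assigned bin) per sample,
which is sufficient to regenerate every mask bit-identically.

The train/validation split (default 5 %) is stratified by bin with
largest-remainder rounding, so the validation histogram stays as flat as
the input's: 24,000 rows split into exactly 22,800 + 1,200.

## Network inputs and the quality regressor

Frames are square-cropped around the candidate mask's bounding-box
centre (centre crop if empty), resized (bilinear image / nearest mask),
and normalized to [−1, 1] via x/127.5 − 1. The network input is a
3-channel stack assembled per a scheme code over {e = image, s = mask}:
eee, sss, see, sse, ees, ess. Mask channels carry {−1, +1}.

The regression head is fixed: global average pooling → dense 256 +
ReLU → dropout 0.1 → dense 1 + sigmoid, so predictions always lie in
(0, 1). Backbones are pluggable through a registry; the default `tiny`
backbone is four conv(3×3)+ReLU+maxpool blocks with 8/16/32/32 channels
at 64×64 input (~24 k parameters), chosen so a full training run
completes in minutes on one CPU core. A `tiny-wide` variant
(16/32/64/64) is registered for users with more time. The engine itself
(im2col convolution, pooling, dense, dropout, the losses and the
SGD-momentum/Adam optimizers) is implemented in numpy in `segqc.nn`,
fully seeded: identical seeds give bit-identical weights.

Training defaults follow the reference protocol: SGD with momentum 0.9
at lr 1e-2 or Adam at 1e-3, with the learning rate decaying by a factor
e^{−0.1} per epoch after epoch 10. The "after 10 epochs" reduction is
read as per-epoch exponential decay (the standard reading); a one-time
reduction is available via `decay_once`. Losses: MSE, MAE, and —
because a categorical cross-entropy is ill-defined for a single sigmoid
unit — a soft-label binary cross-entropy (`bce`, alias `xent`) treating
the true IoU as a soft label; `bce` is the default. A separate 20-class
softmax head was deliberately *not* added: the fixed sigmoid head is an
interface invariant of this package, and the binning already enters
through dataset balancing. The best-validation-loss epoch's weights are
restored after training.

Desk-scale problem sizes were fixed a priori as the package's canonical
test conditions: 2,400 balanced samples (2,000 train+val / 400 test) and
15 epochs for the headline predictability run; 1,400 samples and 8
epochs for the three-scheme comparison. At these sizes the scheme
ordering is unambiguous — mixing image and mask channels (see) beats
mask-only (sss) which beats image-only (eee), whose RMSE is pinned near
the standard deviation of the balanced IoU distribution (≈0.29) because
the image alone carries no information about the candidate mask.

## Rater reliability

For an annotation grid X[i, k, r] (rater, image, round):

- **IeRR(i, j)** averages, over images, the IoU between the two raters'
  round-averaged masks thresholded at >0. The threshold of a mean at >0
  is exactly the union over rounds, and it is implemented literally that
  way (and asserted in tests).
- **IaRR(i)** averages the IoU over all C(R,2) round pairs and all
  images.

Stratified variants recompute both statistics over images grouped by
mean segmented area across all raters and rounds — (0, 20), [20, 200),
[200, ∞) px by default; unanimously-empty images fall outside all
strata, and empty strata are omitted rather than reported as zero.
A distance profile reports per-pixel agreement with the majority-vote
consensus, binned either by normalized distance from the consensus
centre of mass (within the consensus support) or by unsigned Euclidean
distance from the consensus boundary — agreement is high deep inside the
glottal area and drops at the rim. "Distance to the edge" is not
standardized anywhere; the Euclidean distance transform of the
majority-vote consensus, normalized per image, was chosen because it is
scale-free across glottis sizes. Inter-model reliability needs no new
code: models are raters with R = 1.

## Synthetic phantoms

Real frames are emulated by a spindle phantom: a dark, pointed-ended
glottal gap (half-width tapering parabolically along the axis) on a
brighter background textured with smoothed Gaussian noise, soft-edged
via a small Gaussian blur, at 64×64 by default. Spindle length is drawn
from [16, 52] px and maximal width from [4, 24] px, giving mask areas
from ~100 to ~700 px — the proportions of a frame cropped around the
glottal area; a width scale of 0 gives a closed-glottis frame. Videos
modulate the width by |sin| so the area sweeps 0 → maximum for a chosen
number of cycles, passing through the <20 px and >200 px strata.

Simulated raters reuse the corruption vocabulary: a per-rater systematic
erode/dilate tendency (annotation style, fixed across rounds) plus
per-round boundary jitter (each edge-band pixel deviates from the
rater's own contour with a configured probability). Bias ≫ jitter
reproduces the empirically observed ordering: raters agree with
themselves more than with each other (mean IaRR > mean IeRR).

What the phantoms do *not* model: specular highlights, motion blur,
illumination drift, camera noise correlations, anatomy other than the
glottis, and rater errors that are not boundary-local (e.g. annotating
the wrong structure). Passing tests therefore demonstrate that the
pipeline's machinery and orderings are correct, not that a tiny backbone
trained on phantoms transfers to clinical footage.

## Traffic lights

Predicted IoU is classed green (> 0.7), yellow ([0.6, 0.7]), red
(< 0.6); the boundary values count as yellow ("between 0.6 and 0.7"
read inclusively) and both thresholds are configurable. Classification
is a total monotone step function. Bars render one pixel column per
frame (optionally down-sampled for long videos) alongside a CSV of
(frame, predicted IoU, class).

## Numerical and degenerate-input choices

- All randomness flows through explicit `numpy.random.Generator`
  objects; no global seeding.
- Masks are uint8 {0, 1}; PNGs binarize at >127 on read.
- `crop_and_resize` rejects images smaller than 8×8; empty masks fall
  back to a centre crop.
- The engine is float32; training aborts with a diagnostic on a
  non-finite loss instead of silently diverging.
- Mann–Whitney comparisons of two identical constant groups return
  p = 1 (no evidence of difference) rather than an error; Shapiro–Wilk
  is skipped (NaN) for groups of fewer than 3 values or zero range.
- Sphere centres for small artifacts are drawn from the proximity ring;
  an empty mask has no ring and is returned unchanged.

## Known limitations

- The tiny backbone saturates well below the capacity of the
  ImageNet-scale backbones the harness can host via the registry; its
  absolute RMSE on phantoms should not be quoted as clinical accuracy.
- The per-bin annealing schedule is heuristic; exotic corruption configs
  (e.g. all probabilities near 0 with `ensure_any_step` off) can starve
  low bins and will raise rather than loop forever.
- Reliability statistics assume a complete (N, K, R) grid; missing
  annotations must be handled upstream.
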