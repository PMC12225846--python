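# segqc

Reference-free segmentation-quality prediction for laryngeal endoscopy.

Automatic glottal-area segmentation drives the glottal area waveform and
the clinical voice parameters computed from it — but every downstream
number is only as good as the segmentation, and in clinical use there is
no expert ground truth to check against. `segqc` judges segmentation
quality without one: it *predicts* the Intersection-over-Union (IoU)
that a candidate mask would score against an expert annotation, directly
from the endoscopy frame and the mask.

It is aimed at researchers and tool builders working on high-speed
videoendoscopy pipelines who need per-frame quality control, and at
anyone who wants to quantify how much human annotators of glottal areas
agree with themselves and each other.

## What it computes

**IoU regression.** For masks A, B, IoU(A, B) = |A∩B| / |A∪B|
(Dice = 2·IoU/(1+IoU) is interconvertible). A CNN receives a 3-channel
stack assembled from the grayscale frame (`e`) and the candidate mask
(`s`) per a scheme code — `see`, `sss`, `eee`, … — and regresses the
true IoU through a fixed head: global average pooling → dense 256 +
ReLU → dropout 0.1 → dense 1 + sigmoid. Training pairs are manufactured
by corrupting ground-truth masks with four stochastic operators
(erosion/dilation, Sobel-band border fuzz, small discs, thresholded
Perlin blobs) and labelling each result with its exact IoU; a rejection
sampler balances the dataset over 20 IoU bins of width 0.05
(canonically 1,200 per bin → 24,000 samples, split 22,800 / 1,200 at
5 % validation).

**Rater reliability.** For an annotation grid X[i,k,r] (rater, image,
round):

- inter-rater: IeRR(i,j) = (1/K) Σ_k IoU(1(X̄_i,k > 0), 1(X̄_j,k > 0)),
  where X̄ is the round-averaged mask;
- intra-rater: IaRR(i) = (1/C(R,2)) Σ_{r<s} (1/K) Σ_k IoU(X_i,k,r, X_i,k,s);

plus breakdowns by segmented-area stratum and by distance from the
consensus centre/boundary.

**Traffic lights.** Per-frame predicted IoU is classed green (> 0.7),
yellow (0.6–0.7) or red (< 0.6) and rendered as a one-column-per-frame
colour bar plus CSV, flagging the stretches of a video that need human
review.

Everything runs on synthetic glottis phantoms (dark spindle on textured
tissue, oscillating videos, simulated rater campaigns), so no data
download is needed; real PNG frame/mask directories plug into the same
functions and the `segqc` CLI (`fixtures`, `corrupt`, `build-dataset`,
`reliability`, `train`, `trafficlight`).

## Worked example

Build a balanced dataset from 60 phantoms, train the tiny backbone on
scheme `see` for 10 epochs, and score 200 held-out corrupted masks:

```python
import numpy as np
from segqc import (BinSpec, CorruptionConfig, GlottisPhantomSpec, ModelSpec,
                   TrainSpec, build_balanced_dataset, build_model, classify,
                   compose_arrays, make_pair, rmse, split, train)

rng = np.random.default_rng(0)
pairs = [make_pair(GlottisPhantomSpec(), rng, source_id=f"p{i:03d}")
         for i in range(60)]

manifest, samples = build_balanced_dataset(
    pairs, BinSpec(), per_bin=60, cfg=CorruptionConfig(),
    rng=np.random.default_rng(1))
rest, test = split(manifest, 200 / 1200, np.random.default_rng(2))
tr, va = split(rest, 0.05, np.random.default_rng(3))
print(f"dataset: {len(manifest)} samples, "
      f"{len(tr)} train / {len(va)} val / {len(test)} test")

xt, yt = compose_arrays(pairs, tr, samples, "see")
xv, yv = compose_arrays(pairs, va, samples, "see")
xe, ye = compose_arrays(pairs, test, samples, "see")
model = build_model(ModelSpec(), seed=0)
train(model, xt, yt, xv, yv,
      TrainSpec(optimizer="adam", loss="bce", epochs=10),
      np.random.default_rng(0))

pred = model.predict(xe)
print(f"held-out RMSE: {rmse(pred, ye):.3f}")
print(f"Pearson r:     {np.corrcoef(pred, ye)[0, 1]:.3f}")
for v, t in [list(zip(pred, ye))[i] for i in (0, 100, 199)]:
    print(f"true IoU {t:.2f} -> predicted {v:.2f} ({classify(v)})")
```

Output:

```
dataset: 1200 samples, 950 train / 50 val / 200 test
held-out RMSE: 0.039
Pearson r:     0.991
true IoU 0.02 -> predicted 0.01 (red)
true IoU 0.51 -> predicted 0.48 (red)
true IoU 0.96 -> predicted 0.95 (green)
```

The RMSE says predictions are within ±0.04 of the true IoU on average;
the Pearson r says ranking across the whole quality range is essentially
perfect at this scale. The three rows show the traffic-light reading: a
destroyed mask, a mediocre one and a near-perfect one are flagged red,
red and green respectively.

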