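"""IoU-balanced regression dataset construction and input composition.

The quality regressor is trained on (input tensor, true IoU) pairs.
Raw IoU values from random corruption pile up near the extremes, so the
builder rejection-samples degraded masks into 20 equal-width IoU bins
until every bin holds the same number of samples — a perfectly flat
target histogram (the canonical configuration is 1,200 per bin, 24,000
samples in total).

Network inputs are three-channel stacks assembled from the grayscale
endoscopy frame (``e``) and the candidate segmentation mask (``s``)
according to a scheme code such as ``see`` (mask in channel 0, image in
channels 1–2).  Frames are square-cropped around the glottal area,
resized, and normalized to [−1, 1].
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import color, transform

from .corruption import CorruptionConfig, DegradedSample, degrade
from .metrics import BinSpec, bin_index, write_mask
from .phantoms import FramePair

__all__ = [
    "VALID_SCHEMES",
    "crop_and_resize",
    "normalize",
    "compose_input",
    "build_balanced_dataset",
    "replay_sample",
    "split",
]

VALID_SCHEMES = ("eee", "sss", "see", "sse", "ees", "ess")

MANIFEST_COLUMNS = ["sample_id", "source_id", "mask_path", "true_iou", "bin",
                    "seed", "target_bin"]


def crop_and_resize(pair: FramePair, side: int = 224) -> FramePair:
    """Square-crop around the glottal area and resize to ``side``×``side``.

    The crop is the largest square that fits in the frame, centred on
    the mask's bounding-box centre and clipped to the image bounds; an
    empty mask falls back to a centre crop.  The image is resampled
    bilinearly, the mask with nearest-neighbour and re-binarized.
    """
    img, mask = pair.image, pair.mask
    h, w = img.shape
    if h < 8 or w < 8:
        raise ValueError(f"image too small to crop: {img.shape}")
    s = min(h, w)
    if mask.any():
        ys, xs = np.nonzero(mask)
        cy = (ys.min() + ys.max() + 1) / 2.0
        cx = (xs.min() + xs.max() + 1) / 2.0
    else:
        cy, cx = h / 2.0, w / 2.0
    top = int(np.clip(round(cy - s / 2.0), 0, h - s))
    left = int(np.clip(round(cx - s / 2.0), 0, w - s))
    img_c = img[top:top + s, left:left + s]
    mask_c = mask[top:top + s, left:left + s]
    img_r = transform.resize(img_c.astype(float), (side, side), order=1,
                             preserve_range=True, anti_aliasing=s > side)
    mask_r = transform.resize(mask_c.astype(float), (side, side), order=0,
                              preserve_range=True, anti_aliasing=False)
    return FramePair(image=np.clip(img_r, 0, 255).astype(np.uint8),
                     mask=(mask_r > 0.5).astype(np.uint8),
                     source_id=pair.source_id)


def normalize(image: np.ndarray) -> np.ndarray:
    """Map pixel values from [0, 255] to [−1, 1]: x ↦ x/127.5 − 1."""
    return np.asarray(image, dtype=np.float32) / 127.5 - 1.0


def compose_input(pair: FramePair, degraded_mask: np.ndarray,
                  scheme: str) -> np.ndarray:
    """Assemble the H×W×3 network input for a scheme code.

    ``e`` channels carry the normalized grayscale frame, ``s`` channels
    the candidate mask mapped to {−1, 1}.  RGB frames are converted to
    grayscale first.
    """
    if scheme not in VALID_SCHEMES:
        raise ValueError(
            f"invalid scheme {scheme!r}; valid codes are {', '.join(VALID_SCHEMES)}"
        )
    img = pair.image
    if img.ndim == 3:
        img = (color.rgb2gray(img) * 255.0).astype(np.uint8)
    if img.shape != degraded_mask.shape:
        raise ValueError(
            f"image/mask shape mismatch: {img.shape} vs {degraded_mask.shape}"
        )
    e = normalize(img)
    s = degraded_mask.astype(np.float32) * 2.0 - 1.0
    channels = [e if c == "e" else s for c in scheme]
    return np.stack(channels, axis=-1)


def _annealed_config(base: CorruptionConfig, target_bin: int,
                     spec: BinSpec) -> CorruptionConfig:
    """Bias the corruption strength toward a target IoU bin.

    Low bins need destructive settings (deep erosion, generous Perlin
    blobs); the top bins need gentle ones (mostly a lone small
    artifact).  Parameters interpolate with the bin centre; plain
    rejection sampling does the exact placement.
    """
    c = float(spec.centers()[target_bin])
    if c < 0.55:
        # destructive regime: deep erosion and generous blobs
        s = 1.0 - c
        return base.with_(
            p_scaling=1.0, p_border_fuzz=0.5, p_small_artifacts=0.5,
            p_large_artifacts=0.9 if c < 0.3 else 0.5,
            scaling_iterations_range=(1, max(base.scaling_iterations_range[1],
                                             int(round(1 + 12 * s)))),
            perlin_threshold_range=(0.55 + 0.30 * c, 0.80 + 0.17 * c),
            ensure_any_step=True,
        )
    if c < 0.75:
        # one or two moderate steps
        return base.with_(
            p_scaling=0.4, p_border_fuzz=0.5, p_small_artifacts=0.6,
            p_large_artifacts=0.2, scaling_iterations_range=(1, 2),
            perlin_threshold_range=(0.93, 0.995), ensure_any_step=True,
        )
    # near-identity regime: mostly a lone small artifact
    return base.with_(
        p_scaling=0.1, p_border_fuzz=0.1, p_small_artifacts=0.9,
        p_large_artifacts=0.05, scaling_iterations_range=(1, 1),
        perlin_threshold_range=(0.97, 1.0), ensure_any_step=True,
    )


def build_balanced_dataset(pairs: Sequence[FramePair],
                           spec: BinSpec = BinSpec(),
                           per_bin: int = 1200,
                           cfg: CorruptionConfig = CorruptionConfig(),
                           rng: np.random.Generator | None = None,
                           max_attempts_per_bin: int = 60000,
                           out_dir: str | os.PathLike | None = None,
                           ) -> tuple[pd.DataFrame, list[DegradedSample]]:
    """Rejection-sample corrupted masks until every IoU bin is full.

    Candidates are drawn with a config annealed toward the currently
    neediest bin, but a candidate landing in *any* unfilled bin is kept,
    so easy bins fill as a side effect of hunting hard ones.  Returns
    the manifest (one row per accepted sample) and the samples in
    manifest order; with ``out_dir`` the degraded masks are also written
    as PNGs and ``mask_path`` is populated.

    Raises ``RuntimeError`` naming the starving bin if it cannot be
    filled within ``max_attempts_per_bin`` targeted draws.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one frame pair")
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    need = np.full(spec.n_bins, per_bin, dtype=int)
    attempts = np.zeros(spec.n_bins, dtype=int)
    annealed = [_annealed_config(cfg, b, spec) for b in range(spec.n_bins)]
    rows: list[dict] = []
    samples: list[DegradedSample] = []

    while need.sum() > 0:
        target = int(np.argmax(need))  # hunt the neediest bin
        if attempts[target] >= max_attempts_per_bin:
            raise RuntimeError(
                f"bin {target} still needs {need[target]} of {per_bin} samples "
                f"after {attempts[target]} targeted attempts"
            )
        attempts[target] += 1
        seed = int(rng.integers(2**31))
        sub = np.random.default_rng(seed)
        pair_idx = int(sub.integers(len(pairs)))
        sample = degrade(pairs[pair_idx].mask, annealed[target], sub)
        b = bin_index(sample.true_iou, spec)
        if need[b] <= 0:
            continue
        need[b] -= 1
        sid = len(rows)
        mask_path = ""
        if out_dir is not None:
            mask_path = os.path.join(out_dir, f"sample_{sid:06d}.png")
            write_mask(mask_path, sample.degraded)
        rows.append({"sample_id": sid,
                     "source_id": pairs[pair_idx].source_id or str(pair_idx),
                     "mask_path": mask_path,
                     "true_iou": sample.true_iou,
                     "bin": b,
                     "seed": seed,
                     "target_bin": target})
        samples.append(sample)

    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS), samples


def replay_sample(pairs: Sequence[FramePair], row,
                  cfg: CorruptionConfig = CorruptionConfig(),
                  spec: BinSpec = BinSpec()) -> DegradedSample:
    """Regenerate one manifest row's degraded mask bit-identically.

    The manifest stores the candidate seed and the bin the sampler was
    targeting, which together determine the annealed config and every
    random draw.
    """
    sub = np.random.default_rng(int(row["seed"]))
    pair_idx = int(sub.integers(len(pairs)))
    annealed = _annealed_config(cfg, int(row["target_bin"]), spec)
    return degrade(pairs[pair_idx].mask, annealed, sub)


def split(manifest: pd.DataFrame, val_fraction: float = 0.05,
          rng: np.random.Generator | None = None,
          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-bin train/validation split.

    The validation set receives ``round(val_fraction * total)`` rows,
    distributed over bins by largest remainder so the validation
    histogram stays as flat as the input's (24,000 rows at 5 % →
    22,800 train / 1,200 validation).
    """
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    total_val = int(len(manifest) * val_fraction + 0.5)

    groups = [g for _, g in manifest.groupby("bin", sort=True)]
    quotas = np.array([len(g) * val_fraction for g in groups])
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    extra = total_val - base.sum()
    order = np.argsort(-remainder, kind="stable")
    for j in order[:extra]:
        base[j] += 1

    val_idx: list = []
    for g, n_val in zip(groups, base):
        chosen = rng.choice(len(g), size=n_val, replace=False)
        val_idx.extend(g.index[np.sort(chosen)])
    val = manifest.loc[val_idx]
    train = manifest.drop(index=val_idx)
    return train, val
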