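"""Stochastic mask-corruption operators for IoU-labelled training data.

Ground-truth glottal-area masks are degraded by four independent steps,
emulating the failure modes of real segmentation networks:

1. **uniform scaling** — binary erosion or dilation (over-/under-
   segmentation of the whole area);
2. **border fuzz** — Sobel edge detection, dilation of the edge band,
   then random add/remove of each band pixel (annotator-style boundary
   uncertainty);
3. **small artifacts** — up to five discs of radius 1–3 px dropped near
   the glottis (speckle false positives);
4. **large artifacts** — thresholded 2-D Perlin noise unioned onto the
   mask (big spurious blobs such as reflections labelled as glottis).

Each step is applied with its own probability and randomly drawn
hyperparameters; the degraded mask is scored against the untouched
ground truth, producing an exactly-labelled (mask, IoU) training pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import filters

from .metrics import as_mask, iou

__all__ = [
    "CorruptionConfig",
    "DegradedSample",
    "CROSS",
    "perlin_noise_2d",
    "apply_uniform_scaling",
    "apply_border_fuzz",
    "apply_small_artifacts",
    "apply_large_artifacts",
    "degrade",
]

#: 3×3 cross (4-connected) structuring element used by every morphological step.
CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class CorruptionConfig:
    """Hyperparameter ranges for the four corruption steps.

    ``p_*`` are per-step application probabilities; integer ranges are
    inclusive ``(lo, hi)``; ``perlin_threshold_range`` is a *quantile*
    range — a blob layer is the noise field thresholded at that
    quantile, so 0.9 keeps the top 10 % of the field as blob area.
    """

    p_scaling: float = 0.5
    p_border_fuzz: float = 0.5
    p_small_artifacts: float = 0.5
    p_large_artifacts: float = 0.5
    scaling_iterations_range: tuple[int, int] = (1, 5)
    edge_flip_probability: float = 0.5
    max_spheres: int = 5
    sphere_radius_range: tuple[int, int] = (1, 3)
    sphere_proximity: int = 10
    perlin_periods_range: tuple[int, int] = (2, 8)
    perlin_threshold_range: tuple[float, float] = (0.90, 1.0)
    perlin_mode: Literal["union", "xor"] = "union"
    ensure_any_step: bool = True

    def __post_init__(self) -> None:
        for name in ("p_scaling", "p_border_fuzz", "p_small_artifacts",
                     "p_large_artifacts", "edge_flip_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("scaling_iterations_range", "sphere_radius_range",
                     "perlin_periods_range", "perlin_threshold_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")

    def with_(self, **kwargs) -> "CorruptionConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DegradedSample:
    """A corrupted mask, its exact IoU vs. ground truth, and the recipe."""

    original: np.ndarray
    degraded: np.ndarray
    true_iou: float
    applied_steps: tuple = field(default_factory=tuple)


def perlin_noise_2d(shape: tuple[int, int], periods: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Classic lattice-gradient (Perlin) noise over an arbitrary grid.

    Unit gradient vectors are drawn at the nodes of a ``periods×periods``
    lattice and interpolated with the quintic fade ``6t^5-15t^4+10t^3``.
    The grid is padded internally so lattice cells divide it evenly,
    then cropped back to ``shape``.
    """
    if periods < 1:
        raise ValueError("periods must be >= 1")
    h, w = shape
    d = (-(-h // periods), -(-w // periods))  # ceil division: cell size
    hp, wp = d[0] * periods, d[1] * periods

    angles = rng.uniform(0.0, 2.0 * np.pi, (periods + 1, periods + 1))
    grad = np.stack([np.cos(angles), np.sin(angles)], axis=-1)

    # fractional coordinates of each pixel inside its lattice cell
    ty = (np.arange(hp) % d[0] + 0.5) / d[0]
    tx = (np.arange(wp) % d[1] + 0.5) / d[1]
    cy = np.arange(hp) // d[0]
    cx = np.arange(wp) // d[1]

    ty2 = ty[:, None]
    tx2 = tx[None, :]

    def dot(oy: int, ox: int) -> np.ndarray:
        g = grad[cy[:, None] + oy, cx[None, :] + ox]
        return g[..., 0] * (ty2 - oy) + g[..., 1] * (tx2 - ox)

    fy = ty2**3 * (ty2 * (ty2 * 6 - 15) + 10)
    fx = tx2**3 * (tx2 * (tx2 * 6 - 15) + 10)
    n0 = dot(0, 0) * (1 - fx) + dot(0, 1) * fx
    n1 = dot(1, 0) * (1 - fx) + dot(1, 1) * fx
    return (n0 * (1 - fy) + n1 * fy)[:h, :w]


def apply_uniform_scaling(m: np.ndarray, iterations: int,
                          mode: Literal["erode", "dilate"]) -> np.ndarray:
    """Erode or dilate the whole mask with the 3×3 cross element."""
    m = as_mask(m)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    op = ndimage.binary_erosion if mode == "erode" else ndimage.binary_dilation
    if mode not in ("erode", "dilate"):
        raise ValueError(f"mode must be 'erode' or 'dilate', got {mode!r}")
    return op(m, structure=CROSS, iterations=iterations).astype(np.uint8)


def edge_band(m: np.ndarray, sobel_threshold: float = 0.3) -> np.ndarray:
    """Dilated Sobel edge band of a binary mask (boolean array).

    The gradient magnitude is binarized at ``sobel_threshold`` before
    dilation: on a 0/1 mask the immediate boundary responds at ≥0.55
    while the diagonal halo responds at 0.25, so 0.3 keeps the true
    contour and drops the halo.
    """
    edges = filters.sobel(as_mask(m).astype(float)) > sobel_threshold
    return ndimage.binary_dilation(edges, structure=CROSS)


def apply_border_fuzz(m: np.ndarray, flip_p: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Randomize the mask boundary: every pixel in the dilated Sobel edge
    band becomes foreground with probability ``flip_p``, else background.
    Pixels outside the band are untouched; an edge-free mask is returned
    unchanged."""
    m = as_mask(m)
    if not 0.0 <= flip_p <= 1.0:
        raise ValueError(f"flip_p must lie in [0, 1], got {flip_p}")
    band = edge_band(m)
    out = m.copy()
    out[band] = (rng.random(int(band.sum())) < flip_p).astype(np.uint8)
    return out


def apply_small_artifacts(m: np.ndarray, rng: np.random.Generator,
                          max_spheres: int = 5,
                          radius_range: tuple[int, int] = (1, 3),
                          proximity: int = 10) -> np.ndarray:
    """Union 1..max_spheres random discs onto the mask, centred in the
    ``proximity``-pixel neighbourhood of the existing foreground (the
    foreground itself excluded).  An empty mask has no neighbourhood and
    is returned unchanged."""
    m = as_mask(m)
    if not m.any():
        return m
    ring = ndimage.binary_dilation(m, structure=CROSS, iterations=proximity) & ~m.astype(bool)
    ys, xs = np.nonzero(ring)
    if ys.size == 0:
        return m
    n = int(rng.integers(1, max_spheres + 1))
    out = m.copy()
    yy, xx = np.ogrid[: m.shape[0], : m.shape[1]]
    for _ in range(n):
        j = int(rng.integers(ys.size))
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        disc = (yy - ys[j]) ** 2 + (xx - xs[j]) ** 2 <= r * r
        out[disc] = 1
    return out


def apply_large_artifacts(m: np.ndarray, rng: np.random.Generator,
                          periods: int, threshold: float,
                          mode: Literal["union", "xor"] = "union") -> np.ndarray:
    """Union (or XOR) a thresholded Perlin blob layer onto the mask.

    ``threshold`` is the quantile of the noise field kept as blob area:
    1.0 keeps nothing, 0.0 turns the whole frame into foreground.
    """
    m = as_mask(m)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold quantile must lie in [0, 1], got {threshold}")
    noise = perlin_noise_2d(m.shape, periods, rng)
    if threshold >= 1.0:
        blobs = np.zeros_like(m, dtype=bool)
    else:
        blobs = noise >= np.quantile(noise, threshold)
    if mode == "union":
        return (m.astype(bool) | blobs).astype(np.uint8)
    return (m.astype(bool) ^ blobs).astype(np.uint8)


def degrade(mask: np.ndarray, cfg: CorruptionConfig,
            rng: np.random.Generator) -> DegradedSample:
    """Run the four-step corruption pipeline on a ground-truth mask.

    Steps are applied independently, each with its configured
    probability, in the fixed order scaling → border fuzz → small
    artifacts → large artifacts.  With ``ensure_any_step`` the Bernoulli
    draws are redone until at least one step fires, so the identity
    outcome does not dominate.  Hyperparameters are drawn from the
    config ranges; the applied recipe is recorded step by step and the
    exact IoU against the untouched input is stored.
    """
    original = as_mask(mask)
    while True:
        flags = rng.random(4) < (cfg.p_scaling, cfg.p_border_fuzz,
                                 cfg.p_small_artifacts, cfg.p_large_artifacts)
        if flags.any() or not cfg.ensure_any_step:
            break
        if (cfg.p_scaling == cfg.p_border_fuzz == cfg.p_small_artifacts
                == cfg.p_large_artifacts == 0.0):
            break  # identity is the only possible outcome

    out = original
    steps: list[tuple[str, dict]] = []
    if flags[0]:
        lo, hi = cfg.scaling_iterations_range
        its = int(rng.integers(lo, hi + 1))
        mode = "erode" if rng.random() < 0.5 else "dilate"
        out = apply_uniform_scaling(out, its, mode)
        steps.append(("uniform_scaling", {"iterations": its, "mode": mode}))
    if flags[1]:
        out = apply_border_fuzz(out, cfg.edge_flip_probability, rng)
        steps.append(("border_fuzz", {"flip_p": cfg.edge_flip_probability}))
    if flags[2]:
        out = apply_small_artifacts(out, rng, cfg.max_spheres,
                                    cfg.sphere_radius_range, cfg.sphere_proximity)
        steps.append(("small_artifacts", {"max_spheres": cfg.max_spheres,
                                          "radius_range": cfg.sphere_radius_range,
                                          "proximity": cfg.sphere_proximity}))
    if flags[3]:
        lo, hi = cfg.perlin_periods_range
        periods = int(rng.integers(lo, hi + 1))
        thr = float(rng.uniform(*cfg.perlin_threshold_range))
        out = apply_large_artifacts(out, rng, periods, thr, cfg.perlin_mode)
        steps.append(("large_artifacts", {"periods": periods, "threshold": thr,
                                          "mode": cfg.perlin_mode}))
    return DegradedSample(original=original, degraded=out,
                          true_iou=iou(original, out),
                          applied_steps=tuple(steps))
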