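"""Synthetic glottis-like image/mask phantoms.

Real training data for glottal-area quality models consists of
laryngeal endoscopy frames with expert masks.  This module synthesizes
stand-ins: a dark spindle-shaped "glottal gap" (the opening between the
vocal folds, pointed at the anterior and posterior ends) on a brighter
textured background, plus oscillating videos whose gap area sweeps from
fully closed to fully open like a vocal-fold cycle, and simulated
multi-rater annotation sets.  Every generator is deterministic given
its seed, so entire datasets can be regenerated from a manifest.

Rater simulation reuses the corruption operators as the noise model:
a per-rater systematic erode/dilate tendency plays the role of
annotation style (a rater consistently tracing tighter or looser
contours), and per-round border fuzz plays the role of hand jitter.
This makes the inter- vs. intra-rater ordering directly controllable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .corruption import apply_uniform_scaling, edge_band

__all__ = [
    "GlottisPhantomSpec",
    "SimulatedRaterSpec",
    "FramePair",
    "spindle_mask",
    "make_pair",
    "make_video",
    "make_rater_set",
]


@dataclass(frozen=True)
class FramePair:
    """A grayscale endoscopy-like frame with its binary glottal-area mask."""

    image: np.ndarray  # 2-D uint8, [0, 255]
    mask: np.ndarray   # 2-D uint8, {0, 1}, same shape
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )


@dataclass(frozen=True)
class GlottisPhantomSpec:
    """Parameters of the spindle phantom.

    Lengths are in pixels.  ``length_range`` / ``width_range`` are the
    uniform sampling intervals of the spindle's long axis and maximal
    width; widths below one pixel yield a closed-glottis (empty-mask)
    frame.  The defaults at side 64 produce mask areas from 0 to well
    above 200 px, spanning the area strata used in reliability
    analysis.
    """

    side: int = 64
    length_range: tuple[float, float] = (16.0, 52.0)
    width_range: tuple[float, float] = (4.0, 24.0)
    orientation_jitter: float = 0.5   # radians around vertical
    centroid_jitter: float = 6.0      # px around frame centre
    background_level: float = 170.0
    glottis_level: float = 45.0
    texture_amplitude: float = 25.0
    texture_smoothing: float = 2.0


def spindle_mask(side: int, length: float, width: float, angle: float,
                 center: tuple[float, float]) -> np.ndarray:
    """Binary spindle (lens with pointed ends) on a ``side``×``side`` grid.

    Along the long axis the half-width tapers parabolically:
    ``|v| <= (width/2) * (1 - (2u/length)^2)``.
    """
    if width < 1.0 or length < 1.0:
        return np.zeros((side, side), dtype=np.uint8)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    u = dy * np.cos(angle) + dx * np.sin(angle)       # along axis
    v = -dy * np.sin(angle) + dx * np.cos(angle)      # across axis
    taper = 1.0 - (2.0 * u / length) ** 2
    return ((np.abs(u) <= length / 2.0)
            & (np.abs(v) <= (width / 2.0) * np.clip(taper, 0.0, 1.0))
            ).astype(np.uint8)


def _textured_background(side: int, spec: GlottisPhantomSpec,
                         rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, (side, side))
    tex = ndimage.gaussian_filter(noise, spec.texture_smoothing)
    tex /= max(np.abs(tex).max(), 1e-9)
    return spec.background_level + spec.texture_amplitude * tex


def make_pair(spec: GlottisPhantomSpec, rng: np.random.Generator,
              source_id: str = "", width_scale: float = 1.0) -> FramePair:
    """Draw one phantom frame: dark spindle gap on textured tissue.

    ``width_scale`` multiplies the sampled spindle width; 0 produces a
    closed-glottis frame (empty mask, still a textured image).
    """
    side = spec.side
    length = rng.uniform(*spec.length_range)
    width = rng.uniform(*spec.width_range) * width_scale
    angle = rng.uniform(-spec.orientation_jitter, spec.orientation_jitter)
    cy = side / 2.0 + rng.uniform(-spec.centroid_jitter, spec.centroid_jitter)
    cx = side / 2.0 + rng.uniform(-spec.centroid_jitter, spec.centroid_jitter)
    mask = spindle_mask(side, length, width, angle, (cy, cx))

    img = _textured_background(side, spec, rng)
    # darken the gap with a soft edge so the boundary looks imaged, not drawn
    soft = ndimage.gaussian_filter(mask.astype(float), 0.8)
    img = img * (1.0 - soft) + spec.glottis_level * soft
    img += rng.normal(0.0, 3.0, img.shape)
    return FramePair(image=np.clip(img, 0, 255).astype(np.uint8),
                     mask=mask, source_id=source_id)


def make_video(spec: GlottisPhantomSpec, n_frames: int, cycles: int,
               rng: np.random.Generator) -> list[FramePair]:
    """An oscillating phantom video: one anatomy, sinusoidally opening gap.

    The spindle width is modulated by ``|sin|`` so the mask area sweeps
    from 0 (closure) to its maximum ``cycles`` times, passing through
    small (<20 px) and large (>200 px) areas on the way.
    """
    side = spec.side
    length = rng.uniform(*spec.length_range)
    width = spec.width_range[1]  # full-open width: use the top of the range
    angle = rng.uniform(-spec.orientation_jitter, spec.orientation_jitter)
    cy = side / 2.0 + rng.uniform(-spec.centroid_jitter, spec.centroid_jitter)
    cx = side / 2.0 + rng.uniform(-spec.centroid_jitter, spec.centroid_jitter)
    background = _textured_background(side, spec, rng)

    frames = []
    for f in range(n_frames):
        phase = np.pi * cycles * f / max(n_frames - 1, 1)
        w = width * abs(np.sin(phase))
        mask = spindle_mask(side, length, w, angle, (cy, cx))
        soft = ndimage.gaussian_filter(mask.astype(float), 0.8)
        img = background * (1.0 - soft) + spec.glottis_level * soft
        img += rng.normal(0.0, 3.0, img.shape)
        frames.append(FramePair(image=np.clip(img, 0, 255).astype(np.uint8),
                                mask=mask, source_id=f"frame_{f:05d}"))
    return frames


@dataclass(frozen=True)
class SimulatedRaterSpec:
    """Simulated annotation campaign: N raters × K images × R rounds.

    ``bias_strength`` is the maximal magnitude of a rater's systematic
    erode/dilate tendency in morphological iterations (drawn once per
    rater); ``round_noise`` is the border-fuzz flip probability applied
    independently every round.  Bias ≫ noise reproduces the empirical
    situation where each rater is self-consistent but raters disagree
    with each other.
    """

    n_raters: int = 6
    n_images: int = 20
    n_rounds: int = 3
    bias_strength: int = 2
    round_noise: float = 0.25

    def __post_init__(self) -> None:
        if min(self.n_raters, self.n_images, self.n_rounds) < 1:
            raise ValueError("n_raters, n_images, n_rounds must all be >= 1")


def make_rater_set(pairs: list[FramePair], spec: SimulatedRaterSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Simulate the full (rater, image, round) annotation grid.

    Returns an object array of shape (N, K, R) of binary masks.  Rater
    ``i``'s bias (erode or dilate by up to ``bias_strength`` iterations)
    is fixed across rounds; border fuzz with ``round_noise`` is redrawn
    every round.
    """
    if len(pairs) < spec.n_images:
        raise ValueError(f"need {spec.n_images} base pairs, got {len(pairs)}")
    biases = []
    for _ in range(spec.n_raters):
        its = int(rng.integers(0, spec.bias_strength + 1))
        mode = "erode" if rng.random() < 0.5 else "dilate"
        biases.append((its, mode))

    grid = np.empty((spec.n_raters, spec.n_images, spec.n_rounds), dtype=object)
    for i, (its, mode) in enumerate(biases):
        for k in range(spec.n_images):
            base = pairs[k].mask
            biased = apply_uniform_scaling(base, its, mode) if its > 0 else base
            for r in range(spec.n_rounds):
                m = biased
                if spec.round_noise > 0.0:
                    # hand jitter: each edge-band pixel deviates from the
                    # rater's own contour with probability round_noise
                    m = _partial_fuzz(biased, spec.round_noise, rng)
                grid[i, k, r] = m
    return grid


def _partial_fuzz(m: np.ndarray, deviate_p: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Flip each edge-band pixel of ``m`` with probability ``deviate_p``."""
    band = edge_band(m)
    out = m.copy()
    flips = band & (rng.random(m.shape) < deviate_p)
    out[flips] = 1 - out[flips]
    return out
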