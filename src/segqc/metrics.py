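"""Overlap metrics, IoU binning and error measures.

Everything downstream — the artifact generator, the balanced-dataset
builder, the rater-reliability analysis and the traffic-light reports —
scores binary glottal-area masks with the Intersection-over-Union (IoU,
Jaccard) metric implemented here.  Masks are plain 2-D ``uint8`` numpy
arrays with values in {0, 1}; they are read from and written to
single-channel PNG files (0 = background, 255 = foreground).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "BinSpec",
    "as_mask",
    "iou",
    "dice_from_iou",
    "iou_from_dice",
    "bin_index",
    "rmse",
    "read_mask",
    "write_mask",
]


def as_mask(a: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a binary {0,1} uint8 mask.

    Raises ``ValueError`` for non-2-D input or values outside {0, 1}.
    """
    m = np.asarray(a)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if m.dtype == bool:
        return m.astype(np.uint8)
    u = np.unique(m)
    if not np.isin(u, (0, 1)).all():
        raise ValueError(f"mask values must be 0 or 1, found {u[:10]}")
    return m.astype(np.uint8)


def iou(a: np.ndarray, b: np.ndarray, *, empty_value: float = 1.0) -> float:
    """Intersection-over-Union |A∩B| / |A∪B| of two binary masks.

    Parameters
    ----------
    a, b
        Binary masks of identical shape.
    empty_value
        Score returned when *both* masks are empty.  Defaults to 1.0:
        two annotators who both say "the glottis is closed, there is no
        area" are in perfect agreement.  Closed-glottis frames are
        common in vocal-fold videos, so a NaN here would poison every
        reliability average downstream.
    """
    a = as_mask(a)
    b = as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return float(empty_value)
    inter = np.count_nonzero(a & b)
    return inter / union


def dice_from_iou(i: float) -> float:
    """Convert an IoU score to the equivalent Dice score, d = 2i/(1+i)."""
    if not 0.0 <= i <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {i}")
    return 2.0 * i / (1.0 + i)


def iou_from_dice(d: float) -> float:
    """Convert a Dice score to the equivalent IoU score, i = d/(2-d)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"Dice must lie in [0, 1], got {d}")
    return d / (2.0 - d)


@dataclass(frozen=True)
class BinSpec:
    """Partition of the IoU range [0, 1] into equal-width bins.

    The default 20 bins of width 0.05 are the binning used to balance
    the regression training set.  Bins are half-open ``[k·w, (k+1)·w)``
    except the last, which is closed so that IoU 1.0 falls in bin
    ``n_bins - 1``.
    """

    n_bins: int = 20
    width: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if abs(self.n_bins * self.width - 1.0) > 1e-9:
            raise ValueError(
                f"n_bins * width must equal 1, got {self.n_bins} * {self.width}"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


def bin_index(value: float, spec: BinSpec = BinSpec()) -> int:
    """Map an IoU score to its bin, clamping 1.0 into the last bin."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {value}")
    return min(int(value / spec.width), spec.n_bins - 1)


def rmse(predicted: Sequence[float], truth: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length sequences."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty sequences is undefined")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask from a single-channel PNG (binarized at >127)."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return (img > 127).astype(np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(path, (as_mask(mask) * 255).astype(np.uint8))
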