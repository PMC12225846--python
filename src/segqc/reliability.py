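"""Inter- and intra-rater reliability of binary segmentation masks.

An annotation campaign is a complete grid of masks X[i, k, r] for rater
i ∈ 1..N, image k ∈ 1..K and round r ∈ 1..R.  Two IoU-based summary
statistics are computed:

* **Inter-rater reliability (IeRR)** between raters i and j: average
  each rater's masks over rounds, threshold at >0 (equivalently, take
  the union of that rater's rounds), and average the IoU of the two
  thresholded masks over images::

      IeRR(i, j) = (1/K) Σ_k IoU( 1(X̄_i,k > 0), 1(X̄_j,k > 0) )

* **Intra-rater reliability (IaRR)** of rater i: IoU between every pair
  of that rater's rounds, averaged over images and round pairs::

      IaRR(i) = (1 / C(R,2)) Σ_{r<s} (1/K) Σ_k IoU(X_i,k,r, X_i,k,s)

Breakdowns by segmented-area size and by distance from the consensus
centre/boundary expose where raters disagree: tiny glottal areas and
the mask rim are the unreliable regions.

Masks for frames where both raters see a closed glottis (both empty)
score IoU 1; see :func:`segqc.metrics.iou`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .metrics import iou

__all__ = [
    "RaterAnnotationSet",
    "mean_round_mask",
    "union_mask",
    "ierr_pair",
    "ierr_matrix",
    "iarr",
    "iarr_all",
    "stratify_by_area",
    "agreement_vs_distance",
]

#: default area strata (pixel counts): tiny, medium, large glottal areas
DEFAULT_AREA_EDGES = (0, 20, 200)


@dataclass
class RaterAnnotationSet:
    """Complete (N raters × K images × R rounds) grid of binary masks.

    ``masks`` is an object array of shape (N, K, R); all masks of one
    image share dimensions.
    """

    masks: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masks, dtype=object)
        if m.ndim != 3:
            raise ValueError(f"mask grid must be (N, K, R), got ndim {m.ndim}")
        for k in range(m.shape[1]):
            shapes = {m[i, k, r].shape
                      for i in range(m.shape[0]) for r in range(m.shape[2])}
            if len(shapes) != 1:
                raise ValueError(f"image {k} has inconsistent mask shapes: {shapes}")
        self.masks = m

    @property
    def n_raters(self) -> int:
        return self.masks.shape[0]

    @property
    def n_images(self) -> int:
        return self.masks.shape[1]

    @property
    def n_rounds(self) -> int:
        return self.masks.shape[2]


def mean_round_mask(s: RaterAnnotationSet, i: int, k: int) -> np.ndarray:
    """X̄_i,k: rater i's masks for image k averaged over rounds (float grid)."""
    stack = np.stack([s.masks[i, k, r].astype(float) for r in range(s.n_rounds)])
    return stack.mean(axis=0)


def union_mask(s: RaterAnnotationSet, i: int, k: int) -> np.ndarray:
    """1(X̄_i,k > 0): thresholded mean mask == union of rater i's rounds."""
    return (mean_round_mask(s, i, k) > 0).astype(np.uint8)


def ierr_pair(s: RaterAnnotationSet, i: int, j: int,
              images: np.ndarray | None = None) -> float:
    """Inter-rater reliability of raters i and j over the given images."""
    if i == j:
        raise ValueError("inter-rater reliability needs two distinct raters")
    ks = range(s.n_images) if images is None else images
    vals = [iou(union_mask(s, i, k), union_mask(s, j, k)) for k in ks]
    if not vals:
        raise ValueError("no images to compare")
    return float(np.mean(vals))


def ierr_matrix(s: RaterAnnotationSet,
                images: np.ndarray | None = None) -> np.ndarray:
    """Symmetric N×N IeRR matrix; the diagonal is NaN (undefined)."""
    n = s.n_raters
    out = np.full((n, n), np.nan)
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = ierr_pair(s, i, j, images)
    return out


def iarr(s: RaterAnnotationSet, i: int,
         images: np.ndarray | None = None) -> float:
    """Intra-rater reliability of rater i: mean IoU over round pairs."""
    if s.n_rounds < 2:
        raise ValueError("intra-rater reliability needs at least two rounds")
    ks = list(range(s.n_images) if images is None else images)
    if not ks:
        raise ValueError("no images to compare")
    pair_means = []
    for r, t in itertools.combinations(range(s.n_rounds), 2):
        pair_means.append(np.mean([iou(s.masks[i, k, r], s.masks[i, k, t])
                                   for k in ks]))
    return float(np.mean(pair_means))


def iarr_all(s: RaterAnnotationSet,
             images: np.ndarray | None = None) -> np.ndarray:
    """IaRR for every rater."""
    return np.array([iarr(s, i, images) for i in range(s.n_raters)])


def _mean_area(s: RaterAnnotationSet, k: int) -> float:
    """Mean foreground pixel count of image k across all raters and rounds."""
    return float(np.mean([s.masks[i, k, r].sum()
                          for i in range(s.n_raters)
                          for r in range(s.n_rounds)]))


def stratify_by_area(s: RaterAnnotationSet,
                     area_edges: tuple = DEFAULT_AREA_EDGES) -> pd.DataFrame:
    """IeRR/IaRR recomputed within strata of mean segmented area.

    Images are grouped by their mean foreground pixel count across all
    raters and rounds into half-open intervals between consecutive
    edges, the last one unbounded; with the default edges (0, 20, 200)
    the strata are (0, 20), [20, 200) and [200, ∞).  Images with mean
    area 0 (unanimously closed glottis) fall outside every stratum.
    Empty strata are omitted from the table rather than reported as 0.
    """
    areas = np.array([_mean_area(s, k) for k in range(s.n_images)])
    edges = list(area_edges) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = np.nonzero((areas > lo if lo == 0 else areas >= lo)
                             & (areas < hi))[0]
        if members.size == 0:
            continue
        ie = ierr_matrix(s, members)
        ia = iarr_all(s, members) if s.n_rounds >= 2 else np.array([np.nan])
        rows.append({"area_lo": lo, "area_hi": hi, "n_images": members.size,
                     "ierr_mean": float(np.nanmean(ie)),
                     "iarr_mean": float(np.mean(ia))})
    return pd.DataFrame(rows)


def _consensus(s: RaterAnnotationSet, k: int) -> np.ndarray:
    """Majority vote over all raters and rounds for image k."""
    stack = np.stack([s.masks[i, k, r].astype(float)
                      for i in range(s.n_raters) for r in range(s.n_rounds)])
    return (stack.mean(axis=0) > 0.5).astype(np.uint8)


def agreement_vs_distance(s: RaterAnnotationSet, n_rings: int = 5,
                          reference: str = "center") -> np.ndarray:
    """Per-pixel rater agreement as a function of distance.

    For every image, each pixel's agreement is the fraction of all
    (rater, round) masks that match the majority-vote consensus there.
    Pixels are binned into ``n_rings`` rings of normalized distance and
    the mean agreement per ring is returned (averaged over images).

    ``reference='center'`` bins the pixels of the consensus support by
    distance from its centre of mass, normalized by the largest such
    distance (ring 0 = deep inside the glottal area, the last ring its
    extremities).
    ``reference='edge'`` bins by unsigned Euclidean distance from the
    consensus boundary, normalized per image (ring 0 = on the rim).
    Images with an empty consensus are skipped.
    """
    if reference not in ("center", "edge"):
        raise ValueError("reference must be 'center' or 'edge'")
    ring_sums = np.zeros(n_rings)
    ring_counts = np.zeros(n_rings)
    for k in range(s.n_images):
        cons = _consensus(s, k)
        if not cons.any():
            continue
        stack = np.stack([s.masks[i, k, r].astype(np.uint8)
                          for i in range(s.n_raters) for r in range(s.n_rounds)])
        agree = (stack == cons[None]).mean(axis=0)
        if reference == "center":
            cy, cx = ndimage.center_of_mass(cons)
            yy, xx = np.mgrid[0:cons.shape[0], 0:cons.shape[1]]
            dist = np.hypot(yy - cy, xx - cx)
            region = cons.astype(bool)  # within the glottal area only
            scale = max(dist[region].max(), 1e-9)
        else:
            inside = ndimage.distance_transform_edt(cons)
            outside = ndimage.distance_transform_edt(1 - cons)
            dist = np.where(cons > 0, inside, outside)
            scale = max(dist.max(), 1e-9)
            region = np.ones_like(cons, dtype=bool)
        rings = np.minimum((dist / scale * n_rings).astype(int), n_rings - 1)
        for ring in range(n_rings):
            sel = region & (rings == ring)
            ring_sums[ring] += agree[sel].sum()
            ring_counts[ring] += sel.sum()
    with np.errstate(invalid="ignore"):
        return np.where(ring_counts > 0, ring_sums / np.maximum(ring_counts, 1),
                        np.nan)
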