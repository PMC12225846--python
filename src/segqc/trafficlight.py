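"""Traffic-light quality tracks for segmented endoscopy videos.

Per-frame predicted IoU scores are binned into three classes — green
(good segmentation, IoU above 0.7), yellow (moderate, between 0.6 and
0.7) and red (problematic, below 0.6) — and rendered as a horizontal
colour bar, one pixel column per frame, so a clinician can spot the
stretches of a high-speed video that need human review at a glance.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .phantoms import FramePair
from .regressor import QualityModel, predict_iou

__all__ = ["TrafficLightTrack", "classify", "track_video", "render_bar"]

CLASS_COLORS = {"green": (46, 204, 64), "yellow": (255, 220, 0),
                "red": (255, 65, 54)}


def classify(iou_value: float, green_min: float = 0.7,
             red_max: float = 0.6) -> str:
    """Traffic-light class of a predicted IoU.

    green iff value > green_min; red iff value < red_max; boundary
    values (exactly red_max or green_min) count as yellow.
    """
    if red_max > green_min:
        raise ValueError(
            f"thresholds inverted: red_max {red_max} > green_min {green_min}"
        )
    if iou_value > green_min:
        return "green"
    if iou_value < red_max:
        return "red"
    return "yellow"


@dataclass
class TrafficLightTrack:
    """Per-frame predicted IoU and class for one video / mask source."""

    ious: np.ndarray
    classes: list[str]
    video_id: str = ""
    source_id: str = ""
    model_id: str = ""
    green_min: float = 0.7
    red_max: float = 0.6

    def __post_init__(self) -> None:
        if len(self.ious) != len(self.classes):
            raise ValueError("ious and classes must have equal length")

    def __len__(self) -> int:
        return len(self.ious)

    def fractions(self) -> dict[str, float]:
        n = max(len(self.classes), 1)
        return {c: self.classes.count(c) / n for c in ("green", "yellow", "red")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.ious)),
                             "iou": self.ious, "class": self.classes})


def track_video(frames: list[FramePair],
                candidate_masks: dict[str, list[np.ndarray]],
                model: QualityModel, scheme: str,
                green_min: float = 0.7, red_max: float = 0.6,
                video_id: str = "") -> dict[str, TrafficLightTrack]:
    """Score every frame against every mask source.

    ``candidate_masks`` maps a segmentation-source id (e.g. the name of
    the network that produced the masks) to its per-frame mask list,
    which must match the frame count.  Returns one track per source.
    """
    tracks = {}
    for source, masks in candidate_masks.items():
        if len(masks) != len(frames):
            raise ValueError(
                f"source {source!r} has {len(masks)} masks for "
                f"{len(frames)} frames"
            )
        ious = np.array([predict_iou(model, f, m, scheme)
                         for f, m in zip(frames, masks)])
        classes = [classify(v, green_min, red_max) for v in ious]
        tracks[source] = TrafficLightTrack(
            ious=ious, classes=classes, video_id=video_id, source_id=source,
            model_id=model.spec.backbone, green_min=green_min, red_max=red_max)
    return tracks


def render_bar(track: TrafficLightTrack, out_dir: str | os.PathLike | None = None,
               height: int = 24, max_width: int | None = None,
               ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the track as an RGB bar image plus its CSV table.

    The bar is one pixel column per frame (``height`` rows); with
    ``max_width`` set, longer tracks are down-scaled by dropping to
    every n-th frame.  With ``out_dir`` the PNG and CSV are written as
    ``trafficlight_<video>_<source>.png/.csv``.
    """
    n = len(track)
    colors = np.array([CLASS_COLORS[c] for c in track.classes]
                      or np.empty((0, 3)), dtype=np.uint8).reshape(n, 3)
    if max_width is not None and n > max_width:
        step = -(-n // max_width)
        colors = colors[::step]
    bar = np.repeat(colors[None, :, :], height, axis=0)
    table = track.to_frame()
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        stem = f"trafficlight_{track.video_id or 'video'}_{track.source_id or 'masks'}"
        if n > 0:
            iio.imwrite(os.path.join(out_dir, stem + ".png"), bar)
        table.to_csv(os.path.join(out_dir, stem + ".csv"), index=False)
    return bar, table
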