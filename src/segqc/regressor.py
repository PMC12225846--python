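"""IoU quality regression: predict segmentation quality without ground truth.

A convolutional network receives a 3-channel stack built from the
endoscopy frame and/or a candidate segmentation mask (scheme codes
``eee``/``sss``/``see``/…) and regresses the IoU the candidate mask
would score against an expert mask — so segmentation quality can be
judged on frames that have never been annotated.

The regression head is fixed: global average pooling, a 256-unit dense
layer with ReLU, dropout 0.1, and a single sigmoid output unit.
Backbones are pluggable through a registry; the default ``tiny``
backbone is a 4-block convnet sized for 64×64 inputs and CPU training.
Training runs for a configured number of epochs with SGD-momentum
(0.9, lr 1e-2) or Adam (lr 1e-3), decaying the learning rate by
``e^{-0.1}`` per epoch once past epoch 10.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .dataset import compose_input, crop_and_resize
from .metrics import rmse
from .phantoms import FramePair

__all__ = [
    "ModelSpec", "TrainSpec", "QualityModel", "BACKBONES",
    "register_backbone", "build_model", "lr_at_epoch", "compose_arrays",
    "train", "predict_iou", "evaluate_schemes", "compare_models",
]

# backbone registry: name -> builder(rng) -> (layers, output feature dim)
BACKBONES: dict[str, Callable] = {}


def register_backbone(name: str, builder: Callable) -> None:
    """Register a backbone builder: ``builder(rng) -> (layers, out_dim)``."""
    BACKBONES[name] = builder


def _tiny_backbone(rng: np.random.Generator,
                   channels: tuple = (8, 16, 32, 32)) -> tuple[list, int]:
    layers: list = []
    c_in = 3
    for c_out in channels:
        layers += [nn.Conv2D(c_in, c_out, rng), nn.ReLU(), nn.MaxPool2()]
        c_in = c_out
    return layers, c_in


register_backbone("tiny", _tiny_backbone)
register_backbone("tiny-wide",
                  lambda rng: _tiny_backbone(rng, (16, 32, 64, 64)))


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice: a registered backbone plus the fixed head."""

    backbone: str = "tiny"
    pretrained: bool = False
    input_side: int = 64
    head_units: int = 256
    head_dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; registered: "
                f"{', '.join(sorted(BACKBONES))}"
            )
        if self.pretrained:
            raise ValueError(
                f"no pretrained weights are registered for {self.backbone!r}"
            )


@dataclass(frozen=True)
class TrainSpec:
    """Optimization schedule.

    ``optimizer`` is ``sgd`` (momentum 0.9, default lr 1e-2) or ``adam``
    (default lr 1e-3).  After ``decay_after`` epochs the learning rate
    decays by a factor ``e^{-decay_rate}`` per epoch (or once, with
    ``decay_once``).  ``loss`` is one of mse / mae / bce (``xent`` is an
    alias for the soft-label binary cross-entropy).
    """

    optimizer: str = "adam"
    lr: float | None = None
    epochs: int = 50
    batch_size: int = 32
    loss: str = "bce"
    decay_after: int = 10
    decay_rate: float = 0.1
    decay_once: bool = False

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.loss not in nn.LOSSES:
            raise ValueError(f"loss must be one of {sorted(nn.LOSSES)}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def base_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        return 1e-2 if self.optimizer == "sgd" else 1e-3


def lr_at_epoch(spec: TrainSpec, epoch: int) -> float:
    """Learning rate in effect during ``epoch`` (1-based)."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    if epoch <= spec.decay_after:
        return spec.base_lr
    if spec.decay_once:
        return spec.base_lr * np.exp(-spec.decay_rate)
    return float(spec.base_lr * np.exp(-spec.decay_rate * (epoch - spec.decay_after)))


class QualityModel:
    """A backbone + fixed regression head with its metadata."""

    def __init__(self, spec: ModelSpec, seed: int) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        backbone_layers, feat = BACKBONES[spec.backbone](rng)
        self._n_backbone = len(backbone_layers)
        head = [nn.GlobalAvgPool(),
                nn.Dense(feat, spec.head_units, rng),
                nn.ReLU(),
                nn.Dropout(spec.head_dropout, np.random.default_rng(seed + 1)),
                nn.Dense(spec.head_units, 1, rng)]
        self.net = nn.Sequential(backbone_layers + head)

    @property
    def head_layers(self) -> list[str]:
        """Class names of the head, after the ReLU of the 256-unit layer
        is folded into its dense layer conceptually: [GAP, FC256, dropout, FC1]."""
        names = []
        for layer in self.net.layers[self._n_backbone:]:
            if isinstance(layer, nn.ReLU):
                continue
            names.append(type(layer).__name__)
        return names

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in (0, 1) for a batch of NCHW inputs."""
        return self.net.predict(x.astype(np.float32))

    def save(self, path: str | os.PathLike) -> None:
        meta = {"backbone": self.spec.backbone, "input_side": self.spec.input_side,
                "head_units": self.spec.head_units,
                "head_dropout": self.spec.head_dropout, "seed": self.seed}
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "QualityModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(ModelSpec(backbone=meta["backbone"],
                              input_side=meta["input_side"],
                              head_units=meta["head_units"],
                              head_dropout=meta["head_dropout"]),
                    seed=meta["seed"])
        n = len(model.net.get_weights())
        model.net.set_weights([data[f"w{i}"] for i in range(n)])
        return model


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0) -> QualityModel:
    """Instantiate a seeded model; same (spec, seed) → identical weights."""
    return QualityModel(spec, seed)


def compose_arrays(pairs: Sequence[FramePair], manifest: pd.DataFrame,
                   samples: Sequence, scheme: str,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Materialize (N, 3, S, S) inputs and IoU targets for manifest rows.

    ``samples`` is the full sample list from ``build_balanced_dataset``
    indexed by ``sample_id``; the manifest may be any row subset of it.
    """
    by_id = {}
    for idx, p in enumerate(pairs):
        by_id[p.source_id or str(idx)] = p
    xs, ys = [], []
    for _, row in manifest.iterrows():
        pair = by_id[str(row["source_id"])]
        sample = samples[int(row["sample_id"])]
        x = compose_input(pair, sample.degraded, scheme)
        xs.append(x.transpose(2, 0, 1))
        ys.append(float(row["true_iou"]))
    return (np.stack(xs).astype(np.float32),
            np.asarray(ys, dtype=np.float32))


def train(model: QualityModel, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, spec: TrainSpec,
          rng: np.random.Generator) -> pd.DataFrame:
    """Mini-batch training with per-epoch validation and best-val restore.

    Returns the history (epoch, lr, train_loss, val_loss).  The model is
    left holding the weights of the best-validation-loss epoch.  A
    non-finite loss aborts with a diagnostic.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    params = model.net.parameters()
    opt = (nn.SGDMomentum(params, momentum=0.9) if spec.optimizer == "sgd"
           else nn.Adam(params))
    loss_fn = nn.LOSSES[spec.loss]
    history = []
    best_loss, best_weights = np.inf, model.net.get_weights()
    for epoch in range(1, spec.epochs + 1):
        opt.lr = lr_at_epoch(spec, epoch)
        perm = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(perm), spec.batch_size):
            sel = perm[start:start + spec.batch_size]
            z = model.net.forward_logit(x_train[sel], train=True)
            loss, dz = loss_fn(z, y_train[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite {spec.loss} loss at epoch {epoch}, "
                    f"batch starting {start}: {loss}"
                )
            model.net.backward(dz)
            opt.step()
            epoch_loss += loss * len(sel)
        epoch_loss /= len(perm)

        val_losses = []
        for start in range(0, len(x_val), 256):
            z = model.net.forward_logit(x_val[start:start + 256], train=False)
            val_losses.append(loss_fn(z, y_val[start:start + 256])[0]
                              * len(z))
        val_loss = float(np.sum(val_losses) / len(x_val))
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": epoch_loss, "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.net.get_weights()
    model.net.set_weights(best_weights)
    return pd.DataFrame(history)


def predict_iou(model: QualityModel, pair: FramePair,
                candidate_mask: np.ndarray, scheme: str) -> float:
    """Predicted IoU for one (frame, candidate mask) pair.

    Inputs not already at the model's input size are square-cropped
    around the candidate mask and resized first.
    """
    side = model.spec.input_side
    if pair.image.shape != (side, side):
        prepped = crop_and_resize(FramePair(image=pair.image,
                                            mask=candidate_mask.astype(np.uint8),
                                            source_id=pair.source_id), side)
        pair, candidate_mask = prepped, prepped.mask
    x = compose_input(pair, candidate_mask, scheme).transpose(2, 0, 1)
    return float(model.predict(x[None])[0])


def evaluate_schemes(schemes: Sequence[str], pairs: Sequence[FramePair],
                     train_manifest: pd.DataFrame, val_manifest: pd.DataFrame,
                     test_manifest: pd.DataFrame, samples: Sequence,
                     train_spec: TrainSpec,
                     model_spec: ModelSpec = ModelSpec(),
                     seed: int = 0) -> pd.DataFrame:
    """Train one model per input scheme under identical seeds and report
    the held-out RMSE of each, one table row per scheme."""
    rows = []
    for scheme in schemes:
        model = build_model(model_spec, seed=seed)
        xt, yt = compose_arrays(pairs, train_manifest, samples, scheme)
        xv, yv = compose_arrays(pairs, val_manifest, samples, scheme)
        xe, ye = compose_arrays(pairs, test_manifest, samples, scheme)
        train(model, xt, yt, xv, yv, train_spec, np.random.default_rng(seed))
        pred = model.predict(xe)
        rows.append({"scheme": scheme, "rmse": rmse(pred, ye),
                     "n_test": len(ye)})
    return pd.DataFrame(rows)


def compare_models(rmse_samples: dict[str, Sequence[float]],
                   alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Normality screening plus pairwise rank tests between model groups.

    Each group is Shapiro–Wilk-tested for normality, then every pair of
    groups is compared with a two-sided Mann–Whitney U test; p-values
    are Bonferroni-corrected by the number of pairwise comparisons.
    Returns ``{"shapiro": ..., "pairwise": ...}`` tables.
    """
    names = list(rmse_samples)
    shapiro_rows = []
    for name in names:
        x = np.asarray(rmse_samples[name], dtype=float)
        if x.size >= 3 and np.ptp(x) > 0:
            stat, p = stats.shapiro(x)
        else:
            stat, p = np.nan, np.nan
        shapiro_rows.append({"model": name, "n": x.size, "W": stat, "p": p})

    import itertools
    pairs_list = list(itertools.combinations(names, 2))
    m = len(pairs_list)
    pairwise_rows = []
    for a, b in pairs_list:
        xa = np.asarray(rmse_samples[a], dtype=float)
        xb = np.asarray(rmse_samples[b], dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p = np.nan, 1.0  # identical constant groups: no evidence
        else:
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        p_adj = min(1.0, p * m)
        pairwise_rows.append({"model_a": a, "model_b": b, "U": u,
                              "p_raw": p, "p_bonferroni": p_adj,
                              "n_comparisons": m,
                              "significant": bool(p_adj < alpha)})
    return {"shapiro": pd.DataFrame(shapiro_rows),
            "pairwise": pd.DataFrame(pairwise_rows)}
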