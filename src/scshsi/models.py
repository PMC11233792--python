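"""Classifier assembly and training for spectral-spatial patches.

Three architectures operate on (s, s, D) patches:

* ``scs`` — the sharpened-cosine-similarity classifier: one SCS layer
  (default 32 units, kernel min(3, s), stride 1), absolute max-pooling when
  the SCS output retains spatial extent, then a softmax head. No activations
  or normalization between the SCS stage and the head.
* ``cnn2d`` — a compact CNN baseline: Conv 3x3 + ReLU, max-pool, flatten,
  dense 100 with batch normalization and ReLU, softmax head.
* ``lenet`` — the classic two-stage 5x5 conv + average-pool stack with dense
  120/84 layers and a softmax head, adapted to small patches via same-padding.

Training follows a fixed regime: Adam, softmax cross-entropy, 50 epochs,
batch size 256, learning rate 0.001 by default, with randomly initialized
weights; per-epoch train/validation loss and accuracy are recorded so
learning curves can be plotted. All randomness flows from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .hsi_io import HyperspectralCube, LabelMask
from .preprocessing import PatchSet, SplitIndices, extract_patches_full
from .scs import SCSLayerConfig

__all__ = ["ModelSpec", "TrainingConfig", "TrainedModel", "build_scs_classifier",
           "build_baseline", "train_model", "predict_labels", "predict_map",
           "MODEL_NAMES"]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("scs", "cnn2d", "lenet")


@dataclass
class ModelSpec:
    """Resolved architecture: an ordered list of layer descriptors."""

    architecture: list[dict]
    n_classes: int
    input_shape: tuple[int, int, int]
    name: str = "model"

    def instantiate(self, rng: np.random.Generator) -> nn.Sequential:
        layers: list[nn.Layer] = []
        for d in self.architecture:
            kind = d["type"]
            if kind == "scs":
                layers.append(nn.SCSLayer(
                    in_ch=d["in_ch"], n_units=d["n_units"], k=d["k"], rng=rng,
                    stride=d["stride"], q_init=d["q_init"], p_init=d["p_init"],
                    q_trainable=d["q_trainable"], p_trainable=d["p_trainable"],
                    q_floor=d["q_floor"]))
            elif kind == "conv2d":
                layers.append(nn.Conv2D(d["in_ch"], d["out_ch"], d["k"], rng,
                                        padding=d["padding"]))
            elif kind == "relu":
                layers.append(nn.ReLU())
            elif kind == "flatten":
                layers.append(nn.Flatten())
            elif kind == "dense":
                layers.append(nn.Dense(d["in_dim"], d["out_dim"], rng))
            elif kind == "batchnorm":
                layers.append(nn.BatchNorm(d["dim"]))
            elif kind == "maxpool":
                layers.append(nn.MaxPool2D(d["window"]))
            elif kind == "avgpool":
                layers.append(nn.AvgPool2D(d["window"]))
            elif kind == "absmaxpool":
                layers.append(nn.AbsMaxPool2D(d["window"]))
            else:
                raise ValueError(f"unknown layer type {kind!r}")
        return nn.Sequential(layers)


@dataclass
class TrainingConfig:
    """Optimization regime; defaults are the pipeline's standard settings."""

    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "softmax_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1, batch_size >= 1, learning_rate > 0 required")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "softmax_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class TrainedModel:
    """Weights, per-epoch history and the config that produced them."""

    spec: ModelSpec
    model: nn.Sequential
    history: pd.DataFrame
    config: TrainingConfig
    class_names: list[str] = field(default_factory=list)

    def save_history(self, path: str | Path) -> Path:
        path = Path(path)
        self.history.to_csv(path, index=False)
        return path

    def save_weights(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **self.model.get_weights())
        return path


def build_scs_classifier(input_shape: tuple[int, int, int], n_classes: int,
                         layer_cfg: SCSLayerConfig | None = None) -> ModelSpec:
    """SCS layer -> absolute max-pool (when spatial extent remains) -> softmax head."""
    s, s2, D = input_shape
    if n_classes < 2:
        raise ValueError("classification needs at least 2 classes")
    cfg = layer_cfg or SCSLayerConfig(kernel_size=min(3, s))
    k = cfg.kernel_size
    if k > min(s, s2):
        raise ValueError(f"SCS kernel {k} larger than patch {s}x{s2}")
    arch: list[dict] = [{
        "type": "scs", "in_ch": D, "n_units": cfg.n_units, "k": k,
        "stride": cfg.stride, "q_init": cfg.q_init, "p_init": cfg.p_init,
        "q_trainable": cfg.q_trainable, "p_trainable": cfg.p_trainable,
        "q_floor": cfg.q_floor,
    }]
    h = (s - k) // cfg.stride + 1
    w = (s2 - k) // cfg.stride + 1
    if min(h, w) >= 2:
        arch.append({"type": "absmaxpool", "window": 2})
        h, w = (h - 2) // 2 + 1, (w - 2) // 2 + 1
    else:
        logger.info("SCS output is %dx%d; absolute max-pool degrades to identity", h, w)
    arch.append({"type": "flatten"})
    arch.append({"type": "dense", "in_dim": h * w * cfg.n_units, "out_dim": n_classes})
    return ModelSpec(architecture=arch, n_classes=n_classes,
                     input_shape=tuple(input_shape), name="scs")


def build_baseline(name: str, input_shape: tuple[int, int, int],
                   n_classes: int) -> ModelSpec:
    """Reference CNN architectures ``cnn2d`` and ``lenet``."""
    if n_classes < 2:
        raise ValueError("classification needs at least 2 classes")
    s, s2, D = input_shape
    arch: list[dict] = []
    h, w, c = s, s2, D

    def conv(out_ch: int, k: int):
        nonlocal h, w, c
        padding = "valid" if min(h, w) >= k else "same"
        if padding == "same":
            logger.info("%s: %dx%d input smaller than %dx%d kernel; using same-padding",
                        name, h, w, k, k)
        arch.append({"type": "conv2d", "in_ch": c, "out_ch": out_ch, "k": k,
                     "padding": padding})
        if padding == "valid":
            h, w = h - k + 1, w - k + 1
        c = out_ch
        arch.append({"type": "relu"})

    def pool(kind: str):
        nonlocal h, w
        if min(h, w) >= 2:
            arch.append({"type": kind, "window": 2})
            h, w = (h - 2) // 2 + 1, (w - 2) // 2 + 1
        else:
            logger.info("%s: spatial dims %dx%d; %s degrades to identity",
                        name, h, w, kind)

    if name == "cnn2d":
        conv(32, 3)
        pool("maxpool")
        arch.append({"type": "flatten"})
        arch.append({"type": "dense", "in_dim": h * w * c, "out_dim": 100})
        arch.append({"type": "batchnorm", "dim": 100})
        arch.append({"type": "relu"})
        arch.append({"type": "dense", "in_dim": 100, "out_dim": n_classes})
    elif name == "lenet":
        conv(6, 5)
        pool("avgpool")
        conv(16, 5)
        pool("avgpool")
        arch.append({"type": "flatten"})
        arch.append({"type": "dense", "in_dim": h * w * c, "out_dim": 120})
        arch.append({"type": "relu"})
        arch.append({"type": "dense", "in_dim": 120, "out_dim": 84})
        arch.append({"type": "relu"})
        arch.append({"type": "dense", "in_dim": 84, "out_dim": n_classes})
    else:
        raise ValueError(f"unknown baseline {name!r}; choose from {MODEL_NAMES[1:]}")
    return ModelSpec(architecture=arch, n_classes=n_classes,
                     input_shape=tuple(input_shape), name=name)


def build_model(name: str, input_shape: tuple[int, int, int], n_classes: int,
                layer_cfg: SCSLayerConfig | None = None) -> ModelSpec:
    if name == "scs":
        return build_scs_classifier(input_shape, n_classes, layer_cfg)
    return build_baseline(name, input_shape, n_classes)


def _eval(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
          batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for lo in range(0, len(X), batch_size):
        xb, yb = X[lo:lo + batch_size], y[lo:lo + batch_size]
        logits = model.forward(xb, training=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_model(spec: ModelSpec, patchset: PatchSet, split: SplitIndices,
                cfg: TrainingConfig | None = None) -> TrainedModel:
    """Minimize softmax cross-entropy on the train split; track validation.

    Deterministic for a fixed seed. Raises on an empty or single-class train
    split, and on divergence (NaN loss), naming the epoch.
    """
    cfg = cfg or TrainingConfig()
    if spec.input_shape != patchset.patches.shape[1:]:
        raise ValueError(
            f"model expects patches {spec.input_shape}, got "
            f"{patchset.patches.shape[1:]}"
        )
    tr, va = split.train, split.val
    if len(tr) == 0:
        raise ValueError("train split is empty")
    y = patchset.labels
    if len(np.unique(y[tr])) < 2:
        raise ValueError("train split contains a single class; nothing to separate")
    rng = np.random.default_rng(cfg.seed)
    model = spec.instantiate(rng)
    opt = nn.Adam(model, lr=cfg.learning_rate)
    Xtr, ytr = patchset.patches[tr], y[tr]
    Xva, yva = patchset.patches[va], y[va]
    rows = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(Xtr))
        loss_sum, correct = 0.0, 0
        for lo in range(0, len(Xtr), cfg.batch_size):
            sel = perm[lo:lo + cfg.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            logits = model.forward(xb, training=True)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss}")
            model.backward(grad)
            opt.step()
            loss_sum += loss * len(xb)
            correct += int((logits.argmax(axis=1) == yb).sum())
        row = {"epoch": epoch, "train_loss": loss_sum / len(Xtr),
               "train_acc": correct / len(Xtr)}
        if len(Xva):
            row["val_loss"], row["val_acc"] = _eval(model, Xva, yva, cfg.batch_size)
        else:
            row["val_loss"], row["val_acc"] = np.nan, np.nan
        rows.append(row)
    return TrainedModel(spec=spec, model=model, history=pd.DataFrame(rows),
                        config=cfg, class_names=list(patchset.class_names))


def predict_labels(trained: TrainedModel, patches: np.ndarray,
                   batch_size: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Argmax class per patch plus the full softmax probability rows."""
    patches = np.asarray(patches, dtype=np.float64)
    if len(patches) == 0:
        return (np.array([], dtype=np.int64),
                np.zeros((0, trained.spec.n_classes)))
    if patches.shape[1:] != trained.spec.input_shape:
        raise ValueError(
            f"patch shape {patches.shape[1:]} does not match model input "
            f"{trained.spec.input_shape}"
        )
    probs = np.vstack([
        nn.softmax(trained.model.forward(patches[lo:lo + batch_size], training=False))
        for lo in range(0, len(patches), batch_size)
    ])
    return probs.argmax(axis=1), probs


def predict_map(trained: TrainedModel, cube: HyperspectralCube, s: int = 3,
                padding: str = "zero", batch_size: int = 4096) -> LabelMask:
    """Classify every pixel of the scene (patch per pixel) into a LabelMask."""
    if cube.n_bands != trained.spec.input_shape[2]:
        raise ValueError(
            f"cube has {cube.n_bands} bands; model expects "
            f"{trained.spec.input_shape[2]}"
        )
    patches = extract_patches_full(cube, s=s, padding=padding)
    labels, _ = predict_labels(trained, patches, batch_size=batch_size)
    M, N = cube.shape[:2]
    class_names = trained.class_names or [f"class_{i + 1}"
                                          for i in range(trained.spec.n_classes)]
    # predicted codes are 1..C; sentinel -1 never appears (every pixel classified)
    return LabelMask(labels=(labels + 1).reshape(M, N),
                     class_names=class_names, unlabeled_value=-1)
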