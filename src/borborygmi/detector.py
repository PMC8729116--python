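"""The compact convolutional BS/non-BS classifier.

Topology: three 3x3 convolution stages, each followed by ReLU and max
pooling along the Mel axis only (the 3-frame time axis is too narrow to
pool), then dropout, flatten, a 64-unit dense hidden layer and a 2-way
softmax.  Trained with Adadelta on cross-entropy for 30 epochs at batch
size 128.  On the 128x3 input the Mel axis shrinks 128 -> 64 -> 32 -> 16
while the 3 frames survive all stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._cnn import (
    Adadelta,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    cross_entropy_grad,
    softmax,
)
from .features import MelDataset, MelSample, PreprocessConfig


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture and training hyper-parameters."""

    conv_filters: tuple[int, int, int] = (32, 64, 64)
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 1)  # Mel axis only; never shrinks the 3 frames
    dropout_rate: float = 0.2
    dense_units: int = 64
    n_classes: int = 2
    epochs: int = 30
    batch_size: int = 128
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.pool[1] > 1:
            raise ValueError(
                "pooling along the 3-frame axis would annihilate it"
            )


@dataclass
class EvalMetrics:
    """Confusion counts and the derived proportions.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); a metric whose
    denominator is zero is reported as None (undefined), never as 0.
    ``per_subtype_accuracy`` is the fraction of subtype-tagged positive
    samples that are predicted BS.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    per_subtype_accuracy: dict[str, float] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        d = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / d if d else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
            "per_subtype_accuracy": self.per_subtype_accuracy,
        }


def _input_shape(pre: PreprocessConfig) -> tuple[int, int]:
    return (pre.n_mel, pre.frames_per_sample)


class BSDetector:
    """Trainable bowel-sound classifier over 128x3 Mel samples."""

    def __init__(self, cfg: DetectorConfig | None = None,
                 pre: PreprocessConfig | None = None):
        self.cfg = cfg or DetectorConfig()
        self.pre = pre or PreprocessConfig()
        self._rng = np.random.default_rng(self.cfg.seed)
        self.net = self._build(self._rng)
        self.history: dict[str, list[float]] = {
            "train_accuracy": [], "val_accuracy": [], "train_loss": []
        }

    def _build(self, rng: np.random.Generator) -> Sequential:
        h, w = _input_shape(self.pre)
        layers: list = []
        in_ch = 1
        for f in self.cfg.conv_filters:
            layers += [Conv2D(in_ch, f, self.cfg.kernel, rng), ReLU(),
                       MaxPool2D(self.cfg.pool)]
            ph, pw = self.cfg.pool
            if h % ph or w % pw or h // ph < 1 or w // pw < 1:
                raise ValueError(
                    f"pool {self.cfg.pool} annihilates feature map {h}x{w}"
                )
            h, w = h // ph, w // pw
            in_ch = f
        layers += [Dropout(self.cfg.dropout_rate, rng), Flatten(),
                   Dense(h * w * in_ch, self.cfg.dense_units, rng), ReLU(),
                   Dense(self.cfg.dense_units, self.cfg.n_classes, rng)]
        return Sequential(layers)

    @property
    def n_params(self) -> int:
        return self.net.n_params()

    # -- data plumbing ----------------------------------------------------

    def _as_array(self, samples) -> np.ndarray:
        if isinstance(samples, MelDataset):
            X = samples.X
        elif isinstance(samples, np.ndarray):
            X = samples
        else:  # sequence of MelSample
            X = np.stack([s.values for s in samples]) if len(samples) else \
                np.zeros((0,) + _input_shape(self.pre))
        exp = _input_shape(self.pre)
        if X.ndim != 3 or X.shape[1:] != exp:
            raise ValueError(
                f"expected input of shape (n, {exp[0]}, {exp[1]}), got {X.shape}"
            )
        return np.ascontiguousarray(X[:, :, :, None], dtype=np.float32)

    # -- training ---------------------------------------------------------

    def train(self, train_set: MelDataset, val_set: MelDataset,
              verbose: bool = False) -> dict[str, list[float]]:
        """Mini-batch Adadelta training; one val-accuracy entry per epoch."""
        for name, ds in (("train", train_set), ("validation", val_set)):
            if len(np.unique(ds.y)) < 2:
                raise ValueError(f"{name} set must contain both classes")
        Xtr = self._as_array(train_set)
        ytr = np.asarray(train_set.y, dtype=int)
        opt = Adadelta(self.net.params())
        n = Xtr.shape[0]
        bs = self.cfg.batch_size
        for epoch in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            n_correct = 0
            for i0 in range(0, n, bs):
                idx = order[i0:i0 + bs]
                logits = self.net.forward(Xtr[idx], train=True)
                loss, grad = cross_entropy_grad(logits, ytr[idx])
                self.net.backward(grad)
                opt.step()
                losses.append(loss)
                n_correct += int(np.sum(logits.argmax(axis=1) == ytr[idx]))
            tr_acc = n_correct / n  # running accuracy over training batches
            va_acc = float(np.mean(self.predict(val_set)[1] == val_set.y))
            self.history["train_loss"].append(float(np.mean(losses)))
            self.history["train_accuracy"].append(tr_acc)
            self.history["val_accuracy"].append(va_acc)
            if verbose:
                print(f"epoch {epoch + 1:3d}/{self.cfg.epochs}  "
                      f"loss {np.mean(losses):.4f}  train {tr_acc:.4f}  "
                      f"val {va_acc:.4f}")
        return self.history

    # -- inference --------------------------------------------------------

    def predict_proba(self, samples, batch_size: int = 512) -> np.ndarray:
        """P(BS) per sample, order-preserving, batch-size independent."""
        X = self._as_array(samples)
        if X.shape[0] == 0:
            return np.zeros(0)
        out = [softmax(self.net.forward(X[i:i + batch_size], train=False))[:, 1]
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out)

    def predict(self, samples, batch_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, hard labels) with the configured threshold."""
        p = self.predict_proba(samples, batch_size)
        return p, (p >= self.cfg.threshold).astype(int)

    def evaluate(self, ds: MelDataset) -> EvalMetrics:
        """Confusion-matrix metrics plus per-subtype detection accuracy."""
        if len(ds) == 0:
            raise ValueError("cannot evaluate on an empty dataset")
        _, yhat = self.predict(ds)
        y = np.asarray(ds.y, dtype=int)
        tp = int(np.sum((y == 1) & (yhat == 1)))
        tn = int(np.sum((y == 0) & (yhat == 0)))
        fp = int(np.sum((y == 0) & (yhat == 1)))
        fn = int(np.sum((y == 1) & (yhat == 0)))
        per_subtype: dict[str, float] = {}
        for sub in np.unique(ds.subtype):
            if not sub:
                continue
            mask = (ds.subtype == sub) & (y == 1)
            if mask.any():
                per_subtype[str(sub)] = float(np.mean(yhat[mask] == 1))
        return EvalMetrics(tp, tn, fp, fn, per_subtype)

    # -- serialization ----------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        """Weights (npz) + configs (JSON) so detection can verify
        featurization compatibility on load."""
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        weights = self.net.get_weights()
        np.savez(model_dir / "weights.npz",
                 **{f"p{i}": w for i, w in enumerate(weights)})
        meta = {
            "detector_config": asdict(self.cfg),
            "preprocess_config": self.pre.to_dict(),
            "n_params": self.n_params,
            "history": self.history,
        }
        (model_dir / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "BSDetector":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        dc = meta["detector_config"]
        for k in ("conv_filters", "kernel", "pool"):
            dc[k] = tuple(dc[k])
        det = cls(DetectorConfig(**dc),
                  PreprocessConfig(**meta["preprocess_config"]))
        with np.load(model_dir / "weights.npz") as z:
            det.net.set_weights([z[f"p{i}"] for i in range(len(z.files))])
        det.history = meta.get("history", det.history)
        return det


def train_val_split(ds: MelDataset, val_frac: float = 0.3,
                    seed: int = 0) -> tuple[MelDataset, MelDataset]:
    """Random stratified-ish split (shuffle then cut), seeded."""
    if not 0.0 < val_frac < 1.0:
        raise ValueError("val_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(ds))
    n_val = int(round(val_frac * len(ds)))
    return ds.subset(idx[n_val:]), ds.subset(idx[:n_val])
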