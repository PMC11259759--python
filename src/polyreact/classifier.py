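"""The transfer-learning classifier: a convolutional column over the
per-residue embedding block, fused with the assay-condition scalars (coating,
normalized concentration) and, under the location-matrix scheme, the length-4
location vector, feeding a small dense head with a single sigmoid output.

Training follows a 30-epoch Adam schedule: 10 epochs of linear warmup (from
peak/100), 10 epochs constant at the peak rate (1e-3), 10 epochs of cosine
decay to zero.  The weights with the best validation ROC AUC are retained.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score

from .embed import EmbedderSpec
from .errors import ShapeError, ValidationError
from .featurize import BatchInputs, EncodingConfig, g4s_residue_axis
from .nn import (
    Adam,
    Conv2DSame,
    Dense,
    Dropout,
    MaskedGlobalAvgPool,
    ReLU,
    bce_loss,
    sigmoid,
)

F32 = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the transfer-learning head.

    ``conv_blocks`` lists (filters, kernel, downsample) triples; each block
    is a bias-free strided convolution followed by ReLU, the stride providing
    the block's downsampling.  The column is deliberately narrow (8/16/32
    filters): the downstream signal lives in smooth per-residue statistics of
    the embedding block, and a compact column trains quickly on a single CPU
    while retaining the image-style treatment of the residue x feature plane.
    """

    feature_column: str = "conv2d_per_residue"  # or "dense_per_protein"
    conv_blocks: tuple = ((8, 3, (4, 2)), (16, 3, (2, 2)), (32, 3, (2, 2)))
    head_widths: tuple = (64, 16)
    dropout: float = 0.2
    use_location: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.feature_column not in ("conv2d_per_residue", "dense_per_protein"):
            raise ValidationError(
                f"unknown feature column {self.feature_column!r}"
            )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    warmup_epochs: int = 10
    constant_epochs: int = 10
    decay_epochs: int = 10
    peak_lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    class_weight: Optional[dict] = None

    def __post_init__(self):
        if self.warmup_epochs + self.constant_epochs + self.decay_epochs != self.epochs:
            raise ValidationError("warmup + constant + decay must equal epochs")


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate of the warmup/constant/cosine schedule at *epoch*."""
    if not 0 <= epoch < cfg.epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {cfg.epochs})")
    lo = cfg.peak_lr / 100.0
    if epoch < cfg.warmup_epochs:
        if cfg.warmup_epochs == 1:
            return cfg.peak_lr
        return lo + (cfg.peak_lr - lo) * epoch / (cfg.warmup_epochs - 1)
    if epoch < cfg.warmup_epochs + cfg.constant_epochs:
        return cfg.peak_lr
    d = epoch - cfg.warmup_epochs - cfg.constant_epochs
    return cfg.peak_lr * 0.5 * (1.0 + math.cos(math.pi * d / cfg.decay_epochs))


class PolyreactivityModel:
    """Multi-input network mapping BatchInputs to P(polyreactive)."""

    def __init__(self, net: NetworkConfig, input_height: int, feature_dim: int):
        self.net = net
        self.input_height = input_height
        self.feature_dim = feature_dim
        rng = np.random.default_rng(net.seed)
        self._dropout_rng = np.random.default_rng([net.seed, 1])

        self.blocks = []
        if net.feature_column == "conv2d_per_residue":
            c_in = 1
            for filters, kernel, stride in net.conv_blocks:
                self.blocks.append(
                    (Conv2DSame(c_in, filters, kernel, rng, stride=tuple(stride)),
                     ReLU())
                )
                c_in = filters
            self.gap = MaskedGlobalAvgPool()
            feat_dim = c_in
        else:
            self.gap = None
            feat_dim = feature_dim
        head_in = feat_dim + 2 + (4 if net.use_location else 0)
        self.head = []
        for w in net.head_widths:
            self.head.append((Dense(head_in, w, rng), ReLU()))
            head_in = w
        self.dropout = Dropout(net.dropout, self._dropout_rng)
        # zero-initialised output unit: an untrained model predicts 0.5
        self.out = Dense(head_in, 1, rng, zero_init=True)
        self._cache = None

    # -- parameter plumbing ----------------------------------------------
    def params(self):
        out = []
        for conv, _ in self.blocks:
            out.extend(conv.params())
        for dense, _ in self.head:
            out.extend(dense.params())
        out.extend(self.out.params())
        return out

    def grads(self):
        out = []
        for conv, _ in self.blocks:
            out.extend(conv.grads())
        for dense, _ in self.head:
            out.extend(dense.grads())
        out.extend(self.out.grads())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    # -- forward / backward ----------------------------------------------
    def _check(self, batch: BatchInputs) -> None:
        expect_h = self.input_height if self.net.feature_column == "conv2d_per_residue" else 1
        if batch.x1.ndim != 3 or batch.x1.shape[1:] != (expect_h, self.feature_dim):
            raise ShapeError(
                f"input1 shape {batch.x1.shape[1:]} does not match the model's "
                f"({expect_h}, {self.feature_dim})"
            )
        if self.net.use_location and batch.x4 is None:
            raise ShapeError("model is wired for input4 but none was provided")

    def forward(self, batch: BatchInputs, training: bool = False) -> np.ndarray:
        self._check(batch)
        B = len(batch)
        if self.net.feature_column == "conv2d_per_residue":
            h = batch.x1[..., None].astype(F32)
            mask = np.any(batch.x1 != 0, axis=2)
            for conv, relu in self.blocks:
                h = relu.forward(conv.forward(h))
                mask = Conv2DSame.downsample_mask(mask, conv.stride[0], conv.k)
            feat = self.gap.forward(h, mask)
        else:
            feat = batch.x1.reshape(B, -1).astype(F32)
        extras = [batch.x2.astype(F32)[:, None], batch.x3.astype(F32)[:, None]]
        if self.net.use_location:
            extras.append(batch.x4.astype(F32))
        z = np.concatenate([feat] + extras, axis=1)
        self._feat_dim_cached = feat.shape[1]
        for i, (dense, relu) in enumerate(self.head):
            z = relu.forward(dense.forward(z))
            if i == 0:
                z = self.dropout.forward(z, training)
        logit = self.out.forward(z)[:, 0]
        self._logit = logit
        return sigmoid(logit)

    def backward(self, dlogit: np.ndarray) -> None:
        dz = self.out.backward(dlogit[:, None])
        for i, (dense, relu) in enumerate(reversed(self.head)):
            if i == len(self.head) - 1:  # dropout sits after the first block
                dz = self.dropout.backward(dz)
            dz = relu.backward(dz)
            dz = dense.backward(dz)
        dfeat = dz[:, : self._feat_dim_cached]
        if self.net.feature_column == "conv2d_per_residue":
            dh = self.gap.backward(dfeat.astype(F32))
            for conv, relu in reversed(self.blocks):
                dh = conv.backward(relu.backward(dh))


def build_model(
    net: NetworkConfig,
    embedder_spec: EmbedderSpec,
    encoding: EncodingConfig,
) -> PolyreactivityModel:
    """Construct the model with shapes implied by embedder and encoding."""
    if net.feature_column == "conv2d_per_residue":
        if encoding.scheme == "location_matrix":
            height = encoding.residue_axis
        else:
            height = g4s_residue_axis(encoding)
    else:
        height = 1
    if encoding.scheme == "g4s" and net.use_location:
        raise ShapeError(
            "the G4S scheme produces no location vector; build the model "
            "with use_location=False"
        )
    return PolyreactivityModel(net, height, embedder_spec.feature_dim)


def train(
    model: PolyreactivityModel,
    train_set: BatchInputs,
    val_set: BatchInputs,
    cfg: TrainConfig,
) -> tuple[PolyreactivityModel, dict]:
    """Fit with minibatch Adam under the warmup/constant/cosine schedule.

    Returns the model carrying the best-validation-AUC weights, plus a
    history dict with per-epoch learning rate, training loss and val AUC.
    """
    y = train_set.y
    if y is None or val_set.y is None:
        raise ValidationError("train and validation sets must carry labels")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValidationError("training set contains a single class")

    weights = None
    if cfg.class_weight is not None:
        weights = np.where(y == 1, cfg.class_weight.get(1, 1.0),
                           cfg.class_weight.get(0, 1.0)).astype(F32)

    optimizer = Adam(model.params())
    shuffle_rng = np.random.default_rng([cfg.seed, 7])
    history: dict = {"epoch": [], "lr": [], "train_loss": [], "val_auc": []}
    best_auc, best_weights = -np.inf, None
    n = len(train_set)
    for epoch in range(cfg.epochs):
        lr = lr_at(epoch, cfg)
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            mb = train_set.take(idx)
            probs = model.forward(mb, training=True)
            w = weights[idx] if weights is not None else None
            loss = bce_loss(probs, mb.y, w)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}; "
                    f"lr={lr:.2e}"
                )
            losses.append(loss)
            dlogit = (probs - mb.y).astype(F32)
            if w is not None:
                dlogit *= w / w.mean()
            dlogit /= F32(len(idx))
            model.backward(dlogit)
            optimizer.step(model.grads(), lr)
        val_probs = predict(model, val_set)
        val_auc = float(roc_auc_score(val_set.y, val_probs))
        history["epoch"].append(epoch)
        history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_auc"].append(val_auc)
        if val_auc > best_auc:
            best_auc = val_auc
            best_weights = model.get_weights()
    if best_weights is not None:
        model.set_weights(best_weights)
    history["best_val_auc"] = best_auc
    return model, history


def predict(model: PolyreactivityModel, inputs: BatchInputs,
            batch_size: int = 256) -> np.ndarray:
    """Probabilities of the polyreactive class, batch order preserved."""
    out = []
    for start in range(0, len(inputs), batch_size):
        mb = inputs.take(slice(start, start + batch_size))
        out.append(model.forward(mb, training=False))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: PolyreactivityModel, directory,
                    embedder_spec: EmbedderSpec, encoding: EncodingConfig,
                    extra: Optional[dict] = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(model.get_weights())})
    sidecar = {
        "network": asdict(model.net),
        "embedder": asdict(embedder_spec),
        "encoding": asdict(encoding),
        "input_height": model.input_height,
        "feature_dim": model.feature_dim,
    }
    if extra:
        sidecar["extra"] = extra
    (directory / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(directory) -> tuple[PolyreactivityModel, dict]:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    net_d = dict(sidecar["network"])
    net_d["conv_blocks"] = tuple(
        (f, k, tuple(p)) for f, k, p in net_d["conv_blocks"]
    )
    net_d["head_widths"] = tuple(net_d["head_widths"])
    net = NetworkConfig(**net_d)
    model = PolyreactivityModel(
        net, sidecar["input_height"], sidecar["feature_dim"]
    )
    with np.load(directory / "weights.npz") as npz:
        model.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
    return model, sidecar
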