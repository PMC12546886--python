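"""The dual-branch multi-task surrogate.

A small CNN digests a 64x64x3 seed image down to a 2048-dim vector (two
conv/pool stages, then a 1x1 projection to 8 channels before flattening);
a two-layer LSTM with attention pooling digests the 50x128 treatment
sensor sequence to 128 dims.  The 2176-dim fused vector feeds a hidden
dense layer and an 8-target linear head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import (
    DTYPE,
    Adam,
    AttentionPoolLayer,
    Conv2D,
    Dense,
    LSTM,
    MaxPool2x2,
    Param,
    ReLU,
)


@dataclass(frozen=True)
class NetworkConfig:
    image_shape: tuple = (64, 64, 3)
    sequence_shape: tuple = (50, 128)
    conv_channels: tuple = (32, 64)
    projection_channels: int = 8
    lstm_hidden: tuple = (256, 128)
    fc_hidden: int = 512
    n_targets: int = 8
    attention_dk: int = 128

    @property
    def cnn_feature_dim(self) -> int:
        h, w, _ = self.image_shape
        return (h // 4) * (w // 4) * self.projection_channels

    @property
    def fusion_dim(self) -> int:
        return self.cnn_feature_dim + self.lstm_hidden[1]


@dataclass(frozen=True)
class TaskWeights:
    weights: tuple
    lambda_reg: float = 1e-4

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("task weights must be non-negative")


@dataclass(frozen=True)
class TrainingSchedule:
    lr_min: float = 1e-4
    lr_max: float = 1e-2
    cycle: int = 200
    max_epochs: int = 10
    clip_norm: float = 1.0
    batch_size: int = 64
    split_fractions: tuple = (0.70, 0.15, 0.15)
    rng_seed: int = 0
    lambda_reg: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.lr_min < self.lr_max):
            raise ValueError("require 0 < lr_min < lr_max")
        if self.cycle < 1:
            raise ValueError("cycle must be >= 1")


def cyclical_lr(t: int, sched: TrainingSchedule) -> float:
    """Triangular schedule: peaks lr_max at even multiples of ``cycle``,
    troughs lr_min at odd ones; period 2*cycle."""
    if t < 0:
        raise ValueError("t must be non-negative")
    k = round(t / (2.0 * sched.cycle))
    frac = max(0.0, 1.0 - abs(t - 2.0 * k * sched.cycle) / sched.cycle)
    return sched.lr_min + (sched.lr_max - sched.lr_min) * frac


def multitask_loss(
    preds: np.ndarray,
    targets: np.ndarray,
    tw: TaskWeights,
    params: Sequence[Param] = (),
) -> float:
    """Weighted per-task MSE plus L2 penalty on the parameters."""
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape:
        raise ValueError("prediction/target shape mismatch")
    mse = np.mean((preds - targets) ** 2, axis=0)
    loss = float(np.dot(np.asarray(tw.weights), mse))
    if tw.lambda_reg:
        loss += tw.lambda_reg * sum(float((p.value**2).sum()) for p in params)
    return loss


class CnnLstmSurrogate:
    """Image + sequence fusion network with 8 regression heads."""

    def __init__(self, cfg: NetworkConfig = NetworkConfig(), rng_seed: int = 0):
        h, w, _ = cfg.image_shape
        if h % 4 or w % 4:
            raise ValueError("image height/width must be divisible by 4 (two 2x2 pools)")
        if cfg.n_targets < 1 or cfg.lstm_hidden[1] < 1:
            raise ValueError("inconsistent network configuration")
        self.cfg = cfg
        rng = np.random.default_rng(rng_seed)
        c_in = cfg.image_shape[2]
        self.conv1 = Conv2D(c_in, cfg.conv_channels[0], 3, rng)
        self.relu1 = ReLU()
        self.pool1 = MaxPool2x2()
        self.conv2 = Conv2D(cfg.conv_channels[0], cfg.conv_channels[1], 3, rng)
        self.relu2 = ReLU()
        self.pool2 = MaxPool2x2()
        self.proj = Conv2D(cfg.conv_channels[1], cfg.projection_channels, 1, rng)
        self.lstm1 = LSTM(cfg.sequence_shape[1], cfg.lstm_hidden[0], rng)
        self.lstm2 = LSTM(cfg.lstm_hidden[0], cfg.lstm_hidden[1], rng)
        self.attn = AttentionPoolLayer(cfg.lstm_hidden[1], cfg.attention_dk, rng)
        self.fc1 = Dense(cfg.fusion_dim, cfg.fc_hidden, rng)
        self.relu3 = ReLU()
        self.head = Dense(cfg.fc_hidden, cfg.n_targets, rng)
        self._shapes: dict = {}
        # per-channel sequence standardization (set from training data);
        # raw sensor channels span very different scales
        self.seq_mu = np.zeros(cfg.sequence_shape[1], dtype=DTYPE)
        self.seq_sigma = np.ones(cfg.sequence_shape[1], dtype=DTYPE)

    def set_sequence_normalizer(self, mu: np.ndarray, sigma: np.ndarray) -> None:
        self.seq_mu = np.asarray(mu, dtype=DTYPE)
        self.seq_sigma = np.where(np.asarray(sigma) > 1e-6, sigma, 1.0).astype(DTYPE)

    def params(self) -> list[Param]:
        out = []
        for layer in (
            self.conv1,
            self.conv2,
            self.proj,
            self.lstm1,
            self.lstm2,
            self.attn,
            self.fc1,
            self.head,
        ):
            out.extend(layer.params())
        return out

    def forward(self, images: np.ndarray, seqs: np.ndarray) -> np.ndarray:
        images = np.ascontiguousarray(images, dtype=DTYPE)
        seqs = np.ascontiguousarray(seqs, dtype=DTYPE)
        if images.shape[1:] != tuple(self.cfg.image_shape):
            raise ValueError(f"image batch must be (N, {self.cfg.image_shape})")
        if seqs.shape[1:] != tuple(self.cfg.sequence_shape):
            raise ValueError(f"sequence batch must be (N, {self.cfg.sequence_shape})")
        n = images.shape[0]

        a = self.relu1.forward(self.conv1.forward(images))
        self._shapes["conv1"] = a.shape[1:]
        a = self.pool1.forward(a)
        self._shapes["pool1"] = a.shape[1:]
        a = self.relu2.forward(self.conv2.forward(a))
        self._shapes["conv2"] = a.shape[1:]
        a = self.pool2.forward(a)
        self._shapes["pool2"] = a.shape[1:]
        a = self.proj.forward(a)
        img_feat = a.reshape(n, -1)
        self._shapes["cnn_feature"] = img_feat.shape[1:]

        seqs = (seqs - self.seq_mu) / self.seq_sigma
        h1 = self.lstm1.forward(seqs)
        self._shapes["lstm1"] = h1.shape[1:]
        h2 = self.lstm2.forward(h1)
        self._shapes["lstm2"] = h2.shape[1:]
        seq_feat = self.attn.forward(h2)

        fused = np.concatenate([img_feat, seq_feat], axis=1)
        self._shapes["fusion"] = fused.shape[1:]
        z = self.relu3.forward(self.fc1.forward(fused))
        self._shapes["fc1"] = z.shape[1:]
        out = self.head.forward(z)
        self._shapes["output"] = out.shape[1:]
        self._img_dim = img_feat.shape[1]
        return out

    def backward(self, dout: np.ndarray) -> None:
        dz = self.head.backward(np.ascontiguousarray(dout, dtype=DTYPE))
        dfused = self.fc1.backward(self.relu3.backward(dz))
        dimg = dfused[:, : self._img_dim]
        dseq = dfused[:, self._img_dim :]

        dh2 = self.attn.backward(np.ascontiguousarray(dseq))
        dh1 = self.lstm2.backward(dh2)
        self.lstm1.backward(dh1, need_dx=False)

        n = dimg.shape[0]
        h, w, _ = self.cfg.image_shape
        da = dimg.reshape(n, h // 4, w // 4, self.cfg.projection_channels)
        da = self.proj.backward(np.ascontiguousarray(da))
        da = self.relu2.backward(self.pool2.backward(da))
        da = self.conv2.backward(da)
        da = self.relu1.backward(self.pool1.backward(da))
        self.conv1.backward(da, need_dx=False)

    def activation_shapes(self) -> dict:
        """Intermediate shapes recorded on the most recent forward pass."""
        return dict(self._shapes)

    @property
    def fusion_dim(self) -> int:
        return self.cfg.fusion_dim


def make_optimizer(model: CnnLstmSurrogate, weight_decay: float = 0.0) -> Adam:
    return Adam(model.params(), weight_decay=weight_decay)
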