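"""Training loop, leakage-safe splitting, metrics, and permutation
attribution for the fusion surrogate."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CnnLstmSurrogate, TaskWeights, TrainingSchedule, cyclical_lr, multitask_loss
from .nn import Adam, clip_gradients

log = logging.getLogger(__name__)

TARGET_NAMES = (
    "germination_pct",
    "vigor_index",
    "t50",
    "k",
    "seedling_cm",
    "root_cm",
    "moisture",
    "conductivity",
)


@dataclass
class SurrogateBatch:
    """Paired (image, sequence, target) records plus split metadata."""

    images: np.ndarray  # (N, 64, 64, 3)
    sequences: np.ndarray  # (N, 50, 128)
    targets: np.ndarray  # (N, 8)
    batch_ids: np.ndarray  # (N,) str/int batch labels
    records: Optional[pd.DataFrame] = None  # variety / treatment cell per record

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, idx: np.ndarray) -> "SurrogateBatch":
        return SurrogateBatch(
            images=self.images[idx],
            sequences=self.sequences[idx],
            targets=self.targets[idx],
            batch_ids=self.batch_ids[idx],
            records=None if self.records is None else self.records.iloc[idx].reset_index(drop=True),
        )


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(math.floor(v)) for v in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: -(raw[i] - base[i]))
    for i in order[:rem]:
        base[i] += 1
    return base


def split_dataset(
    records: pd.DataFrame,
    sched: TrainingSchedule,
    batch_col: str = "batch_id",
    strata_cols: Sequence[str] = ("variety",),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch-level 70/15/15 split: whole batches go to one partition only
    (largest-remainder counts), allocated stratum-by-stratum so variety and
    treatment proportions stay close to global.  Returns record-index
    arrays (train, val, test)."""
    batches = records[[batch_col, *strata_cols]].drop_duplicates(batch_col)
    n_batches = len(batches)
    if n_batches < 3:
        raise ValueError("need at least 3 batches to split")
    quotas = _largest_remainder(n_batches, sched.split_fractions)
    remaining = list(quotas)
    rng = np.random.default_rng(sched.rng_seed)

    assignment: dict = {}
    for _, stratum in batches.groupby(list(strata_cols), sort=True):
        ids = stratum[batch_col].tolist()
        rng.shuffle(ids)
        for bid in ids:
            # fill the partition currently furthest below its quota share
            deficits = [
                (remaining[p] / quotas[p]) if quotas[p] else -1.0 for p in range(3)
            ]
            p = int(np.argmax(deficits))
            assignment[bid] = p
            remaining[p] -= 1

    parts: list[list[int]] = [[], [], []]
    for i, bid in enumerate(records[batch_col].to_numpy()):
        parts[assignment[bid]].append(i)
    return tuple(np.asarray(p, dtype=int) for p in parts)


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def _predict(model: CnnLstmSurrogate, batch: SurrogateBatch, bs: int = 128) -> np.ndarray:
    outs = []
    for start in range(0, len(batch), bs):
        sl = slice(start, start + bs)
        outs.append(model.forward(batch.images[sl], batch.sequences[sl]))
    return np.concatenate(outs, axis=0)


def train_surrogate(
    model: CnnLstmSurrogate,
    fixtures: SurrogateBatch,
    sched: TrainingSchedule,
    task_weights: Optional[TaskWeights] = None,
    early_stop_r2: Optional[float] = None,
    monitor_tasks: tuple = (0, 1),
) -> tuple[CnnLstmSurrogate, dict]:
    """Train with the weighted multi-task loss, triangular cyclical
    learning rate and global-norm gradient clipping.

    Targets are z-scored on the training partition.  Returns the model and
    a metrics dict with per-epoch losses, per-task test MSE/R2 and the
    split manifest.  Reproducible for a given ``sched.rng_seed``.
    """
    n_tasks = fixtures.targets.shape[1]
    tw = task_weights or TaskWeights(weights=(1.0 / n_tasks,) * n_tasks, lambda_reg=sched.lambda_reg)
    records = fixtures.records
    if records is None:
        records = pd.DataFrame({"batch_id": fixtures.batch_ids, "variety": "all"})
    train_idx, val_idx, test_idx = split_dataset(records, sched)
    train, val, test = (fixtures.subset(i) for i in (train_idx, val_idx, test_idx))

    mu = train.targets.mean(axis=0)
    sigma = train.targets.std(axis=0)
    sigma = np.where(sigma > 1e-9, sigma, 1.0)
    # standardize sensor channels on training statistics (stored in the
    # model so inference sees the same transform)
    model.set_sequence_normalizer(
        train.sequences.mean(axis=(0, 1)), train.sequences.std(axis=(0, 1))
    )

    def z(y):
        return (y - mu) / sigma

    optim = Adam(model.params(), weight_decay=tw.lambda_reg)
    rng = np.random.default_rng(sched.rng_seed)
    w = np.asarray(tw.weights)
    step = 0
    history = {"train_loss": [], "val_loss": [], "val_r2": []}
    for epoch in range(sched.max_epochs):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(train), sched.batch_size):
            idx = order[start : start + sched.batch_size]
            preds = model.forward(train.images[idx], train.sequences[idx])
            tz = z(train.targets[idx])
            loss = multitask_loss(preds, tz, tw, model.params())
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: loss={loss}"
                )
            dpred = 2.0 * w[None, :] * (preds - tz) / len(idx)
            optim.zero_grad()
            model.backward(dpred.astype(np.float32))
            clip_gradients(model.params(), sched.clip_norm)
            optim.step(cyclical_lr(step, sched))
            epoch_loss += loss
            n_batches += 1
            step += 1
        val_pred = _predict(model, val)
        vz = z(val.targets)
        val_loss = multitask_loss(val_pred, vz, tw, model.params())
        val_r2 = [r2_score(vz[:, j], val_pred[:, j]) for j in range(n_tasks)]
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(float(val_loss))
        history["val_r2"].append(val_r2)
        log.info("epoch %d: train %.4f val %.4f", epoch, history["train_loss"][-1], val_loss)
        if early_stop_r2 is not None and all(val_r2[j] >= early_stop_r2 for j in monitor_tasks):
            break

    test_pred = _predict(model, test)
    tz = z(test.targets)
    per_task = [
        {
            "name": TARGET_NAMES[j] if j < len(TARGET_NAMES) else f"task_{j}",
            "mse": float(np.mean((tz[:, j] - test_pred[:, j]) ** 2)),
            "r2": r2_score(tz[:, j], test_pred[:, j]),
        }
        for j in range(n_tasks)
    ]
    metrics = {
        "per_task": per_task,
        "history": history,
        "epochs_run": len(history["train_loss"]),
        "target_mu": mu.tolist(),
        "target_sigma": sigma.tolist(),
        "split": {
            "train_batches": sorted(set(map(str, train.batch_ids))),
            "val_batches": sorted(set(map(str, val.batch_ids))),
            "test_batches": sorted(set(map(str, test.batch_ids))),
        },
    }
    return model, metrics


def permutation_attribution(
    model: CnnLstmSurrogate,
    batch: SurrogateBatch,
    feature_groups: dict[str, Sequence[int]],
    rng_seed: int = 0,
    task_weights: Optional[TaskWeights] = None,
) -> dict[str, float]:
    """Group importance = increase in multi-task loss when the group's
    sequence channels are permuted across records; normalized to sum 1."""
    n_tasks = batch.targets.shape[1]
    tw = task_weights or TaskWeights(weights=(1.0 / n_tasks,) * n_tasks, lambda_reg=0.0)
    n_channels = batch.sequences.shape[2]
    for name, channels in feature_groups.items():
        if any(c < 0 or c >= n_channels for c in channels):
            raise KeyError(f"unknown channel in group {name!r}")

    mu = batch.targets.mean(axis=0)
    sigma = np.where(batch.targets.std(axis=0) > 1e-9, batch.targets.std(axis=0), 1.0)
    tz = (batch.targets - mu) / sigma
    base = multitask_loss(_predict(model, batch), tz, tw)
    rng = np.random.default_rng(rng_seed)
    raw = {}
    for name, channels in feature_groups.items():
        seqs = batch.sequences.copy()
        perm = rng.permutation(len(batch))
        for c in channels:
            seqs[:, :, c] = seqs[perm][:, :, c]
        shuffled = SurrogateBatch(batch.images, seqs, batch.targets, batch.batch_ids)
        raw[name] = max(0.0, multitask_loss(_predict(model, shuffled), tz, tw) - base)
    total = sum(raw.values())
    if total <= 0:
        return {name: 1.0 / len(raw) for name in raw}
    return {name: v / total for name, v in raw.items()}
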