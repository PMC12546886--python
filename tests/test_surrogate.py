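import math

import numpy as np
import pandas as pd
import pytest

from emseed.surrogate import (
    CnnLstmSurrogate,
    NetworkConfig,
    SurrogateBatch,
    TaskWeights,
    TrainingSchedule,
    attention_pool,
    attention_weights,
    cyclical_lr,
    multitask_loss,
    permutation_attribution,
    r2_score,
    split_dataset,
    train_surrogate,
)
from emseed.surrogate.nn import Conv2D, Param

TINY = NetworkConfig(
    image_shape=(16, 16, 3),
    sequence_shape=(10, 16),
    conv_channels=(8, 16),
    projection_channels=4,
    lstm_hidden=(32, 24),
    fc_hidden=64,
    n_targets=8,
    attention_dk=24,
)


def _tiny_batch(n=60, rng_seed=0, noiseless=True):
    """Synthetic records whose targets are simple functions of the inputs."""
    rng = np.random.default_rng(rng_seed)
    images = rng.random((n, 16, 16, 3)).astype(np.float32)
    seqs = rng.random((n, 10, 16)).astype(np.float32)
    sig = seqs[:, :, 0].mean(axis=1)
    targets = np.column_stack(
        [sig * 10, images.mean(axis=(1, 2, 3)) * 5] + [sig * (j + 1) for j in range(6)]
    )
    if not noiseless:
        targets = rng.standard_normal(targets.shape)
    batch_ids = np.array([f"b{i % 12}" for i in range(n)])
    records = pd.DataFrame({"batch_id": batch_ids, "variety": ["v"] * n})
    return SurrogateBatch(images, seqs, targets, batch_ids, records)


class TestAttentionPool:
    def test_equal_scores_is_mean(self):
        F = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = attention_pool(F, np.zeros(3))
        assert np.allclose(out, F.mean(axis=0))

    def test_saturation(self):
        F = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = attention_pool(F, np.array([0.0, 50.0]))
        assert np.allclose(out, F[1], atol=1e-8)

    def test_softmax_weights_oracle(self):
        w = attention_weights(np.array([0.0, math.log(3.0)]), d_k=1)
        assert np.allclose(w, [0.25, 0.75])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        w = attention_weights(rng.standard_normal((5, 7)), d_k=4)
        assert np.allclose(w.sum(axis=-1), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            attention_pool(np.empty((0, 3)), np.empty(0))


class TestMultitaskLoss:
    def test_perfect_prediction_zero(self):
        p = np.random.rand(10, 2)
        tw = TaskWeights(weights=(0.5, 0.5), lambda_reg=0.0)
        assert multitask_loss(p, p, tw) == 0.0

    def test_single_task_plain_mse(self):
        rng = np.random.default_rng(0)
        p, t = rng.random((20, 1)), rng.random((20, 1))
        tw = TaskWeights(weights=(1.0,), lambda_reg=0.0)
        assert multitask_loss(p, t, tw) == pytest.approx(np.mean((p - t) ** 2))

    def test_weighted_combination(self):
        # MSEs (2, 4) with weights (0.5, 0.5) -> 3
        t = np.zeros((2, 2))
        p = np.array([[math.sqrt(2.0), 2.0], [-math.sqrt(2.0), -2.0]])
        tw = TaskWeights(weights=(0.5, 0.5), lambda_reg=0.0)
        assert multitask_loss(p, t, tw) == pytest.approx(3.0)

    def test_regularization_at_perfect_prediction(self):
        p = np.zeros((5, 1))
        params = [Param(np.array([2.0, 1.0]))]
        tw = TaskWeights(weights=(1.0,), lambda_reg=0.1)
        assert multitask_loss(p, p, tw, params) == pytest.approx(0.1 * 5.0)


class TestCyclicalLr:
    SCHED = TrainingSchedule(lr_min=1e-4, lr_max=1e-2, cycle=200)

    def test_peak_at_zero(self):
        assert cyclical_lr(0, self.SCHED) == pytest.approx(1e-2)

    def test_trough_at_cycle(self):
        assert cyclical_lr(200, self.SCHED) == pytest.approx(1e-4)

    def test_midpoint(self):
        assert cyclical_lr(100, self.SCHED) == pytest.approx((1e-2 + 1e-4) / 2)

    def test_periodicity(self):
        for t in range(0, 1000, 37):
            assert cyclical_lr(t, self.SCHED) == pytest.approx(cyclical_lr(t + 400, self.SCHED))

    def test_within_bounds(self):
        lrs = [cyclical_lr(t, self.SCHED) for t in range(1200)]
        assert min(lrs) >= 1e-4 and max(lrs) <= 1e-2


class TestSplitDataset:
    def _records(self, n_batches=20, per_batch=10):
        rows = []
        for b in range(n_batches):
            for _ in range(per_batch):
                rows.append({"batch_id": f"b{b:02d}", "variety": f"v{b % 2}"})
        return pd.DataFrame(rows)

    def test_partition_sizes_largest_remainder(self):
        sched = TrainingSchedule(rng_seed=0)
        tr, va, te = split_dataset(self._records(20), sched)
        batches = lambda idx: set(self._records(20).iloc[idx]["batch_id"])
        assert (len(batches(tr)), len(batches(va)), len(batches(te))) == (14, 3, 3)

    def test_no_batch_leakage(self):
        recs = self._records(20)
        tr, va, te = split_dataset(recs, TrainingSchedule(rng_seed=1))
        b = [set(recs.iloc[i]["batch_id"]) for i in (tr, va, te)]
        assert not (b[0] & b[1]) and not (b[0] & b[2]) and not (b[1] & b[2])

    def test_stratification_balance(self):
        from scipy.stats import chi2_contingency

        recs = self._records(40)
        tr, va, te = split_dataset(recs, TrainingSchedule(rng_seed=2))
        table = []
        for idx in (tr, va, te):
            sub = recs.iloc[idx]
            table.append([np.sum(sub["variety"] == "v0"), np.sum(sub["variety"] == "v1")])
        _, p, _, _ = chi2_contingency(np.array(table))
        assert p > 0.05

    def test_too_few_batches_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._records(2), TrainingSchedule())


class TestNetwork:
    def test_forward_smoke_and_shapes(self):
        model = CnnLstmSurrogate(NetworkConfig(), rng_seed=0)
        out = model.forward(np.zeros((2, 64, 64, 3)), np.zeros((2, 50, 128)))
        assert out.shape == (2, 8)
        assert np.all(np.isfinite(out))
        shapes = model.activation_shapes()
        assert shapes["conv1"] == (64, 64, 32)
        assert shapes["pool1"] == (32, 32, 32)
        assert shapes["conv2"] == (32, 32, 64)
        assert shapes["pool2"] == (16, 16, 64)
        assert shapes["lstm1"] == (50, 256)
        assert shapes["lstm2"] == (50, 128)
        assert shapes["fusion"] == (2176,)
        assert shapes["fc1"] == (512,)
        assert shapes["output"] == (8,)

    def test_fusion_dimension(self):
        assert NetworkConfig().fusion_dim == 2176

    def test_identity_1x1_conv(self):
        rng = np.random.default_rng(0)
        conv = Conv2D(3, 3, 1, rng)
        conv.W.value = np.eye(3, dtype=np.float32)
        conv.b.value[:] = 0.0
        x = rng.random((2, 8, 8, 3)).astype(np.float32)
        assert np.allclose(conv.forward(x), x)

    def test_conv_matches_double_loop(self):
        # direct summation oracle for the convolution definition
        rng = np.random.default_rng(1)
        conv = Conv2D(2, 3, 3, rng)
        x = rng.random((1, 5, 5, 2)).astype(np.float32)
        got = conv.forward(x)
        W = conv.W.value.reshape(3, 3, 2, 3)
        xp = np.pad(x[0], ((1, 1), (1, 1), (0, 0)))
        for i in range(5):
            for j in range(5):
                for co in range(3):
                    acc = conv.b.value[co]
                    for m in range(3):
                        for n in range(3):
                            for ci in range(2):
                                acc += xp[i + m, j + n, ci] * W[m, n, ci, co]
                    assert got[0, i, j, co] == pytest.approx(acc, rel=1e-4)

    def test_gradient_check(self):
        # finite-difference check of the full backward pass on a tiny net
        model = CnnLstmSurrogate(TINY, rng_seed=3)
        rng = np.random.default_rng(0)
        img = rng.random((2, 16, 16, 3)).astype(np.float32)
        seq = rng.random((2, 10, 16)).astype(np.float32)
        tgt = rng.random((2, 8)).astype(np.float32)

        def loss():
            p = model.forward(img, seq)
            return float(np.mean((p - tgt) ** 2))

        preds = model.forward(img, seq)
        for p in model.params():
            p.zero_grad()
        model.backward((2.0 * (preds - tgt) / (preds.size)).astype(np.float32))

        rng_idx = np.random.default_rng(7)
        checks, misses = 0, 0
        for param in model.params():
            flat = param.value.ravel()
            gflat = param.grad.ravel()
            for _ in range(3):
                i = int(rng_idx.integers(flat.size))
                eps = 3e-3
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                checks += 1
                if not math.isclose(gflat[i], numeric, rel_tol=0.1, abs_tol=2e-4):
                    misses += 1
        # a few finite-difference probes straddle ReLU/maxpool kinks where
        # the loss is not differentiable; the rest must agree tightly
        assert misses <= max(2, int(0.12 * checks)), f"{misses}/{checks} gradient mismatches"


class TestTraining:
    def test_loss_decreases(self):
        batch = _tiny_batch(n=120)
        model = CnnLstmSurrogate(TINY, rng_seed=0)
        sched = TrainingSchedule(max_epochs=15, batch_size=16, cycle=20, rng_seed=0)
        _, metrics = train_surrogate(model, batch, sched)
        assert metrics["history"]["train_loss"][-1] < metrics["history"]["train_loss"][0]

    def test_determinism(self):
        results = []
        for _ in range(2):
            batch = _tiny_batch(n=60)
            model = CnnLstmSurrogate(TINY, rng_seed=1)
            sched = TrainingSchedule(max_epochs=2, batch_size=16, rng_seed=5)
            _, metrics = train_surrogate(model, batch, sched)
            results.append(metrics["history"]["train_loss"][-1])
        assert results[0] == results[1]

    def test_null_targets_no_skill(self):
        batch = _tiny_batch(n=400, noiseless=False)
        model = CnnLstmSurrogate(TINY, rng_seed=2)
        sched = TrainingSchedule(max_epochs=2, batch_size=32, lr_max=3e-3, rng_seed=0)
        _, metrics = train_surrogate(model, batch, sched)
        for task in (0, 1):
            assert abs(metrics["per_task"][task]["r2"]) < 0.15

    def test_divergence_detected(self):
        batch = _tiny_batch(n=60)
        batch.targets[0, 0] = np.inf
        model = CnnLstmSurrogate(TINY, rng_seed=0)
        sched = TrainingSchedule(max_epochs=1, batch_size=16, rng_seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            train_surrogate(model, batch, sched)


class TestPermutationAttribution:
    def test_unknown_group_rejected(self):
        batch = _tiny_batch(n=40)
        model = CnnLstmSurrogate(TINY, rng_seed=0)
        with pytest.raises(KeyError):
            permutation_attribution(model, batch, {"bogus": [999]})

    def test_normalized_and_signal_found(self):
        batch = _tiny_batch(n=120)
        model = CnnLstmSurrogate(TINY, rng_seed=0)
        sched = TrainingSchedule(max_epochs=12, batch_size=16, cycle=20, rng_seed=0)
        model, _ = train_surrogate(model, batch, sched)
        groups = {"signal": [0], "null": [7]}
        imp = permutation_attribution(model, batch, groups, rng_seed=0)
        assert sum(imp.values()) == pytest.approx(1.0)
        # channel 0 drives most targets; channel 7 none
        assert imp["signal"] > imp["null"]


class TestR2:
    def test_perfect(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, y) == pytest.approx(1.0)

    def test_mean_predictor_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r2_score(y, np.full(3, 2.0)) == pytest.approx(0.0)
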