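"""Learning-rate schedule, model construction, training determinism."""

import math

import numpy as np
import pytest

from polyreact.classifier import (
    NetworkConfig,
    TrainConfig,
    build_model,
    load_checkpoint,
    lr_at,
    predict,
    save_checkpoint,
    train,
    PolyreactivityModel,
)
from polyreact.embed import MockEmbedder
from polyreact.errors import ShapeError, ValidationError
from polyreact.featurize import BatchInputs, EncodingConfig


class TestSchedule:
    def test_constant_phase_holds_peak_rate(self):
        assert lr_at(15, TrainConfig()) == pytest.approx(1e-3)

    def test_warmup_starts_at_one_percent_of_peak(self):
        assert lr_at(0, TrainConfig()) == pytest.approx(1e-5)

    def test_cosine_tail_closed_form(self):
        cfg = TrainConfig()
        expect = cfg.peak_lr * (1 + math.cos(9 * math.pi / 10)) / 2
        assert lr_at(29, cfg) == pytest.approx(expect)

    def test_continuous_at_phase_boundaries(self):
        cfg = TrainConfig()
        assert lr_at(9, cfg) == pytest.approx(cfg.peak_lr)
        assert lr_at(10, cfg) == pytest.approx(cfg.peak_lr)
        assert lr_at(19, cfg) == pytest.approx(cfg.peak_lr)
        assert lr_at(20, cfg) == pytest.approx(cfg.peak_lr)

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            lr_at(30, TrainConfig())

    def test_phase_lengths_must_sum_to_epochs(self):
        with pytest.raises(ValidationError):
            TrainConfig(epochs=25)


def _random_batch(rng, n, H=536, W=32, active_rows=268):
    active_rows = min(active_rows, H)
    x1 = np.zeros((n, H, W), dtype=np.float32)
    x1[:, :active_rows] = rng.random((n, active_rows, W), dtype=np.float32)
    return BatchInputs(
        x1=x1,
        x2=rng.integers(0, 2, n).astype(np.float32),
        x3=rng.random(n).astype(np.float32),
        x4=np.tile([1, 2, 0, 0], (n, 1)).astype(np.float32),
        y=rng.integers(0, 2, n).astype(np.float32),
    )


class TestModel:
    def test_untrained_model_predicts_half(self, rng):
        model = build_model(NetworkConfig(), MockEmbedder(32).spec, EncodingConfig())
        batch = _random_batch(rng, 4)
        assert np.allclose(predict(model, batch), 0.5)

    def test_batch_of_one_matches_batched_value(self, rng):
        model = build_model(NetworkConfig(), MockEmbedder(32).spec, EncodingConfig())
        batch = _random_batch(rng, 5)
        full = predict(model, batch)
        single = predict(model, batch.take([2]))
        assert single[0] == pytest.approx(full[2], abs=1e-6)

    def test_shape_mismatch_reported(self, rng):
        model = build_model(NetworkConfig(), MockEmbedder(32).spec, EncodingConfig())
        bad = _random_batch(rng, 2, H=100)
        with pytest.raises(ShapeError, match="536"):
            predict(model, bad)

    def test_g4s_model_takes_three_inputs(self, rng):
        cfg = EncodingConfig(scheme="g4s")
        model = build_model(NetworkConfig(use_location=False),
                            MockEmbedder(32).spec, cfg)
        from polyreact.featurize import g4s_residue_axis

        batch = _random_batch(rng, 3, H=g4s_residue_axis(cfg))
        batch.x4 = None
        assert predict(model, batch).shape == (3,)

    def test_g4s_with_location_input_rejected(self):
        with pytest.raises(ShapeError):
            build_model(NetworkConfig(use_location=True), MockEmbedder(32).spec,
                        EncodingConfig(scheme="g4s"))

    def test_dense_per_protein_accepts_pooled_input(self, rng):
        model = build_model(NetworkConfig(feature_column="dense_per_protein"),
                            MockEmbedder(32).spec, EncodingConfig())
        batch = _random_batch(rng, 3, H=1, active_rows=1)
        assert predict(model, batch).shape == (3,)

    def test_appending_empty_slots_leaves_predictions_unchanged(self, rng):
        """All-zero bands beyond the occupied slots do not move the output:
        convolutions are bias-free and the global pool normalises by active
        rows only."""
        net = NetworkConfig(seed=3)
        m1 = PolyreactivityModel(net, 536, 32)
        m2 = PolyreactivityModel(net, 536 + 134, 32)  # same weights, taller input
        batch = _random_batch(rng, 4)
        padded = BatchInputs(
            x1=np.pad(batch.x1, ((0, 0), (0, 134), (0, 0))),
            x2=batch.x2, x3=batch.x3, x4=batch.x4, y=batch.y,
        )
        p1 = predict(m1, batch)
        p2 = predict(m2, padded)
        assert np.allclose(p1, p2, atol=1e-6)


class TestTraining:
    def _separable_batch(self, rng, n):
        """Labels determined by the mean of one embedding channel, with a
        margin well above zero: linearly separable from the pooled feature."""
        batch = _random_batch(rng, n)
        signal = rng.choice([-0.45, 0.45], size=n)
        batch.x1[:, :268, 21] = signal[:, None] + 0.05 * rng.standard_normal(
            (n, 268)
        ).astype(np.float32)
        batch.y = (signal > 0).astype(np.float32)
        return batch

    def test_reaches_high_train_auc_on_separable_data(self, rng):
        from sklearn.metrics import roc_auc_score

        batch = self._separable_batch(rng, 96)
        val = batch.take(slice(0, 24))
        model = build_model(NetworkConfig(), MockEmbedder(32).spec, EncodingConfig())
        model, hist = train(model, batch, val, TrainConfig(seed=1))
        auc = roc_auc_score(batch.y, predict(model, batch))
        assert auc >= 0.95

    def test_same_seed_reproduces_weights_bitwise(self, rng):
        batch = self._separable_batch(rng, 48)
        val = batch.take(slice(0, 16))
        cfg = TrainConfig(epochs=3, warmup_epochs=1, constant_epochs=1,
                          decay_epochs=1, seed=7)
        runs = []
        for _ in range(2):
            model = build_model(NetworkConfig(seed=2), MockEmbedder(32).spec,
                                EncodingConfig())
            model, hist = train(model, batch, val, cfg)
            runs.append((model.get_weights(), hist["train_loss"]))
        (w1, l1), (w2, l2) = runs
        assert l1 == l2
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))

    def test_single_class_training_set_rejected(self, rng):
        batch = _random_batch(rng, 20)
        batch.y = np.zeros(20, dtype=np.float32)
        model = build_model(NetworkConfig(), MockEmbedder(32).spec, EncodingConfig())
        with pytest.raises(ValidationError, match="single class"):
            train(model, batch, batch, TrainConfig())

    def test_history_tracks_schedule_and_best_weights(self, rng):
        batch = self._separable_batch(rng, 48)
        val = batch.take(slice(0, 16))
        cfg = TrainConfig(epochs=3, warmup_epochs=1, constant_epochs=1,
                          decay_epochs=1, seed=0)
        model = build_model(NetworkConfig(), MockEmbedder(32).spec, EncodingConfig())
        model, hist = train(model, batch, val, cfg)
        assert hist["lr"] == [lr_at(e, cfg) for e in range(3)]
        assert hist["best_val_auc"] == max(hist["val_auc"])


def test_checkpoint_roundtrip(tmp_path, rng):
    spec = MockEmbedder(32).spec
    enc = EncodingConfig()
    model = build_model(NetworkConfig(seed=5), spec, enc)
    batch = _random_batch(rng, 6)
    before = predict(model, batch)
    save_checkpoint(model, tmp_path / "ckpt", spec, enc, extra={"note": "x"})
    loaded, sidecar = load_checkpoint(tmp_path / "ckpt")
    assert np.allclose(predict(loaded, batch), before)
    assert sidecar["extra"]["note"] == "x"
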