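"""Network graph, loss, schedulers, training loop, and checkpointing."""

import numpy as np
import pytest

from lasermark.lwunet import (
    Checkpoint,
    NetworkSpec,
    PlateauTracker,
    TrainConfig,
    TrainingError,
    _one_hot,
    build_network,
    pixelwise_crossentropy,
    predict_patches,
    train,
)
from lasermark.patchwork import PatchSet


def _toy_patchset(rng, n=60, window=16, spot=True):
    """Separable toy data: bright discs on a dark background."""
    images = rng.uniform(0.0, 0.25, (n, window, window, 3)).astype(np.float32)
    labels = np.zeros((n, window, window), np.uint8)
    if spot:
        for i in range(n):
            r, c = rng.integers(4, window - 4, 2)
            rad = int(rng.integers(2, 4))
            rr, cc = np.mgrid[0:window, 0:window]
            d = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
            images[i][d] = rng.uniform(0.75, 1.0)
            labels[i][d] = 1
    centers = np.zeros((n, 2), int)
    return PatchSet(images=images, labels=labels, centers=centers)


class TestBuildNetwork:
    def test_softmax_output_shape_and_sum(self, tiny_spec, rng):
        model = build_network(tiny_spec, seed=0)
        x = rng.random((3, 16, 16, 3)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (3, 16, 16, 2)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-6)

    def test_five_dense_blocks(self, tiny_spec):
        assert build_network(tiny_spec).n_dense_blocks == 5

    def test_spatial_size_preserved_for_default_window(self):
        model = build_network(NetworkSpec(), seed=0)
        x = np.zeros((1, 48, 48, 3), np.float32)
        assert model.forward(x).shape == (1, 48, 48, 2)

    def test_all_zero_window_gives_finite_probabilities(self, tiny_spec):
        model = build_network(tiny_spec, seed=1)
        out = model.forward(np.zeros((1, 16, 16, 3), np.float32))
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(n_scales=2, block_channels=(32, 64, 128))
        with pytest.raises(ValueError):
            NetworkSpec(dropout_p=1.0)

    def test_transposed_upsampling_variant_runs(self, rng):
        spec = NetworkSpec(block_channels=(4, 6, 8), window=16, upsample="transposed")
        out = build_network(spec, seed=0).forward(rng.random((2, 16, 16, 3)).astype(np.float32))
        assert out.shape == (2, 16, 16, 2)


class TestPixelwiseCrossentropy:
    def test_perfect_prediction_zero_loss(self):
        y = _one_hot(np.array([[0, 1], [1, 0]]), 2)
        assert pixelwise_crossentropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_closed_form(self):
        n = 57
        y = _one_hot((np.arange(n) % 2), 2)
        p = np.full((n, 2), 0.5)
        assert pixelwise_crossentropy(p, y) == pytest.approx(n * np.log(2), rel=1e-12)

    def test_matches_two_loop_oracle(self, rng):
        p = rng.dirichlet((1, 1), size=40)
        y = _one_hot(rng.integers(0, 2, 40), 2)
        expected = 0.0
        for i in range(40):
            for k in range(2):
                expected -= y[i, k] * np.log(max(p[i, k], 1e-12))
        assert pixelwise_crossentropy(p, y) == pytest.approx(expected, abs=1e-9)

    def test_loss_nonnegative(self, rng):
        p = rng.dirichlet((2, 3), size=100)
        y = _one_hot(rng.integers(0, 2, 100), 2)
        assert pixelwise_crossentropy(p, y) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pixelwise_crossentropy(np.zeros((3, 2)), np.zeros((4, 2)))


class TestSchedules:
    def test_lr_drops_to_3e4_after_11_flat_epochs(self):
        """Eleven consecutive epochs without improvement trigger one reduction."""
        tracker = PlateauTracker(patience=10, reset_on_trigger=True)
        lr = 1e-3
        tracker.update(0.9)  # baseline epoch sets the best value
        for _ in range(11):
            if tracker.update(0.9):
                lr *= 0.3
        assert lr == pytest.approx(3e-4)

    def test_second_reduction_needs_ten_more_epochs(self):
        tracker = PlateauTracker(patience=10, reset_on_trigger=True)
        lr = 1e-3
        tracker.update(0.9)
        for _ in range(21):
            if tracker.update(0.9):
                lr *= 0.3
        assert lr == pytest.approx(1e-3 * 0.3**2)

    def test_early_stop_fires_within_41_flat_epochs(self):
        stopper = PlateauTracker(patience=40, reset_on_trigger=False)
        stopper.update(0.5)
        fired_at = None
        for epoch in range(1, 42):
            if stopper.update(0.5):
                fired_at = epoch
                break
        assert fired_at is not None and fired_at <= 41

    def test_improvement_resets_counters(self):
        tracker = PlateauTracker(patience=3)
        values = [0.1, 0.1, 0.1, 0.2, 0.2, 0.2]  # improvement at index 3
        fired = [tracker.update(v) for v in values]
        assert not any(fired)


class TestTrain:
    def test_loss_decreases_on_separable_toy(self, rng):
        ps = _toy_patchset(rng, n=80, window=16)
        spec = NetworkSpec(block_channels=(4, 6, 8), window=16)
        ckpt = train(ps, TrainConfig(seed=0, max_epochs=4, batch_size=16, lr_init=0.03),
                     spec=spec)
        epochs = [r for r in ckpt.training_log if "epoch" in r]
        assert epochs[-1]["train_loss"] < epochs[0]["train_loss"]
        assert ckpt.training_log[-1]["stop_reason"] in ("max_epochs", "early_stop")

    def test_log_records_lr_and_losses(self, rng):
        ps = _toy_patchset(rng, n=32, window=16)
        spec = NetworkSpec(block_channels=(4, 6, 8), window=16)
        ckpt = train(ps, TrainConfig(seed=1, max_epochs=2, batch_size=16), spec=spec)
        epochs = [r for r in ckpt.training_log if "epoch" in r]
        assert len(epochs) == 2
        for row in epochs:
            assert set(row) >= {"epoch", "lr", "train_loss", "val_loss", "val_acc"}
        assert epochs[0]["lr"] == pytest.approx(1e-3)

    def test_empty_patchset_rejected(self):
        empty = PatchSet(images=np.empty((0, 8, 8, 3), np.float32),
                         labels=np.empty((0, 8, 8), np.uint8),
                         centers=np.empty((0, 2), int))
        with pytest.raises(TrainingError, match="empty"):
            train(empty, TrainConfig())

    def test_init_checkpoint_resumes_with_same_spec(self, rng):
        ps = _toy_patchset(rng, n=32, window=16)
        spec = NetworkSpec(block_channels=(4, 6, 8), window=16)
        first = train(ps, TrainConfig(seed=2, max_epochs=1, batch_size=16), spec=spec)
        second = train(ps, TrainConfig(seed=3, max_epochs=1, batch_size=16), init=first)
        assert second.network_spec == spec


class TestCheckpoint:
    def test_roundtrip_identical_predictions(self, tmp_path, rng):
        ps = _toy_patchset(rng, n=24, window=16)
        spec = NetworkSpec(block_channels=(4, 6, 8), window=16)
        ckpt = train(ps, TrainConfig(seed=0, max_epochs=1, batch_size=8), spec=spec)
        ckpt.save(tmp_path / "model.npz")
        back = Checkpoint.load(tmp_path / "model.npz")
        x = rng.random((4, 16, 16, 3)).astype(np.float32)
        np.testing.assert_allclose(
            predict_patches(back, x), predict_patches(ckpt, x), atol=1e-6
        )
        assert back.network_spec == spec
        assert back.training_log == ckpt.training_log


class TestPredictPatches:
    def test_duplicate_windows_identical_outputs(self, tiny_spec, rng):
        model_ckpt = Checkpoint(
            weights=build_network(tiny_spec, seed=5).state_dict(),
            network_spec=tiny_spec,
        )
        win = rng.random((1, 16, 16, 3)).astype(np.float32)
        windows = np.concatenate([win, win])
        out = predict_patches(model_ckpt, windows)
        np.testing.assert_array_equal(out[0], out[1])
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_wrong_window_shape_rejected(self, tiny_spec):
        ckpt = Checkpoint(weights=build_network(tiny_spec, seed=0).state_dict(),
                          network_spec=tiny_spec)
        with pytest.raises(ValueError, match="windows"):
            predict_patches(ckpt, np.zeros((1, 8, 8, 3), np.float32))
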