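"""Loss arithmetic, the alternating update's freezing contract, and the
fitting loop on desk-scale phantoms."""

import numpy as np
import pytest

from vesselgan import nn
from vesselgan.evaluate import confusion_counts, dice
from vesselgan.train import (
    TrainConfig,
    discriminator_loss,
    fit,
    generator_loss,
    l1_loss,
    make_train_state,
    predict_volume,
    train_step,
)


class TestL1Loss:
    def test_zero_for_equal_inputs(self, rng):
        x = rng.normal(0, 1, (2, 1, 4, 4)).astype(np.float32)
        assert l1_loss(x, x.copy()).item() == 0.0

    def test_constant_offset(self):
        pred = np.ones((2, 1, 3, 3), np.float32)
        assert l1_loss(pred, -pred).item() == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        assert l1_loss(
            np.array([0.5, -0.5], np.float32), np.array([1.0, -1.0], np.float32)
        ).item() == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGeneratorLoss:
    def test_half_confidence_perfect_prediction(self):
        d = np.full((1, 1, 4, 4), 0.5, np.float32)
        y = np.ones((1, 1, 4, 4), np.float32)
        total, adv, l1 = generator_loss(d, y, y, lambda_l1=75.0)
        assert l1.item() == 0.0
        assert total.item() == pytest.approx(-np.log(0.5), abs=1e-4)

    def test_lambda_zero_degenerates_to_adversarial_term(self, rng):
        d = rng.uniform(0.2, 0.8, (1, 1, 4, 4)).astype(np.float32)
        pred = rng.normal(0, 0.5, (1, 1, 8, 8)).astype(np.float32)
        tgt = rng.normal(0, 0.5, (1, 1, 8, 8)).astype(np.float32)
        total, adv, _ = generator_loss(d, pred, tgt, lambda_l1=0.0)
        assert total.item() == pytest.approx(adv.item())

    def test_weighted_combination_arithmetic(self):
        d = np.full((1, 1, 4, 4), 0.5, np.float32)
        pred = np.full((1, 1, 5, 5), 0.1, np.float32)
        tgt = np.zeros((1, 1, 5, 5), np.float32)
        total, _, _ = generator_loss(d, pred, tgt, lambda_l1=75.0)
        assert total.item() == pytest.approx(-np.log(0.5) + 7.5, abs=1e-3)

    def test_total_decomposes_exactly(self, rng):
        d = rng.uniform(0.1, 0.9, (2, 1, 4, 4)).astype(np.float32)
        pred = rng.normal(0, 0.5, (2, 1, 8, 8)).astype(np.float32)
        tgt = rng.normal(0, 0.5, (2, 1, 8, 8)).astype(np.float32)
        total, adv, l1 = generator_loss(d, pred, tgt, lambda_l1=75.0)
        assert total.item() == pytest.approx(adv.item() + 75.0 * l1.item(), rel=1e-6)

    def test_out_of_range_discriminator_output_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            generator_loss(np.array([1.5]), np.zeros(2), np.zeros(2))


class TestDiscriminatorLoss:
    def test_perfect_discriminator_approaches_zero(self):
        loss = discriminator_loss(
            np.full((4,), 1.0 - 1e-7, np.float32), np.full((4,), 1e-7, np.float32)
        )
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_half_confidence_with_pace(self):
        half = np.full((1, 1, 4, 4), 0.5, np.float32)
        assert discriminator_loss(half, half, pace_factor=0.5).item() == pytest.approx(
            0.5 * -np.log(0.5), abs=1e-4
        )

    def test_symmetric_under_role_swap(self, rng):
        a = rng.uniform(0.1, 0.9, 16).astype(np.float32)
        b = rng.uniform(0.1, 0.9, 16).astype(np.float32)
        assert discriminator_loss(a, b).item() == pytest.approx(
            discriminator_loss(1 - b, 1 - a).item(), rel=1e-5
        )


def _tiny_batch(rng, side=16, n=4):
    x = rng.normal(0, 0.4, (n, 1, side, side)).astype(np.float32).clip(-1, 1)
    y = np.where(rng.random((n, 1, side, side)) > 0.9, 1.0, -1.0).astype(np.float32)
    return x, y


class TestTrainStep:
    def test_both_networks_update(self, rng, tiny_net_cfgs, tiny_train_cfg):
        gcfg, dcfg = tiny_net_cfgs
        state = make_train_state(tiny_train_cfg, gcfg, dcfg)
        g_before = state.generator.model.state_dict()
        d_before = state.discriminator.model.state_dict()
        losses = train_step(*_tiny_batch(rng), state)
        assert all(np.isfinite(v) for v in losses.values())
        assert any(
            not np.array_equal(g_before[k], v)
            for k, v in state.generator.model.state_dict().items()
        )
        assert any(
            not np.array_equal(d_before[k], v)
            for k, v in state.discriminator.model.state_dict().items()
        )

    def test_discriminator_frozen_during_generator_substep(self, rng, tiny_net_cfgs):
        # with D's own optimizer disabled, the G sub-step must leave D intact
        gcfg, dcfg = tiny_net_cfgs
        state = make_train_state(TrainConfig(seed=1), gcfg, dcfg)
        state.d_opt.lr = 0.0
        d_before = state.discriminator.model.state_dict()
        train_step(*_tiny_batch(rng), state)
        d_after = state.discriminator.model.state_dict()
        assert all(np.array_equal(d_before[k], d_after[k]) for k in d_before)

    def test_zero_learning_rate_changes_nothing(self, rng, tiny_net_cfgs):
        gcfg, dcfg = tiny_net_cfgs
        state = make_train_state(TrainConfig(lr=0.0, seed=2), gcfg, dcfg)
        g_before = state.generator.model.state_dict()
        losses = train_step(*_tiny_batch(rng), state)
        g_after = state.generator.model.state_dict()
        assert all(np.array_equal(g_before[k], g_after[k]) for k in g_before)
        assert set(losses) == {"g_total", "g_adv", "g_l1", "d_loss"}


class TestFit:
    def test_seeded_runs_reproduce_history(self, tiny_volumes, tiny_net_cfgs, tiny_train_cfg):
        gcfg, dcfg = tiny_net_cfgs
        _, h1 = fit(tiny_volumes[:3], tiny_volumes[3:], tiny_train_cfg, gcfg, dcfg)
        _, h2 = fit(tiny_volumes[:3], tiny_volumes[3:], tiny_train_cfg, gcfg, dcfg)
        assert h1.equals(h2)

    def test_history_has_one_row_per_epoch(self, tiny_volumes, tiny_net_cfgs, tiny_train_cfg):
        gcfg, dcfg = tiny_net_cfgs
        _, hist = fit(tiny_volumes[:3], tiny_volumes[3:], tiny_train_cfg, gcfg, dcfg)
        assert list(hist.columns) == ["epoch", "g_total", "g_adv", "g_l1", "d_loss", "val_dice"]
        assert len(hist) == tiny_train_cfg.epochs
        assert np.isfinite(hist[["g_total", "g_adv", "g_l1", "d_loss"]].to_numpy()).all()

    def test_early_stop_never_trains_past_patience(self, tiny_volumes, tiny_net_cfgs):
        gcfg, dcfg = tiny_net_cfgs
        cfg = TrainConfig(epochs=8, seed=4, early_stop_patience=2, lr=0.0)
        _, hist = fit(tiny_volumes[:3], tiny_volumes[3:], cfg, gcfg, dcfg)
        dices = hist["val_dice"].tolist()
        best = int(np.argmax(dices))
        assert len(hist) <= best + 1 + 2

    def test_empty_training_set_rejected(self, tiny_volumes, tiny_net_cfgs):
        gcfg, dcfg = tiny_net_cfgs
        with pytest.raises(ValueError, match="empty"):
            fit([], tiny_volumes[3:], TrainConfig(), gcfg, dcfg)


class TestPredictVolume:
    def test_output_binary_and_shape_preserving(self, tiny_volumes, tiny_net_cfgs):
        gcfg, dcfg = tiny_net_cfgs
        state = make_train_state(TrainConfig(seed=5), gcfg, dcfg)
        img_vol, _ = tiny_volumes[0]
        pred = predict_volume(state.generator, img_vol, batch_size=2)
        assert pred.shape == img_vol.shape
        assert set(np.unique(pred.as_array())) <= {0.0, 1.0}

    def test_prediction_is_deterministic_without_dropout(self, tiny_volumes, tiny_net_cfgs):
        gcfg, dcfg = tiny_net_cfgs
        state = make_train_state(TrainConfig(seed=6), gcfg, dcfg)
        img_vol, _ = tiny_volumes[0]
        a = predict_volume(state.generator, img_vol).as_array()
        b = predict_volume(state.generator, img_vol).as_array()
        assert np.array_equal(a, b)

    def test_trained_model_beats_thresholdless_untrained_one(self, tiny_volumes, tiny_net_cfgs):
        gcfg, dcfg = tiny_net_cfgs
        cfg = TrainConfig(epochs=4, seed=7, early_stop_patience=None)
        state = make_train_state(cfg, gcfg, dcfg)
        img_vol, mask_vol = tiny_volumes[3]
        truth = mask_vol.as_array().astype(np.uint8)
        before = dice(confusion_counts(predict_volume(state.generator, img_vol), truth)) or 0.0
        gen, _ = fit(tiny_volumes[:3], tiny_volumes[3:], cfg, gcfg, dcfg)
        after = dice(confusion_counts(predict_volume(gen, img_vol), truth)) or 0.0
        assert after > before
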