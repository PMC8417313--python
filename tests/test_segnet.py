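"""Loss closed forms and equivalences, architecture contracts, seeded
training behavior, and prediction-map contracts.

The focal-loss test values are independent hand computations of the loss
expressions; the gamma=0 equivalences are closed-form limits checked on
random probability pairs.
"""

import numpy as np
import pytest

from vesselfuse import (LossConfig, ModelConfig, TrainState, VesselTreeSpec,
                        build_model, build_objectives, enhance, generate_tree,
                        loss_value, predict_map, render_fundus, to_green,
                        train_channel)

LOG2 = float(np.log(2.0))


class TestLossClosedForms:
    def test_binary_ce_half_is_log2(self):
        assert loss_value(np.array([1.0]), np.array([0.5]),
                          LossConfig(kind="binary_ce")) == pytest.approx(LOG2, abs=1e-9)

    @pytest.mark.parametrize("kind,alpha", [
        ("binary_ce", 0.3), ("categorical_ce", 0.3),
        ("binary_focal", 0.3), ("categorical_focal", (0.7, 0.3)),
    ])
    def test_perfect_prediction_near_zero(self, kind, alpha):
        v = loss_value(np.array([1.0]), np.array([1.0 - 1e-7]),
                       LossConfig(kind=kind, alpha=alpha, gamma=2.0))
        assert 0 <= v < 1e-5

    def test_binary_focal_hand_case(self):
        # alpha * (1-p)^gamma * -log p with alpha=0.3, gamma=3, p=0.5
        v = loss_value(np.array([1.0]), np.array([0.5]),
                       LossConfig(kind="binary_focal", alpha=0.3, gamma=3.0))
        assert v == pytest.approx(0.3 * 0.125 * LOG2, abs=1e-6)

    def test_categorical_focal_hand_case(self):
        # vessel pixel, alpha_fg=0.25, gamma=2, p=0.5: 0.25 * 0.25 * log 2
        v = loss_value(np.array([1.0]), np.array([0.5]),
                       LossConfig(kind="categorical_focal", alpha=(0.75, 0.25),
                                  gamma=2.0))
        assert v == pytest.approx(0.25 * 0.25 * LOG2, abs=1e-6)

    def test_gamma0_binary_focal_is_half_bce(self, rng):
        y = (rng.random(1000) > 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, 1000)
        focal = LossConfig(kind="binary_focal", alpha=0.5, gamma=0.0)
        bce = LossConfig(kind="binary_ce")
        for yi, pi in zip(y[:50], p[:50]):
            a = loss_value(np.array([yi]), np.array([pi]), focal)
            b = loss_value(np.array([yi]), np.array([pi]), bce)
            assert a == pytest.approx(0.5 * b, abs=1e-9)
        assert loss_value(y, p, focal) == pytest.approx(0.5 * loss_value(y, p, bce),
                                                        abs=1e-9)

    def test_gamma0_categorical_focal_is_weighted_cce(self, rng):
        y = (rng.random(1000) > 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, 1000)
        a_bg, a_fg = 0.6, 0.4
        focal = LossConfig(kind="categorical_focal", alpha=(a_bg, a_fg), gamma=0.0)
        got = loss_value(y, p, focal)
        p_true = np.where(y == 1, p, 1 - p)
        expected = float(np.mean(np.where(y == 1, a_fg, a_bg) * -np.log(p_true)))
        assert got == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("kind", ["binary_ce", "binary_focal",
                                      "categorical_ce", "categorical_focal"])
    def test_loss_decreasing_in_confidence_for_positive(self, kind):
        cfg = LossConfig(kind=kind, alpha=0.3 if kind.startswith("binary") else (0.7, 0.3),
                         gamma=2.0)
        ps = np.linspace(0.05, 0.95, 19)
        vals = [loss_value(np.array([1.0]), np.array([p]), cfg) for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(kind="dice")
        with pytest.raises(ValueError):
            LossConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            LossConfig(kind="binary_focal", alpha=1.5)


class TestModel:
    def test_output_shape_and_range(self):
        m = build_model(ModelConfig(depth=1, base_filters=4, input_patch=16), seed=0)
        x = np.random.default_rng(0).random((3, 16, 16))
        p = m.forward(x)
        assert p.shape == (3, 16, 16)
        assert p.min() >= 0 and p.max() <= 1

    def test_seed_determinism(self):
        mcfg = ModelConfig(depth=2, base_filters=4, input_patch=16)
        a = build_model(mcfg, seed=3)
        b = build_model(mcfg, seed=3)
        c = build_model(mcfg, seed=4)
        assert a.state_checksum() == b.state_checksum()
        assert a.state_checksum() != c.state_checksum()

    def test_patch_depth_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(depth=3, base_filters=4, input_patch=20)

    def test_gradient_matches_numeric(self, rng):
        mcfg = ModelConfig(depth=1, base_filters=3, input_patch=8)
        lcfg = LossConfig(kind="categorical_focal", alpha=(0.7, 0.3), gamma=2.0)
        m = build_model(mcfg, lcfg, seed=0)
        x = rng.random((2, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.7).astype(float)
        m.forward(x)
        m.backward(y)
        layer = m.enc[0][0]
        analytic = layer.dw[3, 1]
        eps = 1e-6
        layer.w[3, 1] += eps
        lp = loss_value(y, m.forward(x), lcfg)
        layer.w[3, 1] -= 2 * eps
        lm = loss_value(y, m.forward(x), lcfg)
        numeric = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-10)


@pytest.fixture(scope="module")
def toy_training_data():
    geom = generate_tree(VesselTreeSpec(image_size=96, seed=21))
    sample = render_fundus(geom, noise_sd=0.0, contrast=0.3, seed=22)
    img = enhance(to_green(sample.rgb), sample.fov_mask)
    return img, sample


class TestTraining:
    def test_overfit_halves_loss(self, toy_training_data):
        img, sample = toy_training_data
        mcfg = ModelConfig(depth=2, base_filters=8, input_patch=32)
        tcfg = TrainState(seed=5, epochs=15, patches_per_image=150)
        train_channel([img], [sample.vessel_mask], [sample.fov_mask],
                      mcfg, LossConfig(), tcfg)
        assert len(tcfg.loss_history) == 15
        assert tcfg.loss_history[-1] < 0.5 * tcfg.loss_history[0]

    def test_zero_epochs_returns_initialized_model(self, toy_training_data):
        img, sample = toy_training_data
        mcfg = ModelConfig(depth=1, base_filters=4, input_patch=16)
        tcfg = TrainState(seed=5, epochs=0)
        model = train_channel([img], [sample.vessel_mask], [sample.fov_mask],
                              mcfg, LossConfig(), tcfg)
        fresh = build_model(mcfg, LossConfig(), seed=5)
        assert model.state_checksum() == fresh.state_checksum()
        assert tcfg.loss_history == []

    def test_training_determinism(self, toy_training_data):
        img, sample = toy_training_data
        mcfg = ModelConfig(depth=1, base_filters=4, input_patch=16)
        histories = []
        for _ in range(2):
            tcfg = TrainState(seed=9, epochs=3, patches_per_image=60)
            train_channel([img], [sample.vessel_mask], [sample.fov_mask],
                          mcfg, LossConfig(), tcfg)
            histories.append(tcfg.loss_history)
        assert histories[0] == histories[1]

    def test_no_training_images_rejected(self):
        with pytest.raises(ValueError):
            train_channel([], [], [], ModelConfig(), LossConfig(), TrainState())

    def test_empty_fov_rejected(self, toy_training_data):
        img, sample = toy_training_data
        empty = np.zeros_like(sample.fov_mask.grid)
        with pytest.raises(ValueError):
            train_channel([img], [sample.vessel_mask], [empty],
                          ModelConfig(depth=1, base_filters=2, input_patch=16),
                          LossConfig(), TrainState(seed=0, epochs=1))


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self, toy_training_data):
        img, sample = toy_training_data
        mcfg = ModelConfig(depth=2, base_filters=8, input_patch=32)
        tcfg = TrainState(seed=5, epochs=15, patches_per_image=150)
        model = train_channel([img], [sample.vessel_mask], [sample.fov_mask],
                              mcfg, LossConfig(), tcfg)
        return model, img, sample

    def test_zero_outside_fov_and_unit_range(self, trained):
        model, img, sample = trained
        pm = predict_map(model, img, sample.fov_mask)
        assert np.all(pm.grid[sample.fov_mask.grid == 0] == 0)
        assert pm.grid.min() >= 0 and pm.grid.max() <= 1

    def test_stride_blending_tolerance(self, trained):
        model, img, sample = trained
        full = predict_map(model, img, sample.fov_mask, stride=32)
        half = predict_map(model, img, sample.fov_mask, stride=16)
        inside = sample.fov_mask.grid == 1
        assert np.abs(full.grid - half.grid)[inside].mean() < 0.15

    def test_heldout_auc_per_channel(self):
        """Trained on noiseless synthetic data, each channel separates its own
        objective on a held-out image (parameter-recovery surrogate)."""
        from vesselfuse import auc_score
        train_geom = [generate_tree(VesselTreeSpec(image_size=96, seed=s))
                      for s in (31, 32, 33)]
        test_geom = generate_tree(VesselTreeSpec(image_size=96, seed=34))
        train_samples = [render_fundus(g, noise_sd=0.0, contrast=0.3, seed=s)
                         for s, g in enumerate(train_geom)]
        test_sample = render_fundus(test_geom, noise_sd=0.0, contrast=0.3, seed=99)
        imgs = [enhance(to_green(s.rgb), s.fov_mask) for s in train_samples]
        test_img = enhance(to_green(test_sample.rgb), test_sample.fov_mask)
        objs = [build_objectives(s.vessel_mask) for s in train_samples]
        test_obj = build_objectives(test_sample.vessel_mask)
        mcfg = ModelConfig(depth=2, base_filters=8, input_patch=32)
        for channel, get in (("original", lambda o: o.original),
                             ("thin", lambda o: o.thin_objective)):
            # reference training conditions: 30 epochs on 200 patches
            tcfg = TrainState(seed=13, epochs=30, patches_per_image=200)
            model = train_channel(imgs, [get(o) for o in objs],
                                  [s.fov_mask for s in train_samples],
                                  mcfg, LossConfig(), tcfg, channel=channel)
            pm = predict_map(model, test_img, test_sample.fov_mask)
            auc = auc_score(pm.grid, get(test_obj), test_sample.fov_mask)
            assert auc >= 0.95, f"channel {channel} AUC {auc:.3f}"
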