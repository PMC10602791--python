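"""The regression CNN: architecture, augmentation, training, transfer, saliency."""

import numpy as np
import pandas as pd
import pytest

from zfstage import plateio, stagenet
from zfstage.stagenet import (
    AugmentationConfig,
    CenterCropX,
    Dense,
    Flatten,
    StageModelConfig,
    StageNet,
    TransferSpec,
    augment,
    build_model,
    center_crop_x,
    load_model,
    predict,
    saliency_map,
    train,
    transfer_learn,
)


class TestConfig:
    def test_filters_must_match_unit_count(self):
        with pytest.raises(ValueError, match="filters_per_unit"):
            StageModelConfig(n_conv_units=2, filters_per_unit=(8,))

    def test_spatial_collapse_rejected(self):
        # 2^7 = 128 > 64: seven halvings crush the input to nothing
        with pytest.raises(ValueError, match="collapse"):
            StageModelConfig(
                input_height=64, input_width=96, crop_width=64,
                n_conv_units=7, filters_per_unit=(2,) * 7, dense_width=4,
            )

    def test_dropout_bounds(self):
        with pytest.raises(ValueError, match="dropout"):
            StageModelConfig(dropout_rate=1.0)

    def test_default_crop_is_square(self):
        cfg = stagenet.scaled_config()
        assert cfg.effective_crop_width == cfg.input_height == 64


class TestBuildModel:
    def test_output_shape(self, micro_config, rng):
        model = build_model(micro_config)
        x = rng.random((5, 16, 24, 3)).astype(np.float32)
        assert model.forward(x).shape == (5, 1)

    def test_hand_counted_conv_params(self):
        # one unit, 4 filters of 3x3x3 + bias: 4*(27+1) = 112
        cfg = StageModelConfig(
            input_height=64, input_width=96, crop_width=96,
            n_conv_units=1, filters_per_unit=(4,), dense_width=8,
            dropout_rate=0.0,
        )
        model = build_model(cfg)
        conv = model.parametric_layers()[0]
        assert conv.n_params() == 112

    @pytest.mark.parametrize("seed", range(20))
    def test_param_count_formula_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n_units = int(rng.integers(1, 4))
        filters = tuple(int(f) for f in rng.integers(1, 9, n_units))
        h = int(rng.choice([16, 32, 64]))
        w = int(rng.choice([24, 48, 96]))
        dense_w = int(rng.integers(2, 33))
        cfg = StageModelConfig(
            input_height=h, input_width=w, crop_width=min(h, w),
            n_conv_units=n_units, filters_per_unit=filters,
            dense_width=dense_w, dropout_rate=0.0,
        )
        model = build_model(cfg)
        # independent hand formula
        expected = 0
        c = 3
        hh, ww = h, min(h, w)
        for f in filters:
            expected += f * (9 * c + 1)
            c = f
            hh, ww = hh // 2, ww // 2
        expected += (hh * ww * c) * dense_w + dense_w  # hidden dense
        expected += dense_w + 1                        # output neuron
        assert model.n_params() == expected

    def test_deterministic_initialisation(self, micro_config):
        a = build_model(micro_config)
        b = build_model(micro_config)
        for la, lb in zip(a.parametric_layers(), b.parametric_layers()):
            assert np.array_equal(la.w, lb.w)


class TestCenterCropX:
    def test_standard_crop_retains_center_columns(self, rng):
        x = rng.random((2, 180, 240, 3))
        out = center_crop_x(x, 180)
        assert out.shape == (2, 180, 180, 3)
        np.testing.assert_array_equal(out, x[:, :, 30:210, :])

    def test_identity_when_width_matches(self, rng):
        x = rng.random((1, 10, 20, 3))
        np.testing.assert_array_equal(center_crop_x(x, 20), x)

    def test_odd_margin_floor_left_ceil_right(self, rng):
        x = rng.random((1, 4, 15, 1))
        out = center_crop_x(x, 10)  # margin 5 -> 2 left, 3 right
        np.testing.assert_array_equal(out, x[:, :, 2:12, :])

    def test_target_wider_than_image(self, rng):
        with pytest.raises(ValueError, match="crop"):
            center_crop_x(rng.random((1, 4, 8, 1)), 9)


class TestAugment:
    def test_identity_outside_training(self, rng):
        batch = rng.random((4, 32, 48, 3)).astype(np.float32)
        out = augment(batch, AugmentationConfig(), training=False)
        assert out is batch  # bit-identical, not even copied

    def test_horizontal_flip_is_involution(self, rng):
        cfg = AugmentationConfig(
            p_hist_equalise=0, p_saturation=0, noise_sigma=0,
            p_flip_h=1.0, p_flip_v=0, max_x_translation=0, max_zoom=0,
        )
        batch = rng.random((2, 16, 24, 3)).astype(np.float32)
        once = augment(batch, cfg, training=True, rng=np.random.default_rng(0))
        twice = augment(once, cfg, training=True, rng=np.random.default_rng(0))
        np.testing.assert_allclose(twice, batch, atol=1e-6)

    def test_translation_bounded_and_edge_filled(self, rng):
        cfg = AugmentationConfig(
            p_hist_equalise=0, p_saturation=0, noise_sigma=0,
            p_flip_h=0, p_flip_v=0, max_x_translation=0.2, max_zoom=0,
        )
        w = 100
        # a single bright column makes the shift directly measurable
        batch = np.zeros((8, 10, w, 3), dtype=np.float32)
        batch[:, :, 50, :] = 1.0
        out = augment(batch, cfg, training=True, rng=np.random.default_rng(3))
        for img in out:
            cols = np.where(img[0, :, 0] > 0.5)[0]
            shift = cols[0] - 50
            assert abs(shift) <= 20

    def test_deterministic_given_seed(self, rng):
        batch = rng.random((3, 24, 32, 3)).astype(np.float32)
        cfg = AugmentationConfig(seed=11)
        a = augment(batch, cfg, training=True)
        b = augment(batch, cfg, training=True)
        np.testing.assert_array_equal(a, b)

    def test_output_clipped_to_unit_interval(self, rng):
        batch = rng.random((3, 16, 24, 3)).astype(np.float32)
        cfg = AugmentationConfig(noise_sigma=0.5, seed=0)
        out = augment(batch, cfg, training=True)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestBackprop:
    def test_gradients_match_finite_differences(self, micro_config, rng):
        """Full-network analytic gradients agree with central differences."""
        model = build_model(micro_config)
        x = rng.random((3, 16, 24, 3))
        y = np.array([1.0, 2.0, 0.5])

        def loss():
            e = model.forward(x, training=True)[:, 0] - y
            return float(np.mean(e**2))

        e = model.forward(x, training=True)[:, 0] - y
        model.backward((2 * e / len(e))[:, None])
        check_rng = np.random.default_rng(0)
        for layer in model.parametric_layers():
            for pname, p in layer.params().items():
                g = layer.grads()[pname].reshape(-1)
                flat = p.reshape(-1)
                for idx in check_rng.choice(p.size, min(5, p.size), replace=False):
                    eps = 1e-6
                    flat[idx] += eps
                    up = loss()
                    flat[idx] -= 2 * eps
                    down = loss()
                    flat[idx] += eps
                    numeric = (up - down) / (2 * eps)
                    assert g[idx] == pytest.approx(numeric, abs=1e-6, rel=1e-4)


def _manifest_from_plate(manifest, wells):
    return manifest[manifest["well"].isin(wells)].reset_index(drop=True)


class TestTrain:
    def test_constant_label_converges_to_bias(self, tiny_manifest, micro_config,
                                              no_augmentation):
        m = tiny_manifest.copy()
        m["hpf"] = 10.0
        wells = sorted(set(m["well"]))
        train_m = _manifest_from_plate(m, wells[:2])
        cfg = stagenet.StageModelConfig(
            **{**micro_config.__dict__, "epochs": 150, "learning_rate": 0.05,
               "input_height": 16, "input_width": 24, "crop_width": 16}
        )
        model = build_model(cfg)
        model, hist = train(model, train_m, None, cfg, augmentation=no_augmentation)
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        preds = predict(model, train_m)["predicted_hpf"]
        assert np.abs(preds - 10.0).max() < 2.0

    def test_loss_decreases_on_simulated_plate(self, tiny_manifest, no_augmentation):
        wells = sorted(set(tiny_manifest["well"]))
        train_m = _manifest_from_plate(tiny_manifest, wells[:3])
        cfg = stagenet.scaled_config(epochs=8, seed=2)
        model = build_model(cfg)
        model, hist = train(model, train_m, None, cfg, augmentation=no_augmentation)
        assert hist["train_loss"].iloc[-1] < 0.5 * hist["train_loss"].iloc[0]
        assert list(hist.columns) == ["epoch", "train_loss"]
        assert len(hist) == 8

    def test_validation_loss_reported(self, tiny_manifest, micro_config,
                                      no_augmentation):
        wells = sorted(set(tiny_manifest["well"]))
        train_m = _manifest_from_plate(tiny_manifest, wells[:2])
        val_m = _manifest_from_plate(tiny_manifest, wells[2:])
        cfg = stagenet.StageModelConfig(
            **{**micro_config.__dict__, "epochs": 2, "input_height": 16,
               "input_width": 24, "crop_width": 16}
        )
        model = build_model(cfg)
        _, hist = train(model, train_m, val_m, cfg, augmentation=no_augmentation)
        assert {"train_loss", "val_loss"} <= set(hist.columns)

    def test_well_leakage_rejected(self, tiny_manifest, micro_config):
        wells = sorted(set(tiny_manifest["well"]))
        train_m = _manifest_from_plate(tiny_manifest, wells[:3])
        val_m = _manifest_from_plate(tiny_manifest, wells[2:])  # shares wells[2]
        model = build_model(micro_config)
        with pytest.raises(ValueError, match="both"):
            train(model, train_m, val_m, micro_config)

    def test_empty_manifest_rejected(self, tiny_manifest, micro_config):
        model = build_model(micro_config)
        with pytest.raises(ValueError, match="empty"):
            train(model, tiny_manifest.iloc[0:0], None, micro_config)

    def test_checkpoint_round_trip(self, tiny_manifest, micro_config,
                                   no_augmentation, tmp_path):
        wells = sorted(set(tiny_manifest["well"]))
        train_m = _manifest_from_plate(tiny_manifest, wells[:2])
        cfg = stagenet.StageModelConfig(
            **{**micro_config.__dict__, "epochs": 1, "input_height": 16,
               "input_width": 24, "crop_width": 16}
        )
        model = build_model(cfg)
        model, _ = train(model, train_m, None, cfg, augmentation=no_augmentation,
                         checkpoint=tmp_path / "ckpt")
        reloaded = load_model(tmp_path / "ckpt")
        a = predict(model, train_m)["predicted_hpf"]
        b = predict(reloaded, train_m)["predicted_hpf"]
        np.testing.assert_allclose(a, b)
        assert (tmp_path / "ckpt.history.csv").exists()


class TestPredict:
    def test_one_pair_per_record_order_preserved(self, tiny_manifest, micro_config):
        cfg = stagenet.StageModelConfig(
            **{**micro_config.__dict__, "input_height": 16, "input_width": 24,
               "crop_width": 16}
        )
        model = build_model(cfg)
        out = predict(model, tiny_manifest)
        assert len(out) == len(tiny_manifest)
        assert list(out["well"]) == list(tiny_manifest["well"])
        assert {"true_hpf", "predicted_hpf"} <= set(out.columns)
        np.testing.assert_allclose(out["true_hpf"], tiny_manifest["time_h"])

    def test_duplicates_and_permutations_consistent(self, tiny_manifest, micro_config):
        cfg = stagenet.StageModelConfig(
            **{**micro_config.__dict__, "input_height": 16, "input_width": 24,
               "crop_width": 16}
        )
        model = build_model(cfg)
        dup = pd.concat([tiny_manifest.head(3)] * 2, ignore_index=True)
        out = predict(model, dup)
        np.testing.assert_allclose(
            out["predicted_hpf"][:3], out["predicted_hpf"][3:].to_numpy()
        )
        perm = tiny_manifest.sample(frac=1.0, random_state=0).reset_index(drop=True)
        out_perm = predict(model, perm)
        merged = out_perm.set_index("path")["predicted_hpf"]
        orig = predict(model, tiny_manifest).set_index("path")["predicted_hpf"]
        np.testing.assert_allclose(merged.loc[orig.index], orig)


class TestTransferLearn:
    def _toy_model(self):
        # parametric layers with 90, 9 and 1 parameters (input -> output)
        rng = np.random.default_rng(0)
        layers = [Flatten(), Dense(9, 9, rng), Dense(8, 1, rng), Dense(0, 1, rng)]
        return StageNet(layers)

    @pytest.mark.parametrize(
        "target, expected",
        [(0.05, 0.10), (0.01, 0.01), (0.11, 1.0), (1.0, 1.0)],
    )
    def test_greedy_whole_layer_fractions(self, target, expected):
        # layer sizes 90/9/1: unfreezing accumulates 0.01, 0.10, 1.00
        model = self._toy_model()
        achieved = model.set_retrained_fraction(target)
        assert achieved == pytest.approx(expected)

    def test_frozen_layers_marked_untrainable(self):
        model = self._toy_model()
        model.set_retrained_fraction(0.05)
        trainable = [l.trainable for l in model.parametric_layers()]
        assert trainable == [False, True, True]

    def test_invalid_fraction(self):
        model = self._toy_model()
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError, match="fraction"):
                model.set_retrained_fraction(bad)

    def test_frozen_params_bit_identical_after_finetune(
        self, tiny_manifest, micro_config, no_augmentation
    ):
        cfg = stagenet.StageModelConfig(
            **{**micro_config.__dict__, "input_height": 16, "input_width": 24,
               "crop_width": 16}
        )
        model = build_model(cfg)
        frozen_before = {}
        spec = TransferSpec(target_retrained_fraction=0.3, learning_rate=1e-3,
                            epochs=3, seed=0)
        # record conv weights (they stay frozen at this target: dense dominates)
        achieved = model.set_retrained_fraction(spec.target_retrained_fraction)
        for i, layer in enumerate(model.parametric_layers()):
            if not layer.trainable:
                frozen_before[i] = {k: v.copy() for k, v in layer.params().items()}
        assert frozen_before, "test requires at least one frozen layer"
        model, report = transfer_learn(
            model, tiny_manifest.head(16), spec, augmentation=no_augmentation
        )
        assert report["actual_retrained_fraction"] == pytest.approx(achieved)
        for i, layer in enumerate(model.parametric_layers()):
            if i in frozen_before:
                for k, v in layer.params().items():
                    assert np.array_equal(v, frozen_before[i][k]), f"layer {i} moved"
        assert report["final_train_loss"] >= 0


class TestSaliency:
    def test_linear_model_attribution_proportional_to_weights(self, rng):
        h, w, c = 6, 8, 3
        weights_rng = np.random.default_rng(2)
        dense = Dense(h * w * c, 1, weights_rng)
        model = StageNet([Flatten(), dense])
        img = rng.random((h, w, c))
        smap = saliency_map(model, img)
        expected = np.max(np.abs(dense.w[:, 0].reshape(h, w, c)), axis=-1)
        np.testing.assert_allclose(smap, expected, atol=1e-12)

    def test_shape_and_nonnegativity(self, micro_config, rng):
        model = build_model(micro_config)
        img = rng.random((16, 24, 3))
        smap = saliency_map(model, img)
        assert smap.shape == (16, 16)  # cropped input spatial shape
        assert (smap >= 0).all()

    def test_attribution_concentrates_on_embryo(self, tiny_manifest,
                                                no_augmentation):
        """After brief training the saliency should weight embryo pixels
        above background ones."""
        wells = sorted(set(tiny_manifest["well"]))
        train_m = tiny_manifest[tiny_manifest["well"].isin(wells[:3])]
        cfg = stagenet.scaled_config(epochs=6, seed=0)
        model = build_model(cfg)
        model, _ = train(model, train_m.reset_index(drop=True), None, cfg,
                         augmentation=no_augmentation)
        images, _ = plateio.load_batch(tiny_manifest.tail(1), 64, 96)
        img = images[0]
        smap = saliency_map(model, img)
        cropped = img[:, 16:80, 0]  # same field of view as the map
        embryo = cropped < 0.6
        if embryo.sum() > 10 and (~embryo).sum() > 10:
            assert smap[embryo].mean() > smap[~embryo].mean()
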