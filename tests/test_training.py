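"""Normalization, augmentation, architecture contracts and the train loop."""

import numpy as np
import pytest

from perfusionkit import nn
from perfusionkit.core import PerfusionSeries
from perfusionkit.training import (
    ArchSpec,
    AugmentRanges,
    NetworkModel,
    TrainConfig,
    augment,
    build_model,
    desk_train_config,
    normalize_series,
    train_model,
)


class TestNormalizeSeries:
    def test_affine_map(self):
        frames = np.full((3, 4, 4), 100.0)
        frames[1] = 300.0
        frames[2] = 200.0
        out = normalize_series(PerfusionSeries(frames=frames))
        assert np.allclose(out.frames[0], 0.0)
        assert np.allclose(out.frames[1], 1.0)
        assert np.allclose(out.frames[2], 0.5)

    def test_already_normalized_unchanged(self):
        rng = np.random.default_rng(0)
        frames = rng.random((4, 8, 8))
        frames.reshape(-1)[0] = 0.0
        frames.reshape(-1)[1] = 1.0
        out = normalize_series(PerfusionSeries(frames=frames))
        assert np.allclose(out.frames, frames)

    def test_constant_series_maps_to_zero(self):
        out = normalize_series(PerfusionSeries(frames=np.full((3, 4, 4), 7.0)))
        assert np.all(out.frames == 0.0)

    def test_normalization_is_global_not_per_frame(self):
        ramp = np.linspace(0.0, 1.0, 16).reshape(4, 4)
        frames = np.stack([ramp, 2.0 * ramp])
        out = normalize_series(PerfusionSeries(frames=frames))
        # per-frame scaling would map both frames onto [0, 1]
        assert out.frames[0].max() == pytest.approx(0.5)
        assert out.frames[1].max() == pytest.approx(1.0)


class TestAugment:
    def test_identity_ranges_return_input_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        mask = rng.random((32, 32)) > 0.5
        out, lab = augment(img, {"mask": mask}, rng, AugmentRanges())
        assert out is img and lab["mask"] is mask

    def test_pure_translation_shifts_mask_centroid(self):
        from scipy import ndimage

        img = np.zeros((64, 64))
        img[20:30, 25:35] = 1.0
        mask = img > 0.5

        class FixedRng:
            def uniform(self, lo, hi, size=None):
                if size == 2:
                    return np.array([5.0, 0.0])  # +5 rows
                return (lo + hi) / 2.0

            def normal(self, *a, **k):
                raise AssertionError("no noise expected")

        ranges = AugmentRanges(translation_px=5.0)
        out, lab = augment(img, {"mask": mask}, FixedRng(), ranges)
        c0 = ndimage.center_of_mass(mask)
        c1 = ndimage.center_of_mass(lab["mask"])
        assert c1[0] - c0[0] == pytest.approx(5.0, abs=0.05)
        assert c1[1] - c0[1] == pytest.approx(0.0, abs=0.05)

    def test_points_follow_the_same_transform_as_the_mask(self):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        img = np.zeros((64, 64))
        img[30:34, 40:44] = 1.0
        mask = img > 0.5
        pts = np.array([[31.5, 41.5]])
        ranges = AugmentRanges(translation_px=6.0, rotation_deg=15.0, scale=0.1)
        out, lab = augment(img, {"mask": mask, "points": pts}, rng, ranges)
        c = ndimage.center_of_mass(lab["mask"])
        assert np.hypot(c[0] - lab["points"][0][0], c[1] - lab["points"][0][1]) < 1.0

    def test_seeded_reproducibility(self):
        img = np.random.default_rng(1).random((32, 32))
        ranges = AugmentRanges(3.0, 10.0, 0.1, 0.2, 0.05)
        a, _ = augment(img, None, np.random.default_rng(42), ranges)
        b, _ = augment(img, None, np.random.default_rng(42), ranges)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0  # clipped


class TestArchContracts:
    def test_cnn_has_four_conv_blocks_and_two_fc(self):
        arch = ArchSpec("classifier_cnn", in_channels=5, out_units=2, input_size=64,
                        channels=(4, 8, 16, 32), fc_units=16)
        model = build_model(arch)
        convs = [l for l in model.net.layers if isinstance(l, nn.Conv2d)]
        pools = [l for l in model.net.layers if isinstance(l, nn.MaxPool2d)]
        bns = [l for l in model.net.layers if isinstance(l, nn.BatchNorm2d)]
        fcs = [l for l in model.net.layers if isinstance(l, nn.Linear)]
        assert len(convs) == 4 and len(pools) == 4 and len(bns) == 4 and len(fcs) == 2

    def test_l2_decay_applies_to_conv_kernels_only(self):
        arch = ArchSpec("classifier_cnn", in_channels=1, out_units=2, input_size=32,
                        channels=(2, 4, 4, 8), fc_units=8)
        model = build_model(arch)
        decayed = [p.name for p in model.params() if p.decay]
        undecayed = [p.name for p in model.params() if not p.decay]
        assert decayed and all("conv" in n and "weight" in n for n in decayed)
        assert all(("fc" in n) or ("bias" in n) or ("bn" in n) for n in undecayed)

    def test_defaults_echo_training_recipe(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 32
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.l2_weight == pytest.approx(0.001)
        assert cfg.dropout_p == pytest.approx(0.5)
        assert cfg.patience == 3000

    def test_unet_output_shapes(self):
        seg = build_model(ArchSpec("unet_seg", input_size=32, base=2, depth=2))
        act = build_model(ArchSpec("unet_action", input_size=32, base=2, depth=2))
        x = np.zeros((2, 1, 32, 32), dtype=np.float32)
        assert seg.forward(x).shape == (2, 1, 32, 32)
        assert act.forward(x).shape == (2, 4, 32, 32)


class TestOptimization:
    def test_adam_decreases_loss_on_quadratic_toy_problem(self):
        rng = np.random.default_rng(0)
        lin = nn.Linear(4, 1, rng)
        target = np.array([[1.0], [2.0], [3.0]], dtype=np.float32)
        x = rng.normal(0, 1, (3, 4)).astype(np.float32)
        opt = nn.Adam(lin.params(), lr=0.05)
        losses = []
        for _ in range(30):
            pred = lin.forward(x, train=True)
            loss, grad = nn.mse_loss(pred, target)
            losses.append(loss)
            opt.zero_grad()
            lin.backward(grad)
            opt.step()
        assert losses[-1] < losses[0] * 0.5

    def test_l2_decay_shrinks_only_decayed_params(self):
        rng = np.random.default_rng(1)
        conv = nn.Conv2d(1, 1, rng)
        opt = nn.Adam(conv.params(), lr=1e-3, l2_weight=10.0)
        w0 = np.abs(conv.weight.value).sum()
        for _ in range(5):
            opt.zero_grad()
            opt.step()  # zero data gradient: only decay acts
        assert np.abs(conv.weight.value).sum() < w0
        assert np.all(conv.bias.value == 0.0)


def _toy_seg_problem(n=4, size=32, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for _ in range(n):
        center = rng.uniform(12, 20, 2)
        rr, cc = np.mgrid[0:size, 0:size]
        d = np.hypot(rr - center[0], cc - center[1])
        mask = (d >= 5) & (d < 9)
        img = 0.2 + 0.6 * mask + 0.05 * rng.random((size, size))
        xs.append(img[None])
        ys.append(mask[None])
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


class TestTrainModel:
    def test_unet_overfits_four_samples(self):
        x, y = _toy_seg_problem()
        arch = ArchSpec("unet_seg", input_size=32, base=4, depth=2)
        cfg = desk_train_config(
            batch_size=4, max_iterations=120, eval_every=20, patience=120,
            augment=AugmentRanges(), seed=0, learning_rate=3e-3,
        )
        model, log = train_model(arch, (x, y), (x, y), cfg)
        logits = model.predict(x)
        pred = 1.0 / (1.0 + np.exp(-logits)) >= 0.5
        inter = (pred & (y > 0.5)).sum()
        dice = 2 * inter / (pred.sum() + (y > 0.5).sum())
        assert dice >= 0.95

    def test_early_stopping_with_frozen_metric(self):
        x, y = _toy_seg_problem(n=2)
        arch = ArchSpec("unet_seg", input_size=32, base=2, depth=1)
        cfg = desk_train_config(
            batch_size=2, max_iterations=500, eval_every=1, patience=10,
            augment=AugmentRanges(), learning_rate=0.0,  # frozen: no parameter updates
        )
        model, log = train_model(arch, (x, y), (x, y), cfg)
        evals = [r for r in log.records if r["val_metric"] is not None]
        # improvement only at the first evaluation, stop within patience + 1
        assert len(evals) <= 11

    def test_empty_dataset_rejected(self):
        arch = ArchSpec("unet_seg", input_size=32, base=2, depth=1)
        with pytest.raises(ValueError):
            train_model(arch, (np.zeros((0, 1, 32, 32)), np.zeros((0, 1, 32, 32))), None, TrainConfig())

    def test_checkpoint_round_trip(self, tmp_path):
        x, y = _toy_seg_problem(n=2)
        arch = ArchSpec("unet_seg", input_size=32, base=2, depth=1)
        cfg = desk_train_config(batch_size=2, max_iterations=5, eval_every=5, augment=AugmentRanges())
        model, _ = train_model(arch, (x, y), (x, y), cfg)
        path = tmp_path / "seg.npz"
        model.save(path)
        loaded = NetworkModel.load(path)
        assert np.allclose(loaded.predict(x), model.predict(x), atol=1e-6)
        assert loaded.arch == model.arch
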