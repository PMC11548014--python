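"""Segmentation network: loss contracts, training sanity, inference chain."""

import numpy as np
import pytest

from dualev.segnet import (
    SegNet,
    SegNetConfig,
    jaccard_loss,
    jaccard_grad,
    load_model,
    predict_image,
    predict_patch_image,
    save_model,
    train,
)


def tiny_cfg(**kw):
    base = dict(depth=2, base_channels=4, epochs=4, batch_size=4, crop=32, learning_rate=3e-3, seed=0)
    base.update(kw)
    return SegNetConfig.small(**base)


def spot_dataset(n=12, side=64, seed=0):
    """8-bit patches with bright discs and their value-10 maps."""
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        img = np.zeros((side, side), np.uint8)
        for _ in range(rng.integers(2, 5)):
            r, c = rng.integers(8, side - 8, size=2)
            rad = rng.integers(2, 4)
            yy, xx = np.mgrid[0:side, 0:side]
            img[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = rng.integers(60, 200)
        data.append((img, img >= 10))
    return data


class TestJaccardLoss:
    def test_exact_agreement_is_zero(self):
        t = np.zeros((1, 4, 4, 2))
        t[..., 1] = np.eye(4)
        t[..., 0] = 1 - t[..., 1]
        assert jaccard_loss(t, t, eps=0.0) == pytest.approx(0.0)

    def test_complement_approaches_one(self):
        t = np.zeros((1, 8, 8, 2))
        t[..., 1] = 1.0
        p = 1.0 - t
        assert jaccard_loss(p, t, eps=1e-6) == pytest.approx(1.0, abs=1e-4)

    def test_hand_enumerated_2x2(self):
        # pred probs and one-hot truth on a 2x2 toy, k=2
        p = np.array([[[[0.8, 0.2], [0.3, 0.7]], [[0.6, 0.4], [0.1, 0.9]]]])
        t = np.zeros_like(p)
        t[0, :, :, 1] = [[0, 1], [1, 0]]
        t[..., 0] = 1 - t[..., 1]
        eps = 1.0
        # class sums by hand
        i0 = 0.8 * 1 + 0.3 * 0 + 0.6 * 0 + 0.1 * 1
        u0 = (0.8 + 0.3 + 0.6 + 0.1) + 2 - i0
        i1 = 0.2 * 0 + 0.7 * 1 + 0.4 * 1 + 0.9 * 0
        u1 = (0.2 + 0.7 + 0.4 + 0.9) + 2 - i1
        expected = 1 - 0.5 * ((i0 + eps) / (u0 + eps) + (i1 + eps) / (u1 + eps))
        assert jaccard_loss(p, t, eps) == pytest.approx(expected)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        p = rng.random((2, 8, 8, 2))
        p /= p.sum(-1, keepdims=True)
        t = np.zeros_like(p)
        fg = rng.random((2, 8, 8)) > 0.5
        t[..., 1] = fg
        t[..., 0] = ~fg
        loss = jaccard_loss(p, t)
        assert 0.0 <= loss <= 1.0

    def test_gradient_matches_numeric(self):
        rng = np.random.default_rng(1)
        p = rng.random((1, 4, 4, 2))
        p /= p.sum(-1, keepdims=True)
        t = np.zeros_like(p)
        fg = rng.random((1, 4, 4)) > 0.5
        t[..., 1] = fg
        t[..., 0] = ~fg
        g = jaccard_grad(p, t)
        for idx in [(0, 1, 2, 0), (0, 3, 3, 1), (0, 0, 0, 1)]:
            eps = 1e-5
            pp = p.copy()
            pp[idx] += eps
            pm = p.copy()
            pm[idx] -= eps
            num = (jaccard_loss(pp, t) - jaccard_loss(pm, t)) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_loss(np.zeros((1, 4, 4, 2)), np.zeros((1, 5, 5, 2)))


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(tiny_cfg(), [])

    def test_loss_decreases_on_spot_data(self):
        run = train(tiny_cfg(epochs=6), spot_dataset(16))
        assert run.losses[-1] < run.losses[0]
        assert len(run.losses) == 6
        assert all(np.isfinite(l) for l in run.losses)

    def test_same_seed_identical_trajectory(self):
        d = spot_dataset(8)
        r1 = train(tiny_cfg(), d)
        r2 = train(tiny_cfg(), d)
        assert r1.losses == r2.losses

    def test_different_seed_differs(self):
        d = spot_dataset(8)
        r1 = train(tiny_cfg(seed=0), d)
        r2 = train(tiny_cfg(seed=1), d)
        assert r1.losses != r2.losses

    def test_single_sample_overfit(self):
        d = spot_dataset(1, side=32)
        run = train(tiny_cfg(epochs=30, crop=32), d * 4)
        assert run.losses[-1] < 0.25

    def test_invalid_crop_rejected(self):
        with pytest.raises(ValueError):
            SegNetConfig(depth=4, crop=100).validate()


class TestPrediction:
    @pytest.fixture(scope="class")
    def trained(self):
        return train(tiny_cfg(epochs=10, crop=64), spot_dataset(24, side=64) * 6)

    def test_prediction_deterministic(self, trained):
        img = spot_dataset(1, side=64, seed=99)[0][0]
        a = predict_patch_image(trained.model, img, patch=64)
        b = predict_patch_image(trained.model, img, patch=64)
        assert np.array_equal(a, b)

    def test_shape_preserved_odd_sizes(self, trained):
        for shape in [(300, 300), (256, 300)]:
            img = np.zeros(shape, np.uint8)
            out = predict_patch_image(trained.model, img, patch=256)
            assert out.shape == shape
            assert out.dtype == bool

    def test_blank_image_empty_mask(self, trained):
        img = np.zeros((128, 128), np.uint8)
        assert not predict_patch_image(trained.model, img, patch=64).any()

    def test_learns_threshold_rule(self, trained):
        img, truth = spot_dataset(1, side=64, seed=123)[0]
        pred = predict_patch_image(trained.model, img, patch=64)
        inter = (pred & truth).sum()
        union = (pred | truth).sum()
        assert union > 0
        assert inter / union > 0.8

    def test_save_load_round_trip(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_model(trained, path)
        model2 = load_model(path)
        img = spot_dataset(1, side=64, seed=7)[0][0]
        assert np.array_equal(
            predict_patch_image(trained.model, img, patch=64),
            predict_patch_image(model2, img, patch=64),
        )


def test_predict_image_full_chain(small_scene):
    """Raw-counts inference runs the preprocess->patch->stitch chain."""
    _, pair, _ = small_scene
    run = train(tiny_cfg(epochs=2), spot_dataset(8))
    out = predict_image(run.model, pair.mask_image)
    assert out.shape == pair.mask_image.shape
    assert out.dtype == bool
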