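"""Fusion U-Net: SE/AG blocks, variants, Dice loss, training, prediction."""

import numpy as np
import pytest

from kidseg import nn
from kidseg.dfln import (
    AGBlock,
    DFLN,
    DFLNConfig,
    SEBlock,
    augment_rotate,
    build_model,
    dice_loss,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
    train,
)
from kidseg.nn import Tensor


def tiny_config(**kw):
    defaults = dict(
        variant="parallel2", depth=2, base_channels=4, input_size=(32, 32),
        epochs=2, batch_size=4, augment_max_degrees=0.0, seed=0,
    )
    defaults.update(kw)
    return DFLNConfig(**defaults)


def blob_dataset(n, size=32, seed=0):
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(n):
        cy, cx = rng.integers(10, size - 10, 2)
        r = rng.integers(5, 9)
        yy, xx = np.mgrid[0:size, 0:size]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        image = (60 + 80 * mask + rng.normal(0, 8, (size, size))).clip(0, 255)
        data.append((image.astype(np.uint8), mask))
    return data


class TestSEBlock:
    def test_zero_input_zero_output(self):
        se = SEBlock(4, 2, np.random.default_rng(0))
        out = se(Tensor(np.zeros((1, 4, 3, 3))))
        assert (out.data == 0).all()

    def test_identical_channels_identical_gates(self):
        # with permutation-symmetric excitation weights, identical channels
        # must receive identical gates
        se = SEBlock(3, 1, np.random.default_rng(1))
        se.fc1.weight.data = np.full_like(se.fc1.weight.data, 0.3)
        se.fc2.weight.data = np.full_like(se.fc2.weight.data, 0.2)
        se.fc1.bias.data[:] = 0.1
        se.fc2.bias.data[:] = -0.1
        x = np.tile(np.random.default_rng(2).normal(size=(1, 1, 4, 4)), (1, 3, 1, 1))
        out = se(Tensor(x))
        ratio = out.data / np.where(x == 0, 1, x)
        assert np.allclose(ratio[0, 0], ratio[0, 1]) and np.allclose(ratio[0, 1], ratio[0, 2])

    def test_matches_hand_computed_forward(self):
        se = SEBlock(2, 1, np.random.default_rng(0))
        x = np.array([[[[2.0]], [[-1.0]]]])  # (1, 2, 1, 1)
        # set the bottleneck weights explicitly
        se.fc1.weight.data = np.array([[[[1.0]], [[0.0]]], [[[0.0]], [[1.0]]]], np.float32)
        se.fc1.bias.data = np.zeros(2, np.float32)
        se.fc2.weight.data = np.array([[[[0.5]], [[0.0]]], [[[0.0]], [[0.5]]]], np.float32)
        se.fc2.bias.data = np.zeros(2, np.float32)
        out = se(Tensor(x))
        squeeze = np.array([2.0, -1.0])  # global max per channel
        excited = 0.5 * np.maximum(squeeze, 0)
        gates = 1 / (1 + np.exp(-excited))
        np.testing.assert_allclose(out.data[0, :, 0, 0], x[0, :, 0, 0] * gates, rtol=1e-6)

    def test_reduction_clamped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="kidseg.dfln"):
            SEBlock(2, 8, np.random.default_rng(0))
        assert any("clamping" in r.message for r in caplog.records)

    def test_gates_strictly_inside_unit_interval(self):
        se = SEBlock(4, 2, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(2, 4, 5, 5)).astype(np.float32)
        out = se(Tensor(x))
        nonzero = x != 0
        gates = out.data[nonzero] / x[nonzero]
        assert (gates > 0).all() and (gates < 1).all()


class TestAGBlock:
    def test_zero_skip_zero_output(self):
        ag = AGBlock(3, 3, np.random.default_rng(0))
        skip = Tensor(np.zeros((1, 3, 4, 4)))
        gate = Tensor(np.random.default_rng(1).normal(size=(1, 3, 4, 4)))
        assert (ag(skip, gate).data == 0).all()

    def test_saturated_attention_is_identity(self):
        ag = AGBlock(2, 2, np.random.default_rng(0))
        ag.att.weight.data = np.zeros_like(ag.att.weight.data)
        ag.att.bias.data = np.array([50.0], np.float32)  # sigmoid -> 1
        skip = Tensor(np.random.default_rng(2).normal(size=(1, 2, 4, 4)))
        gate = Tensor(np.random.default_rng(3).normal(size=(1, 2, 4, 4)))
        np.testing.assert_allclose(ag(skip, gate).data, skip.data, rtol=1e-6)

    def test_hand_computed_tiny_case(self):
        ag = AGBlock(1, 1, np.random.default_rng(0))
        ag.att.weight.data = np.array([[[[1.0]], [[1.0]]]], np.float32)
        ag.att.bias.data = np.zeros(1, np.float32)
        skip = np.array([[[[1.0, -2.0], [0.5, 3.0]]]])
        gate = np.array([[[[0.5, 0.5], [0.5, 0.5]]]])
        out = ag(Tensor(skip), Tensor(gate)).data
        att = 1 / (1 + np.exp(-(np.maximum(skip, 0) + np.maximum(gate, 0))[0, 0]))
        np.testing.assert_allclose(out[0, 0], skip[0, 0] * att, rtol=1e-6)

    def test_gate_upsampled_when_half_size(self):
        ag = AGBlock(2, 2, np.random.default_rng(0))
        out = ag(
            Tensor(np.ones((1, 2, 4, 4))), Tensor(np.ones((1, 2, 2, 2)))
        )
        assert out.shape == (1, 2, 4, 4)

    def test_channel_mismatch_raises(self):
        ag = AGBlock(2, 2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channel mismatch"):
            ag(Tensor(np.ones((1, 3, 4, 4))), Tensor(np.ones((1, 2, 4, 4))))


class TestBuildModel:
    @pytest.mark.parametrize("variant", ["serial1", "serial2", "parallel1", "parallel2"])
    def test_forward_shape_and_range(self, variant):
        model = build_model(tiny_config(variant=variant))
        x = Tensor(np.random.default_rng(0).uniform(size=(1, 1, 32, 32)))
        out = model(x)
        assert out.shape == (1, 1, 32, 32)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_variants_differ_but_share_ag_structure(self):
        x = np.random.default_rng(1).uniform(size=(1, 1, 32, 32))
        outs, ag_counts = {}, {}
        for variant in ("serial1", "serial2", "parallel1", "parallel2"):
            model = build_model(tiny_config(variant=variant))
            outs[variant] = model(Tensor(x)).data
            ag_counts[variant] = sum(
                p.data.size for b in model.ag_blocks for p in b.parameters()
            )
        vs = list(outs)
        assert all(
            not np.allclose(outs[a], outs[b]) for i, a in enumerate(vs) for b in vs[i + 1 :]
        )
        assert ag_counts["parallel1"] == ag_counts["parallel2"]

    def test_invalid_variant_lists_options(self):
        with pytest.raises(ValueError, match="serial1.*parallel2"):
            DFLNConfig(variant="bogus")

    def test_depth_divisibility_rule(self):
        DFLNConfig(variant="parallel2", depth=3, input_size=(64, 64))  # ok
        with pytest.raises(ValueError, match="divisible"):
            DFLNConfig(variant="parallel2", depth=7, input_size=(64, 64))


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        q = np.zeros((8, 8))
        q[2:6, 2:6] = 1
        assert dice_loss(q, q) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_prediction(self):
        n = 64
        q = np.zeros(n)
        q[: n // 2] = 1
        p = 1 - q
        assert dice_loss(p, q) == pytest.approx(1 - 1 / (n + 1), abs=1e-12)

    def test_uniform_half_probability(self):
        n = 100
        q = np.zeros(n)
        q[: n // 2] = 1
        p = np.full(n, 0.5)
        assert dice_loss(p, q) == pytest.approx(1 - (n / 2 + 1) / (n + 1), abs=1e-12)

    def test_symmetry_for_binary_masks(self, rng):
        p = (rng.random((10, 10)) > 0.5).astype(float)
        q = (rng.random((10, 10)) > 0.5).astype(float)
        assert dice_loss(p, q) == pytest.approx(dice_loss(q, p), abs=1e-12)

    def test_consistent_with_dsc_as_eps_vanishes(self, rng):
        from kidseg.geometry import dsc

        p = rng.random((12, 12)) > 0.4
        q = rng.random((12, 12)) > 0.6
        assert 1 - dice_loss(p.astype(float), q.astype(float), eps=1e-9) == pytest.approx(
            dsc(p, q), abs=1e-6
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAugmentRotate:
    def test_zero_degrees_identity(self):
        img = np.arange(64, dtype=float).reshape(8, 8)
        mask = img > 30
        out_img, out_mask = augment_rotate(img, mask, 0.0, seed=1)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_90_degree_override_relocates_square(self):
        mask = np.zeros((9, 9), bool)
        mask[1:3, 6:8] = True
        img = mask * 200.0
        _, out_mask = augment_rotate(img, mask, 90.0, seed=0, angle_override=90.0)
        expected = np.zeros((9, 9), bool)
        # rotating 90 deg counter-clockwise about the canvas center
        ys, xs = np.nonzero(mask)
        for y, x in zip(ys, xs):
            expected[4 - (x - 4), 4 + (y - 4)] = True
        assert (out_mask == expected).all()

    def test_same_seed_same_pair(self):
        rng_img = np.random.default_rng(0).uniform(size=(16, 16))
        mask = rng_img > 0.5
        a = augment_rotate(rng_img, mask, 20.0, seed=9)
        b = augment_rotate(rng_img, mask, 20.0, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestTraining:
    def test_loss_descends_on_blobs(self):
        cfg = tiny_config(epochs=8, learning_rate=3e-3)
        model = build_model(cfg)
        result = train(model, blob_dataset(8), cfg)
        assert result.train_losses[-1] < result.train_losses[0]

    def test_zero_learning_rate_frozen(self):
        cfg = tiny_config(epochs=3, learning_rate=0.0)
        model = build_model(cfg)
        result = train(model, blob_dataset(4), cfg)
        assert max(result.train_losses) - min(result.train_losses) < 1e-6

    def test_seeded_training_reproducible(self):
        histories = []
        for _ in range(2):
            cfg = tiny_config(epochs=2)
            model = build_model(cfg)
            histories.append(train(model, blob_dataset(4), cfg).train_losses)
        assert histories[0] == histories[1]

    def test_empty_dataset_rejected(self):
        cfg = tiny_config()
        with pytest.raises(ValueError):
            train(build_model(cfg), [], cfg)


class TestPredictMask:
    def test_saturated_head_full_frame(self):
        model = build_model(tiny_config())
        model.head.bias.data = np.array([50.0], np.float32)
        image = np.zeros((32, 32), np.uint8)
        seg, contour = predict_mask(model, image)
        assert seg.binary_mask.all() and not seg.no_object
        border = {
            (x, y) for y in range(32) for x in range(32)
            if x in (0, 31) or y in (0, 31)
        }
        assert {tuple(map(int, p)) for p in contour.points} == border

    def test_suppressed_head_no_object(self):
        model = build_model(tiny_config())
        model.head.bias.data = np.array([-50.0], np.float32)
        seg, contour = predict_mask(model, np.zeros((32, 32), np.uint8))
        assert seg.no_object and contour is None

    def test_trained_model_beats_empty_mask(self):
        from kidseg.geometry import dsc

        cfg = tiny_config(epochs=10, learning_rate=3e-3)
        model = build_model(cfg)
        data = blob_dataset(8)
        train(model, data, cfg)
        held_img, held_mask = blob_dataset(1, seed=99)[0]
        seg, _ = predict_mask(model, held_img)
        assert dsc(seg.binary_mask, held_mask) > dsc(np.zeros_like(held_mask), held_mask)

    def test_resizes_foreign_image(self):
        model = build_model(tiny_config())
        seg, _ = predict_mask(model, np.full((48, 40), 128, np.uint8))
        assert seg.probability_map.shape == (48, 40)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        model = build_model(tiny_config())
        x = np.random.default_rng(0).uniform(size=(32, 32))
        before = model.forward_array(x[None])[0]
        save_checkpoint(model, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        after = loaded.forward_array(x[None])[0]
        np.testing.assert_array_equal(before, after)
        assert loaded.config.variant == "parallel2"
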