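"""Network construction: shapes, parameter counts, freezing, trainability."""

import numpy as np
import pytest

from iwnet import nn
from iwnet.architecture import (BlockSpec, IWNetModel, UNetBlock,
                                build_first_block, build_iwnet,
                                count_parameters, predict_automatic,
                                predict_guided)
from iwnet.geometry import PointPair
from iwnet.losses import iou_loss, iou_loss_grad

SMALL = BlockSpec(stage_filters=(2, 4, 6, 8), input_channels=1)


class TestParameterCount:
    def test_single_conv_bn_unit(self):
        # 3x3x3 conv 1->8 with bias plus affine BN: 27*8 + 8 + 16 = 240
        conv = nn.Conv3d(1, 8, bias=True)
        bn = nn.BatchNorm3d(8)
        assert conv.n_params() + bn.n_params() == 240

    def test_reference_first_block_total(self):
        assert count_parameters(build_first_block()) == 1_592_093

    def test_freezing_is_structural_only(self):
        model = build_first_block(BlockSpec(stage_filters=(2, 4)))
        before = count_parameters(model)
        model.block1.frozen = True
        assert count_parameters(model) == before

    def test_skip_concatenation_widens_decoder_kernels(self):
        # each decoder conv sees 2*f input channels; the skip contributes
        # exactly 27*f*f kernel weights per level
        block = UNetBlock(SMALL)
        for j, i in enumerate(range(SMALL.depth - 1, -1, -1)):
            f = SMALL.stage_filters[i]
            assert block.dec[j].conv.w.shape == (f, 2 * f, 3, 3, 3)


class TestForwardContracts:
    def test_output_shape_and_range(self, rng):
        model = build_first_block(SMALL)
        x = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        y = model.block1.forward(x)
        assert y.shape == (2, 1, 16, 16, 16)
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_fully_convolutional_across_sizes(self, rng):
        model = build_first_block(SMALL)
        for size in (8, 16, 32):
            x = rng.random((1, 1, size, size, size)).astype(np.float32)
            assert model.block1.forward(x).shape == (1, 1, size, size, size)

    def test_indivisible_shape_rejected(self, rng):
        model = build_first_block(SMALL)
        x = rng.random((1, 1, 12, 12, 12)).astype(np.float32)
        with pytest.raises(ValueError, match="divisible"):
            model.block1.forward(x)

    def test_inference_is_deterministic(self, rng):
        model = build_first_block(SMALL)
        x = rng.random((1, 16, 16, 16), dtype=np.float32)
        a = predict_automatic(model, x)
        b = predict_automatic(model, x)
        assert np.array_equal(a, b)

    def test_batch_of_identical_inputs_gives_identical_outputs(self, rng):
        model = build_first_block(SMALL)
        cube = rng.random((16, 16, 16)).astype(np.float32)
        out = predict_automatic(model, np.stack([cube, cube]))
        assert np.array_equal(out[0], out[1])

    def test_unnormalized_input_rejected(self, rng):
        model = build_first_block(SMALL)
        with pytest.raises(ValueError, match="normalized"):
            predict_automatic(model, rng.random((16, 16, 16)) * 900 - 500)


class TestGuidedPath:
    def test_zero_map_still_yields_valid_output(self, rng):
        model = build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, 3))
        x = rng.random((16, 16, 16)).astype(np.float32)
        with pytest.warns(RuntimeWarning, match="zero weight map"):
            initial, corrected = predict_guided(model, x, None)
        assert corrected.shape == x.shape
        assert 0.0 <= corrected.min() and corrected.max() <= 1.0

    def test_both_outputs_have_input_shape(self, rng):
        model = build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, 3))
        x = rng.random((16, 16, 16)).astype(np.float32)
        initial, corrected = predict_guided(model, x, PointPair((4, 8, 8), (12, 8, 8)))
        assert initial.shape == corrected.shape == x.shape

    def test_initial_prediction_ignores_second_block(self, rng):
        model = build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, 3))
        solo = IWNetModel(model.block1)
        x = rng.random((16, 16, 16)).astype(np.float32)
        assert np.array_equal(predict_automatic(model, x),
                              predict_automatic(solo, x))

    def test_frozen_first_block_is_bit_identical_across_block2_steps(self, rng):
        model = build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, 3))
        x = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        m = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        probe = model.block1.forward(x, training=False).copy()
        opt = nn.Adam(model.block2.layers(), lr=1e-2)
        truth = (rng.random((2, 16, 16, 16)) > 0.7)
        for _ in range(3):
            _, corrected = model.forward_guided(x, m, training=True)
            opt.zero_grad()
            grad = np.stack([iou_loss_grad(truth[i], corrected[i, 0])[None]
                             for i in range(2)]).astype(np.float32)
            model.block2.backward(grad)
            opt.step()
        assert np.array_equal(model.block1.forward(x, training=False), probe)

    def test_block2_gradients_are_nonzero(self, rng):
        model = build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, 3))
        x = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        m = rng.random((2, 1, 16, 16, 16)).astype(np.float32)
        truth = (rng.random((2, 16, 16, 16)) > 0.7)
        _, corrected = model.forward_guided(x, m, training=True)
        for l in model.block2.layers():
            l.zero_grad()
        grad = np.stack([iou_loss_grad(truth[i], corrected[i, 0])[None]
                         for i in range(2)]).astype(np.float32)
        model.block2.backward(grad)
        total = sum(float(np.abs(g).sum()) for l in model.block2.layers()
                    for g in l.grads)
        assert total > 0.0


class TestTraining:
    def test_fifty_steps_reduce_the_loss_on_one_phantom(self, tiny_phantom):
        x = tiny_phantom.image.values.astype(np.float32)[None, None]
        truth = tiny_phantom.masks[0]
        block = UNetBlock(BlockSpec((2, 4, 6, 8)), np.random.default_rng(0))
        opt = nn.Adam(block.layers(), lr=1e-3)
        first = None
        for step in range(50):
            pred = block.forward(x, training=True)
            loss = iou_loss(truth, pred[0, 0])
            if first is None:
                first = loss
            opt.zero_grad()
            block.backward(iou_loss_grad(truth, pred[0, 0])[None, None]
                           .astype(np.float32))
            opt.step()
        final = iou_loss(truth, block.forward(x, training=False)[0, 0])
        assert final < first

    def test_conv_gradient_matches_finite_difference(self, rng):
        # spot-check the engine's weight gradient on a fixed BN-free conv
        conv = nn.Conv3d(2, 3, bias=True, rng=rng)
        x = rng.random((2, 2, 4, 4, 4)).astype(np.float32)

        def loss():
            y = conv.forward(x)
            return 0.5 * float(np.sum(y * y)), y

        L, y = loss()
        conv.zero_grad()
        conv.backward(y)
        g = conv.grads[0][1, 0, 0, 1, 2]
        eps = 1e-2
        conv.w[1, 0, 0, 1, 2] += eps
        Lp, _ = loss()
        conv.w[1, 0, 0, 1, 2] -= 2 * eps
        Lm, _ = loss()
        conv.w[1, 0, 0, 1, 2] += eps
        assert g == pytest.approx((Lp - Lm) / (2 * eps), rel=1e-2)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, 3), seed=3)
        x = rng.random((16, 16, 16)).astype(np.float32)
        pts = PointPair((4, 8, 8), (12, 8, 8))
        before = predict_guided(model, x, pts)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = IWNetModel.load(path)
        after = predict_guided(loaded, x, pts)
        assert np.array_equal(before[0], after[0])
        assert np.array_equal(before[1], after[1])
        assert loaded.n_params() == model.n_params()


def test_block_spec_validation():
    with pytest.raises(ValueError):
        BlockSpec(stage_filters=(8,))
    with pytest.raises(ValueError):
        BlockSpec(stage_filters=(4, 8), input_channels=0)
    with pytest.raises(ValueError, match="3 input channels"):
        build_iwnet(SMALL, BlockSpec(SMALL.stage_filters, input_channels=2))
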