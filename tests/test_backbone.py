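import numpy as np
import pytest

import oracles
from lesionseg.backbone import (
    DenseAttentionUNet,
    DenseBlock,
    DenseLayer,
    DecoderLevel,
    ModelConfig,
    TransitionDown,
    channel_plan,
)
from lesionseg.nn.tensor import Tensor, no_grad
from lesionseg.training import initialize_weights

TINY = ModelConfig(
    base_channels=4,
    growth_rate=3,
    block_layers=(1, 1, 1, 1),
    reduction_r=2,
    decoder_channels=(8, 6, 5, 4),
)


def randomize(module, rng, std=0.3):
    for _, p in module.named_parameters():
        p.data = rng.normal(scale=std, size=p.data.shape).astype(np.float32)


class TestDenseLayer:
    def test_shape_contract(self, rng):
        layer = DenseLayer(8, 12)
        randomize(layer, rng)
        out = layer(Tensor(rng.normal(size=(2, 8, 16, 16)).astype(np.float32)))
        assert out.data.shape == (2, 12, 16, 16)

    def test_zero_conv_weights_give_zero(self, rng):
        layer = DenseLayer(4, 6)
        layer.conv.weight.data[:] = 0
        layer.conv.bias.data[:] = 0
        out = layer(Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_direct_oracle(self, rng):
        layer = DenseLayer(2, 3)
        randomize(layer, rng)
        x = rng.normal(size=(1, 2, 5, 5)).astype(np.float32)
        out = layer(Tensor(x))
        normed = oracles.batch_norm_loop(
            x, layer.bn.weight.data, layer.bn.bias.data, eps=layer.bn.eps
        )
        expected = oracles.conv2d_loop(
            np.maximum(normed, 0), layer.conv.weight.data, layer.conv.bias.data, padding=1
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-5)


class TestDenseBlock:
    def test_empty_block_is_identity(self, rng):
        block = DenseBlock(5, 0, 3)
        x = Tensor(rng.normal(size=(1, 5, 4, 4)).astype(np.float32))
        assert block(x) is x

    def test_channel_arithmetic(self):
        block = DenseBlock(16, 4, 12)
        assert block.out_channels == 64

    def test_output_channels_executed(self, rng):
        block = DenseBlock(4, 3, 2)
        randomize(block, rng)
        out = block(Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32)))
        assert out.data.shape == (2, 4 + 3 * 2, 8, 8)

    def test_two_layer_unrolled_oracle(self, rng):
        block = DenseBlock(3, 2, 2)
        randomize(block, rng)
        x = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        out = block(x)
        # unroll by hand with the tested layers themselves
        y0 = block.layers[0](x)
        cat0 = np.concatenate([x.data, y0.data], axis=1)
        y1 = block.layers[1](Tensor(cat0))
        expected = np.concatenate([x.data, y0.data, y1.data], axis=1)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)


class TestTransitionDown:
    def test_compression_and_halving(self, rng):
        trans = TransitionDown(64, 0.5)
        randomize(trans, rng)
        out = trans(Tensor(rng.normal(size=(1, 64, 16, 16)).astype(np.float32)))
        assert out.data.shape == (1, 32, 8, 8)

    def test_constant_image_stays_constant(self):
        trans = TransitionDown(2, 1.0)
        trans.conv.weight.data = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1)
        trans.conv.bias.data[:] = 0
        out = trans(Tensor(np.full((1, 2, 4, 4), 3.0, np.float32)))
        np.testing.assert_allclose(out.data, 3.0, atol=1e-6)

    def test_odd_dims_floor(self, rng):
        trans = TransitionDown(3, 0.5)
        randomize(trans, rng)
        out = trans(Tensor(rng.normal(size=(1, 3, 5, 7)).astype(np.float32)))
        assert out.data.shape == (1, 2, 2, 3)

    def test_stepwise_oracle(self, rng):
        trans = TransitionDown(4, 0.5)
        randomize(trans, rng)
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        out = trans(Tensor(x))
        proj = oracles.conv2d_loop(x, trans.conv.weight.data, trans.conv.bias.data)
        pooled = proj.reshape(1, 2, 3, 2, 3, 2).mean(axis=(3, 5))
        np.testing.assert_allclose(out.data, pooled, atol=1e-5)


class TestDecoderLevel:
    def test_shape_contract(self, rng):
        level = DecoderLevel(deep_channels=128, skip_channels=64, out_channels=32,
                             reduction=8)
        randomize(level, rng)
        deep = Tensor(rng.normal(size=(1, 128, 16, 16)).astype(np.float32))
        skip = Tensor(rng.normal(size=(1, 64, 32, 32)).astype(np.float32))
        out = level(deep, skip)
        assert out.data.shape == (1, 32, 32, 32)

    def test_zero_inputs_zero_weights_give_zero(self):
        level = DecoderLevel(4, 4, 3, reduction=2)
        deep = Tensor(np.zeros((1, 4, 8, 8), np.float32))
        skip = Tensor(np.zeros((1, 4, 16, 16), np.float32))
        out = level(deep, skip)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_manual_composition_oracle(self, rng):
        level = DecoderLevel(5, 4, 3, reduction=2)
        randomize(level, rng, std=0.2)
        deep = Tensor(rng.normal(size=(1, 5, 4, 4)).astype(np.float32))
        skip = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        out = level(deep, skip)
        # compose the four stages from the already-tested submodules
        from lesionseg.nn import concat
        from lesionseg.nn import functional as F

        g = level.up_conv(F.upsample2(deep))
        gated, _ = level.gate(skip, g)
        merged = concat([gated, g], axis=1)
        expected = level.fuse(level.channel_attention(merged))
        np.testing.assert_allclose(out.data, expected.data, atol=1e-6)


class TestChannelPlan:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_plan_matches_built_model(self, seed):
        rng = np.random.default_rng(seed)
        cfg = ModelConfig(
            base_channels=int(rng.integers(2, 8)),
            growth_rate=int(rng.integers(2, 8)),
            block_layers=tuple(int(v) for v in rng.integers(1, 3, 4)),
            compression=float(rng.uniform(0.4, 1.0)),
            reduction_r=2,
            decoder_channels=tuple(int(v) for v in rng.integers(4, 12, 4)),
        )
        plan = channel_plan(cfg)
        model = DenseAttentionUNet(cfg)
        assert [b.out_channels for b in model.enc_blocks] == plan["skips"]
        assert [t.out_channels for t in model.transitions] == plan["transitions"]
        assert model.bottleneck.out_channels == plan["bottleneck"][0]
        for lvl, deep_c, cat_c, out_c in zip(
            model.decoder_levels, plan["decoder_deep_in"], plan["decoder_concat"],
            plan["decoder_out"],
        ):
            assert lvl.up_conv.in_channels == deep_c
            assert lvl.channel_attention.channels == cat_c
            assert lvl.fuse.out_channels == out_c
        # executed shapes agree: the forward pass would raise on any mismatch
        initialize_weights(model, seed=seed)
        with no_grad():
            out = model(Tensor(np.zeros((1, cfg.in_channels, 32, 32), np.float32)))
        assert out.data.shape == (1, cfg.n_classes, 32, 32)


class TestForward:
    def test_shape_64(self, rng):
        model = DenseAttentionUNet(TINY)
        initialize_weights(model, seed=0)
        with no_grad():
            out = model(Tensor(rng.normal(size=(2, 1, 64, 64)).astype(np.float32)))
        assert out.data.shape == (2, 2, 64, 64)

    def test_shape_128(self, rng):
        # 128x128 input resolution convention
        model = DenseAttentionUNet(TINY)
        initialize_weights(model, seed=0)
        with no_grad():
            out = model(Tensor(rng.normal(size=(1, 1, 128, 128)).astype(np.float32)))
        assert out.data.shape == (1, 2, 128, 128)

    def test_indivisible_size_raises(self, rng):
        model = DenseAttentionUNet(TINY)
        with pytest.raises(ValueError, match="divisible by 16"):
            model(Tensor(np.zeros((1, 1, 40, 40), np.float32)))

    def test_wrong_channel_count_raises(self):
        model = DenseAttentionUNet(TINY)
        with pytest.raises(ValueError, match="input channels"):
            model(Tensor(np.zeros((1, 3, 32, 32), np.float32)))

    def test_gradient_reaches_every_parameter(self, rng):
        from lesionseg.nn import functional as F

        model = DenseAttentionUNet(TINY)
        initialize_weights(model, seed=1)
        x = Tensor(rng.normal(size=(2, 1, 32, 32)).astype(np.float32))
        labels = rng.integers(0, 2, size=(2, 32, 32))
        loss = F.softmax_cross_entropy(model(x), labels)
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.any(p.grad != 0), name

    def test_determinism_under_seed(self, rng):
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        outs = []
        for _ in range(2):
            model = DenseAttentionUNet(TINY)
            initialize_weights(model, seed=42)
            model.eval()
            with no_grad():
                outs.append(model(Tensor(x.copy())).data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_parameter_count_independent_of_resolution(self, rng):
        model = DenseAttentionUNet(TINY)
        initialize_weights(model, seed=0)
        n_params = sum(p.data.size for p in model.parameters())
        with no_grad():
            model(Tensor(np.zeros((1, 1, 32, 32), np.float32)))
            model(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
        assert sum(p.data.size for p in model.parameters()) == n_params

    def test_state_dict_round_trip_bit_identical(self, rng, tmp_path):
        from lesionseg.training import load_checkpoint, save_checkpoint, TrainHistory

        model = DenseAttentionUNet(TINY)
        initialize_weights(model, seed=3)
        model.eval()
        x = Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        with no_grad():
            ref = model(x).data
        ckpt = {
            "model_config": TINY.to_dict(),
            "state": model.state_dict(),
            "norm_mean": 0.0,
            "norm_std": 1.0,
            "history": TrainHistory(),
        }
        save_checkpoint(ckpt, tmp_path / "ck.npz")
        loaded, meta = load_checkpoint(tmp_path / "ck.npz")
        with no_grad():
            out = loaded(x).data
        np.testing.assert_array_equal(ref, out)


class TestModelConfig:
    def test_defaults_validate(self):
        cfg = ModelConfig()
        assert cfg.block_layers == (4, 4, 4, 4)

    def test_bad_compression_rejected(self):
        with pytest.raises(ValueError, match="compression"):
            ModelConfig(compression=0.0)

    def test_wrong_block_count_rejected(self):
        with pytest.raises(ValueError, match="four"):
            ModelConfig(block_layers=(1, 2, 3))

    def test_round_trip_dict(self):
        cfg = ModelConfig.small()
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg
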