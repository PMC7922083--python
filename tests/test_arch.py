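"""Architecture contracts: encoder shape arithmetic, dense-block growth,
transitions, attention gates, decoder topology and the full forward pass."""

import numpy as np
import pytest

from adenseunet import (
    ModelConfig,
    build_attention_gate,
    build_decoder_node,
    build_dense_block,
    build_model,
    build_transition,
    count_parameters,
    infer_encoder_shapes,
    nn,
)
from adenseunet.arch import grid_columns, node_channels
from adenseunet.nn import functional as F
from adenseunet.nn.tensor import Tensor
from conftest import reduced_model_config, tiny_model_config


class TestEncoderShapes:
    def test_default_spatial_sides(self):
        shapes = infer_encoder_shapes(ModelConfig())
        assert [s.spatial_side for s in shapes] == [112, 56, 28, 14, 7]

    def test_default_channels(self):
        shapes = infer_encoder_shapes(ModelConfig())
        assert [s.channels for s in shapes] == [96, 384, 768, 2112, 2208]

    def test_halving_for_other_input(self):
        cfg = ModelConfig(input_side=96)
        assert [s.spatial_side for s in infer_encoder_shapes(cfg)] == [48, 24, 12, 6, 3]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            infer_encoder_shapes(ModelConfig(input_side=100))

    def test_depth_mismatch_rejected(self):
        with pytest.raises(ValueError, match="depth_s"):
            infer_encoder_shapes(ModelConfig(block_layers=[6, 12, 36]))

    def test_built_encoder_matches_inferred_contract(self):
        cfg = reduced_model_config()
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(0).random((1, 3, 96, 96), dtype=np.float32)
        model.eval()
        with nn.no_grad():
            feats = model.encoder_features(Tensor(x))
        for feat, contract in zip(feats, infer_encoder_shapes(cfg)):
            assert feat.shape[1] == contract.channels
            assert feat.shape[2] == feat.shape[3] == contract.spatial_side


class TestDenseBlock:
    @pytest.mark.parametrize(
        "in_ch,n,k,out_ch", [(96, 6, 48, 384), (192, 12, 48, 768), (16, 3, 8, 40)]
    )
    def test_channel_arithmetic(self, in_ch, n, k, out_ch):
        _, got = build_dense_block(in_ch, n, k)
        assert got == out_ch

    def test_growth_linear_in_layer_count(self):
        for n in range(7):
            _, out = build_dense_block(8, n, 4)
            assert out == 8 + n * 4

    def test_zero_layers_is_identity(self):
        block, out_ch = build_dense_block(5, 0, 48)
        assert out_ch == 5
        x = Tensor(np.random.default_rng(0).standard_normal((1, 5, 6, 6)))
        assert np.array_equal(block(x).data, x.data)

    def test_forward_channels_and_spatial(self):
        block, out_ch = build_dense_block(6, 3, 4, rate=2, seed=1)
        x = Tensor(np.random.default_rng(1).random((2, 6, 12, 12)).astype(np.float32))
        block.eval()
        with nn.no_grad():
            y = block(x)
        assert y.shape == (2, out_ch, 12, 12)

    def test_negative_layers_rejected(self):
        with pytest.raises(ValueError):
            build_dense_block(8, -1, 4)


class TestTransition:
    @pytest.mark.parametrize(
        "in_ch,theta,out_ch", [(384, 0.5, 192), (2112, 0.5, 1056), (7, 1.0, 7)]
    )
    def test_compression_arithmetic(self, in_ch, theta, out_ch):
        _, got = build_transition(in_ch, theta)
        assert got == out_ch

    def test_spatial_halving(self):
        t, out_ch = build_transition(6, 0.5, seed=0)
        x = Tensor(np.random.default_rng(0).random((1, 6, 8, 8)).astype(np.float32))
        t.eval()
        with nn.no_grad():
            y = t(x)
        assert y.shape == (1, out_ch, 4, 4)

    @pytest.mark.parametrize("theta", [0.0, -0.2, 1.5])
    def test_invalid_theta_rejected(self, theta):
        with pytest.raises(ValueError):
            build_transition(8, theta)


class TestAttentionGate:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.skip = Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        self.gate_in = Tensor(rng.standard_normal((2, 6, 4, 4)).astype(np.float32))

    def test_saturated_gate_is_identity(self):
        g = build_attention_gate(4, 6, 3, seed=1)
        g.saturate()
        assert np.array_equal(g(self.skip, self.gate_in).data, self.skip.data)

    def test_zeroed_gate_halves_skip(self):
        g = build_attention_gate(4, 6, 3, seed=1)
        g.zero_weights()
        np.testing.assert_allclose(
            g(self.skip, self.gate_in).data, 0.5 * self.skip.data, atol=1e-7
        )

    def test_output_shape_and_attenuation(self):
        g = build_attention_gate(4, 6, 3, seed=2)
        out = g(self.skip, self.gate_in)
        assert out.shape == self.skip.shape
        assert np.all(np.abs(out.data) <= np.abs(self.skip.data) + 1e-7)

    def test_coefficients_bounded(self):
        g = build_attention_gate(4, 6, 3, seed=3)
        coeff = g.coefficients(self.skip, self.gate_in)
        assert coeff.data.min() >= 0.0 and coeff.data.max() <= 1.0

    def test_unresamplable_spatial_mismatch_rejected(self):
        g = build_attention_gate(4, 6, 3, seed=4)
        bad_gate = Tensor(np.zeros((2, 6, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="spatial"):
            g(self.skip, bad_gate)


class TestDecoderTopology:
    def test_dense_links_grid_columns(self):
        cfg = tiny_model_config()
        assert grid_columns(cfg, 1) == [1, 2, 3, 4]
        assert grid_columns(cfg, 4) == [1]

    def test_ablated_topology_is_single_column(self):
        cfg = tiny_model_config()
        cfg.use_dense_decoder_links = False
        assert grid_columns(cfg, 1) == [4]
        assert grid_columns(cfg, 3) == [2]

    def test_nonexistent_node_rejected(self):
        cfg = tiny_model_config()
        with pytest.raises(ValueError, match="not in the topology"):
            node_channels(cfg, 1, 5)
        with pytest.raises(ValueError, match="level"):
            node_channels(cfg, 5, 1)

    def test_zeroed_convs_give_projected_shortcut(self):
        cfg = tiny_model_config()
        cfg.use_attention = False
        node = build_decoder_node(4, 1, cfg, seed=0)
        for conv in (node.conv1, node.conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        skip_ch, deeper_ch, out_ch = node_channels(cfg, 4, 1)
        rng = np.random.default_rng(0)
        skips = [Tensor(rng.standard_normal((1, skip_ch, 4, 4)).astype(np.float32))]
        deeper = Tensor(rng.standard_normal((1, deeper_ch, 2, 2)).astype(np.float32))
        node.eval()
        with nn.no_grad():
            out = node(skips, deeper)
            x = F.concat([skips[0], node.up(deeper)], axis=1)
            expected = node.shortcut(x)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-6)

    def test_node_output_spatial_matches_level(self):
        cfg = tiny_model_config()
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(1).random((1, 3, 32, 32), dtype=np.float32)
        model.eval()
        with nn.no_grad():
            y = model(x)
        assert y.shape == (1, 1, 32, 32)


class TestFullModel:
    def test_reduced_forward_contract(self):
        cfg = reduced_model_config()
        model = build_model(cfg, seed=0)
        x = np.random.default_rng(0).standard_normal((1, 3, 96, 96)).astype(np.float32)
        model.eval()
        with nn.no_grad():
            y = model(100.0 * x)  # arbitrary large-magnitude inputs
        assert y.shape == (1, 1, 96, 96)
        assert y.data.min() >= 0.0 and y.data.max() <= 1.0

    def test_invalid_input_shape_rejected(self):
        model = build_model(tiny_model_config(), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model(np.zeros((1, 4, 32, 32), dtype=np.float32))

    def test_invalid_config_names_violated_invariant(self):
        with pytest.raises(ValueError, match="growth_rate_k"):
            build_model(ModelConfig(growth_rate_k=0))

    def test_ablations_shrink_parameters_keep_shape(self):
        cfg = tiny_model_config()
        full = build_model(cfg, seed=0)
        n_full = count_parameters(full)
        x = np.random.default_rng(0).random((1, 3, 32, 32), dtype=np.float32)
        from adenseunet import ablate

        for flag in ("no_attention", "no_dilation", "no_dense_links"):
            variant = build_model(ablate(cfg, [flag]), seed=0)
            assert count_parameters(variant) < n_full
            variant.eval()
            with nn.no_grad():
                assert variant(x).shape == (1, 1, 32, 32)


class TestCountParameters:
    def test_single_pointwise_conv_hand_count(self):
        conv = nn.Conv2d(3, 1, 1, np.random.default_rng(0))
        assert conv.num_parameters() == 4

    def test_two_layer_toy_hand_count(self):
        rng = np.random.default_rng(0)
        seq = nn.Sequential(nn.Conv2d(2, 3, 3, rng), nn.BatchNorm2d(3),
                            nn.Conv2d(3, 1, 1, rng))
        # 3*2*9+3 kernel+bias, 3+3 BN affine, 1*3+1 head
        assert seq.num_parameters() == (54 + 3) + 6 + 4

    def test_monotone_in_growth_rate(self):
        counts = []
        for k in (2, 4, 6):
            cfg = tiny_model_config()
            cfg.growth_rate_k = k
            counts.append(count_parameters(build_model(cfg, seed=0)))
        assert counts[0] < counts[1] < counts[2]
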