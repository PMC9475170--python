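"""Architecture contracts: pyramid, attention gate, SDC block,
receptive-field arithmetic, model assembly and parameter accounting."""

import numpy as np
import pytest

from nnetseg.arch import (
    ArchitectureConfig,
    AttentionGate,
    LayerSpec,
    SDCBlock,
    ablation_configs,
    build_model,
    count_parameters,
    impulse_footprint,
    multi_scale_pyramid,
    receptive_field,
    sdc_branch_specs,
)
from nnetseg.nn import Conv2d
from nnetseg.nn.tensor import Tensor


class TestPyramid:
    def test_level_sizes_halve(self, rng):
        img = rng.random((1, 1, 512, 512))
        levels = multi_scale_pyramid(img, 4)
        assert [lv.shape[-1] for lv in levels] == [512, 256, 128, 64]
        assert levels[0] is img  # level 1 is the input unchanged

    def test_constant_image_stays_constant(self):
        levels = multi_scale_pyramid(np.full((8, 8), 0.37), 3)
        for lv in levels:
            np.testing.assert_allclose(lv, 0.37)

    def test_checkerboard_averages_to_half(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        levels = multi_scale_pyramid(board.astype(float), 2)
        np.testing.assert_allclose(levels[1], 0.5)

    def test_global_mean_preserved_each_level(self, rng):
        img = rng.random((16, 16))
        for lv in multi_scale_pyramid(img, 3):
            np.testing.assert_allclose(lv.mean(), img.mean(), rtol=1e-12)

    def test_nondivisible_dimension_names_axis(self):
        with pytest.raises(ValueError, match="height 6"):
            multi_scale_pyramid(np.zeros((6, 8)), 3)
        with pytest.raises(ValueError, match="width 10 .*axis -1"):
            multi_scale_pyramid(np.zeros((8, 10)), 3)


class TestAttentionGate:
    def test_output_shape_matches_features(self, rng):
        gate = AttentionGate(6, np.random.default_rng(0))
        img = rng.random((2, 1, 8, 8)).astype(np.float32)
        f = rng.random((2, 6, 8, 8)).astype(np.float32)
        assert gate(Tensor(img), Tensor(f)).shape == f.shape

    def test_zero_weights_gate_at_half(self, rng):
        gate = AttentionGate(4, np.random.default_rng(0))
        for p in gate.parameters():
            p.data[...] = 0.0
        f = rng.random((1, 4, 6, 6)).astype(np.float32)
        out = gate(Tensor(np.zeros((1, 1, 6, 6), np.float32)), Tensor(f))
        np.testing.assert_allclose(out.data, 0.5 * f, rtol=1e-6)

    def test_gating_values_strictly_inside_unit_interval(self, rng):
        gate = AttentionGate(5, np.random.default_rng(3))
        g = gate.gating_map(Tensor(rng.random((2, 1, 8, 8)).astype(np.float32)),
                            Tensor(rng.standard_normal((2, 5, 8, 8)).astype(np.float32)))
        assert g.shape == (2, 1, 8, 8)
        assert (g > 0).all() and (g < 1).all()

    def test_spatial_mismatch_raises(self, rng):
        gate = AttentionGate(4, np.random.default_rng(0))
        with pytest.raises(ValueError, match="spatial mismatch"):
            gate(Tensor(np.zeros((1, 1, 4, 4), np.float32)),
                 Tensor(np.zeros((1, 4, 8, 8), np.float32)))


class TestSDCBlock:
    @pytest.mark.parametrize("shape", [(1, 4, 8, 8), (2, 4, 16, 12), (1, 4, 6, 6)])
    def test_output_shape_equals_input_shape(self, shape, rng):
        block = SDCBlock(4, ((1,), (3,), (1, 3), (1, 3, 11)),
                         np.random.default_rng(0))
        x = rng.standard_normal(shape).astype(np.float32)
        assert block(Tensor(x)).shape == shape

    def test_shape_preserved_on_many_random_shapes(self, rng):
        block = SDCBlock(3, ((1,), (3,), (1, 3), (1, 3, 11)),
                         np.random.default_rng(1))
        for _ in range(50):
            h, w = rng.integers(4, 24, 2)
            x = rng.standard_normal((1, 3, int(h), int(w))).astype(np.float32)
            assert block(Tensor(x)).shape == x.shape

    def test_zero_input_zero_biases_gives_zero_output(self):
        block = SDCBlock(2, ((1,), (1, 3)), np.random.default_rng(0))
        # conv biases are zero-initialised; zero input stays zero through
        # every branch and the identity skip
        out = block(Tensor(np.zeros((1, 2, 8, 8), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_identity_branch_passes_input_through(self, rng):
        """Zero 3x3 weights + identity 1x1 fusion reduce the block to
        input + relu(input) on a non-negative input, traced by hand."""
        block = SDCBlock(2, ((1,),), np.random.default_rng(0))
        conv3, _, conv1, _ = block.branches[0].layers
        conv3.weight.data[...] = 0.0
        conv1.weight.data[...] = np.eye(2)[:, :, None, None]
        conv1.bias.data[...] = 0.0
        x = rng.random((1, 2, 5, 5)).astype(np.float32)  # non-negative
        out = block(Tensor(x))
        # branch: relu(conv3x3=0) = 0 -> 1x1 identity -> relu(0) = 0
        np.testing.assert_allclose(out.data, x, rtol=1e-6)

    def test_empty_branch_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            SDCBlock(2, ((1,), ()), np.random.default_rng(0))


class TestReceptiveField:
    @pytest.mark.parametrize("rates,expected", [
        ((1,), 3), ((3,), 7), ((1, 3), 9), ((1, 3, 11), 31),
    ])
    def test_default_branches_printed_values(self, rates, expected):
        stack = [LayerSpec(3, d) for d in rates]
        assert receptive_field(stack) == expected

    def test_one_by_one_conv_sees_one_pixel(self):
        assert receptive_field([LayerSpec(1, 1)]) == 1

    @pytest.mark.parametrize("rates", [(1,), (3,), (1, 3), (1, 3, 11), (2, 5), (1, 1, 1)])
    def test_formula_matches_impulse_response_oracle(self, rates):
        """Brute-force: propagate a unit impulse through all-ones kernels
        and measure the nonzero footprint."""
        stack = [LayerSpec(3, d) for d in rates]
        assert impulse_footprint(stack) == receptive_field(stack)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="at least one layer"):
            receptive_field([])

    def test_default_branch_specs_cover_four_branches(self):
        assert [receptive_field(s) for s in sdc_branch_specs()] == [3, 7, 9, 31]


class TestBuildModel:
    def test_forward_maps_image_to_probabilities(self, tiny_model, rng):
        x = rng.random((1, 1, 64, 64), dtype=np.float32)
        out = tiny_model.predict(x)
        assert out.shape == (1, 1, 64, 64)
        assert (out > 0).all() and (out < 1).all()

    def test_output_spatial_dims_follow_input(self, tiny_model, rng):
        out = tiny_model.predict(rng.random((1, 1, 32, 32), dtype=np.float32))
        assert out.shape == (1, 1, 32, 32)

    @pytest.mark.parametrize("flags", [
        (False, False, False), (False, True, False),
        (True, True, False), (True, True, True),
    ])
    def test_ablation_rows_all_buildable(self, flags, rng):
        ms, ag, sdc = flags
        cfg = ArchitectureConfig(depth=2, base_channels=4, input_size=16,
                                 use_multiscale=ms, use_attention=ag, use_sdc=sdc)
        model = build_model(cfg, seed=0)
        out = model.predict(rng.random((1, 1, 16, 16), dtype=np.float32))
        assert out.shape == (1, 1, 16, 16)

    def test_ablation_parameter_counts_strictly_increase(self):
        counts = [count_parameters(build_model(cfg))
                  for _, cfg in ablation_configs(depth=3, base_channels=8,
                                                 input_size=64)]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_invalid_config_rejected_before_weight_allocation(self):
        with pytest.raises(ValueError, match="not divisible"):
            ArchitectureConfig(depth=4, input_size=100)
        with pytest.raises(ValueError, match="depth"):
            ArchitectureConfig(depth=1)

    def test_seeded_builds_are_identical(self, tiny_config):
        a = build_model(tiny_config, seed=5).state_dict()
        b = build_model(tiny_config, seed=5).state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])


class TestParameterCounting:
    @pytest.mark.parametrize("dilation", [1, 3, 11])
    def test_dilation_does_not_change_parameter_count(self, dilation):
        conv = Conv2d(8, 8, 3, dilation=dilation, rng=np.random.default_rng(0))
        assert count_parameters(conv) == 9 * 8 * 8 + 8  # == 584

    def test_pointwise_conv_no_bias_is_c_squared(self):
        conv = Conv2d(6, 6, 1, bias=False, rng=np.random.default_rng(0))
        assert count_parameters(conv) == 36

    def test_sdc_adds_exactly_its_branch_parameters(self):
        common = dict(depth=3, base_channels=8, input_size=64,
                      use_multiscale=True, use_attention=True)
        plain = build_model(ArchitectureConfig(use_sdc=False, **common))
        full = build_model(ArchitectureConfig(use_sdc=True, **common))
        assert (count_parameters(full) - count_parameters(plain)
                == count_parameters(full.sdc))
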