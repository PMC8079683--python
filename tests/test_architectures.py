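import numpy as np
import pytest

from radcal import nn
from radcal.architectures import (
    ArchitectureSpec, CONVNET_WIDTHS, DenseBlockSpec, LayerSpec,
    ResidualBlockSpec, TransitionSpec, build_model, convnet_spec,
    count_parameters, densenet_spec, feature_map_side, iter_param_layers,
    resnet_spec, tiny_convnet_spec,
)


def conv_widths(spec):
    return [e[2] for e in iter_param_layers(spec) if e[0] == "conv"]


class TestConvnetSpec:
    def test_14_conv_layers(self):
        assert convnet_spec().conv_layer_count() == 14

    def test_width_schedule(self):
        assert conv_widths(convnet_spec()) == list(CONVNET_WIDTHS)
        assert conv_widths(convnet_spec())[12] == 1024  # 13th conv layer

    def test_seven_pools_and_fc_head(self):
        kinds = [l.kind for l in convnet_spec().layers if isinstance(l, LayerSpec)]
        assert kinds.count("maxpool2x2") == 7
        assert kinds.count("batch_norm") == 14
        fc = [l.width for l in convnet_spec().layers
              if isinstance(l, LayerSpec) and l.kind == "fully_connected"]
        assert fc == [512, 256]

    def test_flatten_side_is_2(self):
        assert feature_map_side(convnet_spec()) == 2  # 256 / 2**7


class TestResnetSpec:
    def test_default_25_blocks(self):
        blocks = [l for l in resnet_spec().layers if isinstance(l, ResidualBlockSpec)]
        assert len(blocks) == 25
        assert all(b.pre_activation for b in blocks)
        assert {b.block_type for b in blocks} == {"identity_skip", "projection_skip"}

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            resnet_spec(0)

    def test_identity_block_preserves_shape(self, rng):
        blk = nn.PreActIdentityBlock(4, np.random.default_rng(0))
        x = rng.random((2, 4, 8, 8))
        assert blk.forward(x, training=True).shape == x.shape

    def test_zero_residual_branch_is_identity(self, rng):
        # M(x) = F(x) + x: forcing F to zero must leave x untouched
        blk = nn.PreActIdentityBlock(3, np.random.default_rng(1))
        last_conv = blk.branch.layers[-1]
        last_conv.w.value[:] = 0.0
        last_conv.b.value[:] = 0.0
        x = rng.random((2, 3, 6, 6))
        np.testing.assert_allclose(blk.forward(x, training=True), x)


class TestDensenetSpec:
    def test_169_weighted_layers(self):
        assert densenet_spec().weighted_layer_count() == 169

    def test_first_conv_single_channel(self):
        first = next(e for e in iter_param_layers(densenet_spec()) if e[0] == "conv")
        assert first[1] == 1  # grayscale in

    def test_dense_connectivity_channel_arithmetic(self):
        blk = nn.DenseBlock(8, n_units=4, growth=3, rng=np.random.default_rng(0))
        assert [u.c_in for u in blk.units] == [8, 11, 14, 17]
        assert blk.c_out == 8 + 4 * 3

    def test_block_concatenates_all_predecessors(self, rng):
        blk = nn.DenseBlock(2, n_units=2, growth=3, rng=np.random.default_rng(0))
        x = rng.random((1, 2, 4, 4))
        out = blk.forward(x, training=True)
        assert out.shape[1] == 2 + 2 * 3
        np.testing.assert_array_equal(out[:, :2], x)  # input carried through


class TestCountParameters:
    def test_single_conv(self):
        spec = ArchitectureSpec("one", (LayerSpec("conv3x3", 16),), (8, 8, 1))
        assert count_parameters(spec, include=("conv",)) == 9 * 1 * 16 + 16

    def test_empty_spec(self):
        assert count_parameters(ArchitectureSpec("none", (), (8, 8, 1))) == 0

    def test_convnet_conv_stack(self):
        # brute-force oracle over the printed width schedule
        widths = list(CONVNET_WIDTHS)
        expected = sum(9 * cin * cout + cout
                       for cin, cout in zip([1] + widths[:-1], widths))
        assert expected == 18_876_272
        assert count_parameters(convnet_spec(), include=("conv",)) == expected

    def test_matches_built_model_enumeration(self):
        spec = tiny_convnet_spec(widths=(4, 8), input_shape=(16, 16, 1))
        model = build_model(spec, seed=0)
        convs = [l for l in model.layers if isinstance(l, nn.Conv2D)]
        enumerated = sum(l.w.value.size + l.b.value.size for l in convs)
        assert count_parameters(spec, include=("conv",)) == enumerated


class TestBuildModel:
    def test_probabilities_in_unit_interval(self, rng):
        m = build_model(tiny_convnet_spec(), seed=0)
        p = m.forward(rng.random((5, 32, 32)))
        assert p.shape == (5,)
        assert np.all((p >= 0) & (p <= 1))

    def test_seeded_builds_identical(self, rng):
        x = rng.random((3, 32, 32))
        a = build_model(tiny_convnet_spec(), seed=9).forward(x)
        b = build_model(tiny_convnet_spec(), seed=9).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_convnet_tap_spatial_size(self):
        m = build_model(convnet_spec(), seed=0)
        feats = m.feature_tap(np.random.default_rng(0).random((1, 256, 256)))
        assert feats.shape[2:] == (2, 2)
        assert feats.shape[1] == 1024

    def test_pooling_exhaustion_rejected(self):
        spec = tiny_convnet_spec(widths=(2, 2, 2, 2), input_shape=(8, 8, 1))
        with pytest.raises(ValueError):
            build_model(spec, seed=0)

    def test_pooling_arithmetic_property(self):
        for p in range(1, 8):
            spec = tiny_convnet_spec(widths=(2,) * p, input_shape=(256, 256, 1))
            assert feature_map_side(spec) == 256 // 2 ** p

    def test_resnet_forward_and_gap_head(self, rng):
        m = build_model(resnet_spec(n_blocks=5, input_shape=(32, 32, 1)), seed=0)
        p = m.forward(rng.random((2, 32, 32)), training=True)
        assert np.all((p >= 0) & (p <= 1))
        assert m.head_weights() is not None

    def test_densenet_small_build_forward(self, rng):
        spec = ArchitectureSpec("mini-dense", (
            LayerSpec("conv7x7", 8, stride=(2, 2)),
            LayerSpec("batch_norm"), LayerSpec("activation"), LayerSpec("maxpool2x2"),
            DenseBlockSpec(2, 4), TransitionSpec(),
            DenseBlockSpec(2, 4),
            LayerSpec("batch_norm"), LayerSpec("activation"),
            LayerSpec("global_avg_pool")), (32, 32, 1))
        m = build_model(spec, seed=0)
        p = m.forward(rng.random((2, 32, 32)), training=True)
        assert np.all((p >= 0) & (p <= 1))
        assert m.parameter_count == count_parameters(
            spec, include=("conv", "bn", "dense"), include_head=True)
        # closed-form vs enumeration, conv stack only
        convs = sum(l.w.value.size + l.b.value.size
                    for l in _all_convs(m.layers))
        assert convs == count_parameters(spec, include=("conv",))

    def test_spec_serialization_round_trip(self, tmp_path):
        for spec in (convnet_spec(), resnet_spec(), densenet_spec()):
            p = tmp_path / f"{spec.name}.json"
            spec.save(p)
            again = ArchitectureSpec.load(p)
            assert again == spec


def _all_convs(layers):
    out = []
    for l in layers:
        if isinstance(l, nn.Conv2D):
            out.append(l)
        for attr in ("layers", "units"):
            out.extend(_all_convs(getattr(l, attr, [])))
        for attr in ("branch", "pre", "proj", "chain"):
            sub = getattr(l, attr, None)
            if sub is not None:
                out.extend(_all_convs([sub]))
    return out


class TestGradients:
    def test_finite_difference_check(self):
        spec = ArchitectureSpec("mix", (
            LayerSpec("conv3x3", 4), LayerSpec("batch_norm"), LayerSpec("activation"),
            ResidualBlockSpec("projection_skip", 6, stride=2),
            ResidualBlockSpec("identity_skip", 6),
            DenseBlockSpec(2, 3), TransitionSpec(),
            LayerSpec("batch_norm"), LayerSpec("activation"),
            LayerSpec("global_avg_pool")), (8, 8, 1))
        m = build_model(spec, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((3, 8, 8))
        y = np.array([1.0, 0.0, 1.0])

        def loss():
            p = np.clip(m.forward(x, training=True), 1e-7, 1 - 1e-7)
            return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

        p = np.clip(m.forward(x, training=True), 1e-7, 1 - 1e-7)
        for par in m.parameters():
            par.zero_grad()
        m.backward((-(y / p) + (1 - y) / (1 - p)) / 3)
        for par in m.parameters()[::7]:
            flat = par.value.ravel()
            idx = flat.size // 2
            eps, old = 1e-5, flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = par.grad.ravel()[idx]
            assert abs(num - ana) <= 1e-6 + 1e-4 * (abs(num) + abs(ana))
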