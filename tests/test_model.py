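"""Generator/discriminator architecture and fusion-module algebra."""

import numpy as np
import pytest

from pggan.model import (
    FUSION_MODES,
    Discriminator,
    FeatureModulation,
    Generator,
    GeneratorSpec,
    ffm_modulate,
    mffm_modulate,
)
from pggan.nn import Tensor


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float64))


class TestFfmAlgebra:
    def test_identity_modulation(self):
        fin = t(np.random.default_rng(0).normal(size=(1, 2, 3, 3, 3)))
        mod = FeatureModulation(scale=t(np.ones_like(fin.data)),
                                shift=t(np.zeros_like(fin.data)))
        assert np.array_equal(ffm_modulate(fin, mod).data, fin.data)

    def test_zero_scale_gives_shift(self):
        fin = t(np.random.default_rng(1).normal(size=(1, 2, 2, 2, 2)))
        shift = np.full_like(fin.data, 0.7)
        mod = FeatureModulation(scale=t(np.zeros_like(fin.data)), shift=t(shift))
        assert np.array_equal(ffm_modulate(fin, mod).data, shift)

    def test_hand_computed_example(self):
        # two channels of a 2x1x1 block: [1,2] and [3,4]
        fin = t(np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 2, 2, 1, 1))
        scale = t(np.array([2.0, 2.0, 0.5, 0.5]).reshape(1, 2, 2, 1, 1))
        shift = t(np.array([1.0, 1.0, -1.0, -1.0]).reshape(1, 2, 2, 1, 1))
        out = ffm_modulate(fin, FeatureModulation(scale=scale, shift=shift))
        expected = np.array([3.0, 5.0, 0.5, 1.0]).reshape(1, 2, 2, 1, 1)
        assert np.array_equal(out.data, expected)

    def test_linearity_at_zero_shift(self):
        rng = np.random.default_rng(2)
        f1, f2 = rng.normal(size=(2, 1, 2, 2, 2, 2))
        scale = rng.normal(size=(1, 2, 2, 2, 2))
        mod = FeatureModulation(scale=t(scale), shift=t(np.zeros_like(scale)))
        a, b = 1.7, -0.3
        combined = ffm_modulate(t(a * f1 + b * f2), mod).data
        separate = a * ffm_modulate(t(f1), mod).data + b * ffm_modulate(t(f2), mod).data
        assert np.allclose(combined, separate, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        fin = t(np.zeros((1, 2, 2, 2, 2)))
        bad = t(np.zeros((1, 2, 3, 3, 3)))
        with pytest.raises(ValueError):
            ffm_modulate(fin, FeatureModulation(scale=bad, shift=bad))


class TestMffmAlgebra:
    def test_zero_attribute_branch_reduces_to_ffm(self):
        rng = np.random.default_rng(3)
        fin = t(rng.normal(size=(2, 3, 2, 2, 2)))
        scale = t(rng.normal(size=(2, 3, 2, 2, 2)))
        shift = t(rng.normal(size=(2, 3, 2, 2, 2)))
        map_mod = FeatureModulation(scale=scale, shift=shift, source="map")
        attr_mod = FeatureModulation(
            scale=t(np.zeros((2, 3))), shift=t(np.zeros((2, 3))), source="attribute"
        )
        ffm_out = ffm_modulate(fin, map_mod).data
        mffm_out = mffm_modulate(fin, map_mod, attr_mod).data
        assert np.array_equal(ffm_out, mffm_out)

    def test_zero_map_identity_attributes(self):
        fin = t(np.random.default_rng(4).normal(size=(1, 2, 2, 2, 2)))
        zero = t(np.zeros_like(fin.data))
        map_mod = FeatureModulation(scale=zero, shift=zero, source="map")
        attr_mod = FeatureModulation(
            scale=t(np.ones((1, 2))), shift=t(np.zeros((1, 2))), source="attribute"
        )
        assert np.array_equal(mffm_modulate(fin, map_mod, attr_mod).data, fin.data)

    def test_additive_parameters(self):
        # scales 1+1, shifts 0.5+0.5 on unit features: 2*1 + 1 = 3
        fin = t(np.ones((1, 1, 2, 2, 2)))
        ones, halves = t(np.ones_like(fin.data)), t(np.full_like(fin.data, 0.5))
        map_mod = FeatureModulation(scale=ones, shift=halves, source="map")
        attr_mod = FeatureModulation(
            scale=t(np.ones((1, 1))), shift=t(np.full((1, 1), 0.5)), source="attribute"
        )
        assert np.allclose(mffm_modulate(fin, map_mod, attr_mod).data, 3.0)


class TestChannelSchedule:
    def test_full_scale_encoder_decoder_pairs(self):
        spec = GeneratorSpec(fusion_mode="ffm", base_channels=64)
        assert spec.encoder_channels == [(1, 64), (64, 128), (128, 256), (256, 512)]
        assert spec.decoder_channels == [(512, 512), (512, 256), (256, 128), (128, 64)]
        concat_spec = GeneratorSpec(fusion_mode="image_concat", base_channels=64)
        assert concat_spec.encoder_channels[0] == (2, 64)
        assert concat_spec.input_channels == 2

    def test_map_conv_spec(self):
        spec = GeneratorSpec(fusion_mode="ffm", base_channels=64)
        assert spec.map_conv == (1, 128, 4, 2)

    def test_instantiated_layers_match_schedule(self):
        spec = GeneratorSpec(fusion_mode="ffm", base_channels=64)
        gen = Generator(spec, np.random.default_rng(0))
        enc = [(c.in_ch, c.out_ch) for c in gen.enc_convs]
        assert enc == [(1, 64), (64, 128), (128, 256), (256, 512)]
        # deconvs emit half of each block-level output; the skip concat
        # restores the printed pair
        dec = [(c.in_ch, c.out_ch) for c in gen.dec_convs]
        assert dec == [(512, 256), (512, 128), (256, 64), (128, 64)]
        assert (gen.head.in_ch, gen.head.out_ch) == (64, 1)
        assert gen.map_conv.out_ch == 128

    def test_discriminator_schedule(self):
        disc = Discriminator((32, 32, 32), np.random.default_rng(0), base_channels=32)
        assert disc.channel_pairs == [(1, 32), (32, 64), (64, 128), (128, 256)]
        assert disc.flat_dim == 256 * 2 * 2 * 2  # 2048 after four halvings of 32
        assert disc.fc1.out_features == 1000
        assert disc.fc2.out_features == 1


class TestMapToModulation:
    def test_spatial_dims_halve(self):
        spec = GeneratorSpec(fusion_mode="ffm", base_channels=8)
        gen = Generator(spec, np.random.default_rng(0))
        mod = gen.map_to_modulation(t(np.zeros((1, 1, 32, 32, 32))))
        assert mod.scale.shape == (1, 8, 16, 16, 16)
        assert mod.shift.shape == (1, 8, 16, 16, 16)

    def test_odd_grid_halves_with_ceil(self):
        spec = GeneratorSpec(fusion_mode="ffm", base_channels=2)
        gen = Generator(spec, np.random.default_rng(0))
        mod = gen.map_to_modulation(t(np.zeros((1, 1, 90, 98, 90))))
        assert mod.scale.shape[2:] == (45, 49, 45)

    def test_zero_map_zero_modulation(self):
        spec = GeneratorSpec(fusion_mode="ffm", base_channels=4)
        gen = Generator(spec, np.random.default_rng(0))
        mod = gen.map_to_modulation(t(np.zeros((1, 1, 16, 16, 16))))
        assert np.all(mod.scale.data == 0.0) and np.all(mod.shift.data == 0.0)


class TestGeneratorForward:
    @pytest.mark.parametrize("mode", FUSION_MODES)
    def test_output_shape_equals_input_shape(self, mode):
        spec = GeneratorSpec(fusion_mode=mode, base_channels=4)
        gen = Generator(spec, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
        m = (
            Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
            if spec.needs_map
            else None
        )
        a = Tensor(np.array([[0.3, 1.0]], dtype=np.float32)) if spec.needs_attrs else None
        out = gen(x, m, a)
        assert out.shape == x.shape
        assert np.all(np.abs(out.data) <= 1.0)  # tanh head

    def test_odd_spatial_sizes_supported(self):
        gen = Generator(GeneratorSpec(base_channels=2), np.random.default_rng(0))
        x = Tensor(np.zeros((1, 1, 48, 40, 32), dtype=np.float32))
        assert gen(x).shape == (1, 1, 48, 40, 32)

    def test_zeroed_map_conv_zeroes_stage_one(self):
        """With a zero map the first fused block is exactly zero, and the
        network output equals a hand-traced forward pass that replaces the
        stage-1 features by zeros."""
        from pggan.nn import concat

        spec = GeneratorSpec(fusion_mode="ffm", base_channels=2)
        gen = Generator(spec, np.random.default_rng(3))
        gen.eval()
        rng = np.random.default_rng(4)
        x = Tensor(rng.normal(size=(1, 1, 16, 16, 16)).astype(np.float32))
        m = Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        out = gen(x, m).data

        # manual trace with stage-1 block forced to zero
        h = gen.enc_bns[0](gen.enc_convs[0](x).leaky_relu(0.2))
        s1 = Tensor(np.zeros_like(h.data))
        skips = [s1]
        h = s1
        for conv, bn in zip(gen.enc_convs[1:], gen.enc_bns[1:]):
            h = bn(conv(h).leaky_relu(0.2))
            skips.append(h)
        h = skips[-1]
        for i, (deconv, bn) in enumerate(zip(gen.dec_convs, gen.dec_bns)):
            h = bn(deconv(h)).leaky_relu(0.2)
            if i < 3:
                h = concat([h, skips[2 - i]], axis=1)
        expected = gen.head(h).tanh().data
        assert np.allclose(out, expected, atol=1e-6)

    def test_condition_mismatch_errors(self):
        rng = np.random.default_rng(0)
        x = Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        m = Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        gen_ffm = Generator(GeneratorSpec(fusion_mode="ffm", base_channels=2), rng)
        with pytest.raises(ValueError):
            gen_ffm(x)  # map required
        gen_none = Generator(GeneratorSpec(fusion_mode="none", base_channels=2), rng)
        with pytest.raises(ValueError):
            gen_none(x, m)  # no map expected
        with pytest.raises(ValueError):
            gen_none(Tensor(np.zeros((1, 1, 8, 8, 8), dtype=np.float32)))

    def test_mffm_with_zero_attr_branch_equals_ffm(self):
        """Zeroing the attribute head makes the multi-view fusion bit-equal
        to plain feature-wise fusion with shared backbone weights."""
        from pggan import nn

        rng_init = np.random.default_rng(7)
        mffm_gen = Generator(GeneratorSpec(fusion_mode="mffm", base_channels=2), rng_init)
        ffm_gen = Generator(GeneratorSpec(fusion_mode="ffm", base_channels=2),
                            np.random.default_rng(8))
        # share every common weight; zero the attribute branch
        state = nn.state_dict(mffm_gen)
        common = {k: v for k, v in state.items() if not k.startswith("attr_fc")}
        nn.load_state_dict(ffm_gen, common)
        mffm_gen.attr_fc2.weight.data[...] = 0.0
        mffm_gen.attr_fc2.bias.data[...] = 0.0
        mffm_gen.eval()
        ffm_gen.eval()
        rng = np.random.default_rng(9)
        x = Tensor(rng.normal(size=(1, 1, 16, 16, 16)).astype(np.float32))
        m = Tensor(rng.normal(size=(1, 1, 16, 16, 16)).astype(np.float32))
        a = Tensor(np.array([[0.4, 1.0]], dtype=np.float32))
        assert np.array_equal(mffm_gen(x, m, a).data, ffm_gen(x, m).data)


class TestDiscriminator:
    def test_output_is_probability(self):
        disc = Discriminator((16, 16, 16), np.random.default_rng(0), base_channels=2)
        rng = np.random.default_rng(1)
        p = disc(Tensor(rng.normal(size=(3, 1, 16, 16, 16)).astype(np.float32)))
        assert p.shape == (3, 1)
        assert np.all(p.data > 0) and np.all(p.data < 1)

    def test_zero_final_layer_gives_half(self):
        disc = Discriminator((16, 16, 16), np.random.default_rng(0), base_channels=2)
        disc.fc2.weight.data[...] = 0.0
        disc.fc2.bias.data[...] = 0.0
        p = disc(Tensor(np.random.default_rng(2).normal(
            size=(2, 1, 16, 16, 16)).astype(np.float32)))
        assert np.allclose(p.data, 0.5)

    def test_wrong_shape_rejected(self):
        disc = Discriminator((16, 16, 16), np.random.default_rng(0), base_channels=2)
        with pytest.raises(ValueError):
            disc(Tensor(np.zeros((1, 1, 32, 32, 32), dtype=np.float32)))


def test_invalid_fusion_mode_rejected():
    with pytest.raises(ValueError):
        GeneratorSpec(fusion_mode="bogus")
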