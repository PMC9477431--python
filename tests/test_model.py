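"""Network architecture contracts: shapes, attention algebra, patch weighting."""

import numpy as np
import pytest

import e2sgan.autodiff as ad
from e2sgan.autodiff import Tensor
from e2sgan.model import (
    CSA,
    Discriminator,
    Generator,
    ModelConfig,
    csa_attention,
    csa_forward,
    wpp_forward,
)
from e2sgan.nn import EqualizedConv2d, conv2d, pixel_norm


SMALL = ModelConfig(size=32, gen_base=8, disc_base=8)


class TestGenerator:
    def test_full_scale_geometry(self, rng):
        gen = Generator(ModelConfig(), seed=0)
        out = gen(rng.uniform(-1, 1, (1, 2, 128, 128)))
        assert out.shape == (1, 2, 128, 128)
        assert gen.last_padded_side == 134
        assert np.abs(out.data).max() <= 1.0

    def test_reduced_scale_geometry(self, rng):
        gen = Generator(SMALL, seed=0)
        out = gen(rng.uniform(-1, 1, (2, 2, 32, 32)))
        assert out.shape == (2, 2, 32, 32)
        assert gen.last_padded_side == 38

    def test_wrong_shape_rejected(self, rng):
        gen = Generator(SMALL, seed=0)
        with pytest.raises(ValueError, match="expected input"):
            gen(rng.uniform(-1, 1, (1, 3, 32, 32)))

    def test_untrained_map_is_not_constant(self, rng):
        gen = Generator(SMALL, seed=0)
        a = gen(rng.uniform(-1, 1, (1, 2, 32, 32))).data
        b = gen(rng.uniform(-1, 1, (1, 2, 32, 32))).data
        assert not np.allclose(a, b)

    def test_zero_input_gives_finite_bounded_output(self):
        gen = Generator(SMALL, seed=0)
        out = gen(np.zeros((1, 2, 32, 32))).data
        assert np.isfinite(out).all()
        assert np.abs(out).max() <= 1.0

    def test_parameter_count_matches_hand_count(self):
        # layer-by-layer count for the published full-scale layout:
        # conv(2->32,4x4), conv(32->64,4x4), 2 res blocks of two 3x3
        # same-convs at 64, conv(64->32,3x3), conv(32->16,3x3), head
        # conv(16->2,7x7); all with biases
        def cnt(cin, cout, k):
            return cout * (cin * k * k) + cout

        expected = (cnt(2, 32, 4) + cnt(32, 64, 4)
                    + 4 * cnt(64, 64, 3)
                    + cnt(64, 32, 3) + cnt(32, 16, 3)
                    + cnt(16, 2, 7))
        gen = Generator(ModelConfig(), seed=0)
        assert gen.n_parameters() == expected


class TestCSA:
    def test_attention_rows_sum_to_one(self, rng):
        csa = CSA(32, seed=0)
        alpha = csa_attention(rng.uniform(-1, 1, (32, 32)),
                              rng.uniform(-1, 1, (32, 32)), csa)
        assert alpha.shape == (32, 32)
        assert np.allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_parameters_give_uniform_attention(self, rng):
        csa = CSA(16, seed=0)
        for p in (csa.w1, csa.b1, csa.w2, csa.b2):
            p.data = np.zeros_like(p.data)
        e = rng.uniform(-1, 1, (16, 16))
        alpha = csa_attention(e, rng.uniform(-1, 1, (16, 16)), csa)
        assert np.allclose(alpha, 1.0 / 16, atol=1e-12)
        # uniform attention averages the scalp magnitude over frequency rows
        out = csa_forward(e, rng.uniform(-1, 1, (16, 16)), csa)
        assert np.allclose(out, np.tile(e.mean(axis=0), (16, 1)), atol=1e-12)

    def test_output_concatenable_as_extra_channel(self, rng):
        csa = CSA(32, seed=0)
        out = csa_forward(rng.uniform(-1, 1, (32, 32)),
                          rng.uniform(-1, 1, (32, 32)), csa)
        assert out.shape == (32, 32)

    def test_shape_mismatch_rejected(self, rng):
        csa = CSA(32, seed=0)
        with pytest.raises(ValueError, match="share a shape"):
            csa_forward(rng.uniform(-1, 1, (32, 32)),
                        rng.uniform(-1, 1, (16, 16)), csa)


class TestWPP:
    def test_hand_computed_example(self):
        # k=2, patches (1,2,3,4), slope 0.2, unit weights:
        # p_global = LReLU(2.5) = 2.5; score = 2.5 + 1 + 2 + 3 + 4 = 12.5
        grid = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert wpp_forward(grid, np.ones(5), 0.2) == pytest.approx(12.5)

    def test_negative_mean_passes_through_leaky_slope(self):
        grid = -np.array([[1.0, 2.0], [3.0, 4.0]])
        # p_global = 0.2 * (-2.5) = -0.5; score = -0.5 - 10
        assert wpp_forward(grid, np.ones(5), 0.2) == pytest.approx(-10.5)

    def test_zero_patches_give_zero(self, rng):
        assert wpp_forward(np.zeros((3, 3)), rng.uniform(-1, 1, 10)) == 0.0

    def test_one_hot_beta_selects_patch(self):
        grid = np.arange(9, dtype=float).reshape(3, 3)
        beta = np.zeros(10)
        beta[3] = 1.0  # first entry is the global term
        assert wpp_forward(grid, beta) == pytest.approx(grid.ravel()[2])

    def test_linear_in_patch_scores_for_fixed_beta(self, rng):
        beta = rng.uniform(-1, 1, 5)
        a = rng.uniform(-1, 1, (2, 2))
        b = rng.uniform(-1, 1, (2, 2))
        # linearity holds when the global mean stays on one side of zero
        a, b = np.abs(a), np.abs(b)
        assert wpp_forward(a + b, beta) == pytest.approx(
            wpp_forward(a, beta) + wpp_forward(b, beta), rel=1e-9)

    def test_non_square_grid_rejected(self):
        with pytest.raises(ValueError, match="square"):
            wpp_forward(np.zeros((2, 3)), np.ones(7))


class TestDiscriminator:
    def test_patch_grid_side_is_14_at_full_scale(self, rng):
        disc = Discriminator(ModelConfig(), seed=0)
        pair = Tensor(rng.uniform(-1, 1, (1, 4, 128, 128)))
        em = ad.reshape(ad.narrow(pair, 1, 0, 1), (1, 128, 128))
        sm = ad.reshape(ad.narrow(pair, 1, 2, 1), (1, 128, 128))
        csa_ch = ad.reshape(disc.csa(em, sm), (1, 1, 128, 128))
        grid = disc.trunk(ad.concat([pair, csa_ch], axis=1))
        assert grid.shape == (1, 1, 14, 14)
        assert disc.wpp.beta.shape == (14 * 14 + 1,)

    def test_scalar_output_and_determinism(self, rng):
        disc = Discriminator(SMALL, seed=0)
        e = rng.uniform(-1, 1, (2, 2, 32, 32))
        s = rng.uniform(-1, 1, (2, 2, 32, 32))
        y1 = disc(e, s).data
        y2 = disc(e, s).data
        assert y1.shape == (2,)
        assert np.array_equal(y1, y2)

    def test_finite_scores_across_seeds(self):
        disc = Discriminator(SMALL, seed=3)
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = disc(r.uniform(-1, 1, (1, 2, 32, 32)),
                     r.uniform(-1, 1, (1, 2, 32, 32))).data
            assert np.isfinite(y).all()

    def test_csa_disabled_equals_zero_attention_channel(self, rng):
        disc = Discriminator(SMALL, seed=0)
        e = rng.uniform(-1, 1, (1, 2, 32, 32))
        s = rng.uniform(-1, 1, (1, 2, 32, 32))
        off = disc(e, s, use_csa=False).data
        on = disc(e, s, use_csa=True).data
        assert np.isfinite(off).all()
        assert not np.allclose(off, on)  # the attention channel matters

    def test_shape_mismatch_rejected(self, rng):
        disc = Discriminator(SMALL, seed=0)
        with pytest.raises(ValueError, match="share a shape"):
            disc(rng.uniform(-1, 1, (1, 2, 32, 32)),
                 rng.uniform(-1, 1, (2, 2, 32, 32)))


class TestLayers:
    def test_pixel_norm_of_ones_is_one(self):
        x = Tensor(np.ones((1, 1, 4, 4)))
        out = pixel_norm(x, eps=1e-8).data
        assert np.allclose(out, 1.0, atol=1e-4)

    def test_pixel_norm_unit_rms_at_every_position(self, rng):
        x = Tensor(rng.standard_normal((2, 8, 5, 5)))
        out = pixel_norm(x).data
        rms = np.sqrt((out ** 2).mean(axis=1))
        assert np.allclose(rms, 1.0, atol=1e-4)

    def test_equalized_conv_matches_plain_conv_scaled_by_he_constant(self, rng):
        conv = EqualizedConv2d(3, 4, 3, padding=1, rng=rng)
        x = Tensor(rng.standard_normal((1, 3, 6, 6)))
        out = conv(x).data
        plain = conv2d(x, conv.weight, conv.bias, stride=1, padding=1).data
        he = np.sqrt(2.0 / (3 * 9))
        bias = conv.bias.data.reshape(1, 4, 1, 1)
        assert np.allclose(out, (plain - bias) * he + bias, atol=1e-12)
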