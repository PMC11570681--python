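"""Generator/discriminator architecture contracts and the coil-wise recon path."""

import gc

import numpy as np
import pytest

from msrecon.errors import ConfigurationError, DimensionError
from msrecon.kspace import apply_mask, fft2c, make_cartesian_mask, zero_fill_recon
from msrecon.recon_net import (
    DiscriminatorConfig,
    ReconNetConfig,
    build_discriminator,
    build_generator,
    reconstruct_case,
)

SMALL = ReconNetConfig(stem_channels=4, encoder_base_channels=8, n_scales=2)


# ---------------------------------------------------------------------------
# Independent layer-arithmetic oracle for trainable parameter counts.
# A residual block is two (3x3 conv, BN, ReLU) units with an identity
# shortcut (1x1 projection when channel counts differ); upsampling is a
# 2x2 stride-2 transposed convolution.
# ---------------------------------------------------------------------------
def _resblock_count(cin: int, cout: int) -> int:
    n = cout * cin * 9 + cout  # conv1 weights + bias
    n += 2 * cout  # bn1 gamma/beta
    n += cout * cout * 9 + cout  # conv2
    n += 2 * cout  # bn2
    if cin != cout:
        n += cout * cin + cout  # 1x1 projection shortcut
    return n


def _generator_count(stem: int, base: int, ns: int, dual: bool) -> int:
    total = _resblock_count(2, stem) * (2 if dual else 1)
    for s in range(ns):
        cin = stem * (2 if dual else 1) if s == 0 else base * 2 ** (s - 1)
        total += _resblock_count(cin, base * 2**s)
    total += _resblock_count(base * 2 ** (ns - 1), base * 2**ns)  # bottleneck
    for s in range(ns - 1, -1, -1):
        ch = base * 2**s
        total += (ch * 2) * ch * 4 + ch  # transposed conv
        total += _resblock_count(ch * 2, ch)  # after skip concatenation
    total += 2 * base * 9 + 2  # output conv to (real, imag)
    return total


class TestGenerator:
    def test_shape_contract(self, rng):
        g = build_generator(SMALL, seed=0)
        x = rng.normal(size=(1, 2, 64, 64))
        ref = rng.normal(size=(1, 2, 64, 64))
        assert g(x, ref).shape == (1, 2, 64, 64)

    def test_zeroed_residual_branch_is_identity(self, rng):
        g = build_generator(SMALL, seed=0)
        g.zero_residual_branch()
        x = rng.normal(size=(2, 2, 32, 32))
        ref = rng.normal(size=(2, 2, 32, 32))
        assert np.array_equal(g(x, ref), x)

    def test_parameter_count_matches_layer_arithmetic(self):
        for cfg in (
            SMALL,
            ReconNetConfig(stem_channels=4, encoder_base_channels=8, n_scales=2,
                           use_reference_branch=False),
            ReconNetConfig(stem_channels=8, encoder_base_channels=16, n_scales=3),
        ):
            g = build_generator(cfg, seed=0)
            expected = _generator_count(
                cfg.stem_channels, cfg.encoder_base_channels, cfg.n_scales,
                cfg.use_reference_branch,
            )
            assert g.n_parameters() == expected

    def test_default_architecture_parameter_count(self):
        """Full-scale config: 32-channel stems, encoder 128..1024, 2048 bottleneck."""
        cfg = ReconNetConfig()
        expected = _generator_count(32, 128, 4, dual=True)
        g = build_generator(cfg, seed=0)
        assert g.n_parameters() == expected
        del g
        gc.collect()

    def test_single_input_mode_differs_only_in_stem(self):
        dual = build_generator(SMALL, seed=0)
        single = build_generator(
            ReconNetConfig(stem_channels=4, encoder_base_channels=8, n_scales=2,
                           use_reference_branch=False),
            seed=0,
        )
        # same body: parameter difference is exactly one stem block plus the
        # widened first encoder block's input channels
        stem = _resblock_count(2, 4)
        delta_enc = _resblock_count(8, 8) - _resblock_count(4, 8)
        assert dual.n_parameters() - single.n_parameters() == stem + delta_enc

    def test_indivisible_dims_rejected(self, rng):
        g = build_generator(SMALL, seed=0)
        with pytest.raises(DimensionError):
            g(rng.normal(size=(1, 2, 30, 30)), rng.normal(size=(1, 2, 30, 30)))

    def test_reference_contract_enforced(self, rng):
        x = rng.normal(size=(1, 2, 32, 32))
        dual = build_generator(SMALL, seed=0)
        with pytest.raises(ConfigurationError):
            dual(x)  # missing reference
        single = build_generator(
            ReconNetConfig(stem_channels=4, encoder_base_channels=8, n_scales=2,
                           use_reference_branch=False),
            seed=0,
        )
        with pytest.raises(ConfigurationError):
            single(x, x)  # unexpected reference


class TestDiscriminator:
    def test_deterministic_in_eval_mode(self, rng):
        d = build_discriminator(DiscriminatorConfig(n_layers=3, base_channels=8), seed=0)
        x = rng.normal(size=(1, 2, 64, 64))
        assert np.array_equal(d(x), d(x))

    def test_three_stride2_layers_give_8x8_map(self, rng):
        d = build_discriminator(DiscriminatorConfig(n_layers=3, base_channels=8), seed=0)
        scores = d(rng.normal(size=(1, 2, 64, 64)))
        assert scores.shape == (1, 1, 8, 8)
        assert np.isfinite(scores).all()

    def test_zero_weights_give_constant_bias_map(self, rng):
        d = build_discriminator(DiscriminatorConfig(n_layers=2, base_channels=4), seed=0)
        for p in d.parameters():
            p.data[...] = 0.0
        scores = d(rng.normal(size=(1, 2, 32, 32)))
        assert np.all(scores == 0.0)

    def test_input_below_receptive_field_rejected(self):
        d = build_discriminator(DiscriminatorConfig(n_layers=4, base_channels=4), seed=0)
        with pytest.raises(DimensionError):
            d(np.zeros((1, 2, 8, 8)))


class TestReconstructCase:
    def test_identity_generator_equals_zero_fill(self, small_dataset):
        case = small_dataset[1]
        g = build_generator(SMALL, seed=0)
        g.zero_residual_branch()
        k = fft2c(case.coil_images["T2_FLAIR"])
        mask = make_cartesian_mask(64, 4.0, 4, seed=0)
        km = apply_mask(k, mask)
        recon = reconstruct_case(g, km, case.coil_images["T2WI"])
        assert np.abs(recon - zero_fill_recon(km)).max() < 1e-6

    def test_single_coil_full_mask_identity_recovers_truth(self, tissue_map, contrast_model):
        from msrecon.phantom import render_contrast

        img = render_contrast(tissue_map, contrast_model, "T2_FLAIR", seed=0)
        ref = render_contrast(tissue_map, contrast_model, "T2WI", seed=1)
        g = build_generator(SMALL, seed=0)
        g.zero_residual_branch()
        k = fft2c(img[None])
        recon = reconstruct_case(g, k, ref[None])
        assert np.abs(recon - np.abs(img)).max() < 1e-6

    def test_coil_count_mismatch_rejected(self, small_dataset):
        case = small_dataset[0]
        g = build_generator(SMALL, seed=0)
        k = fft2c(case.coil_images["T2_FLAIR"])  # 2 coils
        with pytest.raises(DimensionError):
            reconstruct_case(g, k, case.coil_images["T2WI"][:1])

    def test_uncombined_output_keeps_coil_axis(self, small_dataset):
        case = small_dataset[0]
        g = build_generator(SMALL, seed=0)
        g.zero_residual_branch()
        k = fft2c(case.coil_images["T2_FLAIR"])
        out = reconstruct_case(g, k, case.coil_images["T2WI"], combine=False)
        assert out.shape == k.shape and np.iscomplexobj(out)
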