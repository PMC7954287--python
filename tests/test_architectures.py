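import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlseg.architectures import (ShapeError, build_network, count_parameters,
                                 output_shape, shape_trace)
from dlseg.config import ArchitectureSpec

from conftest import random_valid_spec


def s1_aniso(**over):
    kw = dict(family="unet3d_aniso", patch_size=(128, 128, 64, 2),
              n_classes=3, depth_levels=2, n_first_filters=32,
              padding="same")
    kw.update(over)
    return ArchitectureSpec(**kw)


class TestOutputShape:
    @pytest.mark.parametrize("size, depth, expect", [
        (572, 4, 388),   # classic overlap-tile geometry: 572 - (12*16-8)
        (100, 2, 60),    # 100 - 40
        (44, 2, 4),
        (20, 1, 4),
    ])
    def test_valid_2d_shrink(self, size, depth, expect):
        spec = ArchitectureSpec("unet2d", (size, size, 1, 1), 2,
                                depth_levels=depth, padding="valid")
        assert output_shape(spec) == (1, expect, expect)
        assert size - expect == 12 * 2 ** depth - 8

    def test_same_padding_identity(self):
        for fam, patch in [("unet2d", (64, 64, 1, 1)),
                           ("unet3d", (64, 64, 64, 1)),
                           ("unet3d_aniso", (64, 64, 32, 2)),
                           ("segnet2d", (64, 64, 1, 3))]:
            spec = ArchitectureSpec(fam, patch, 2, depth_levels=2)
            h, w, d, _ = patch
            assert output_shape(spec) == (d, h, w)

    def test_divisibility_error_names_junction(self):
        spec = ArchitectureSpec("unet2d", (64, 64, 1, 1), 2, depth_levels=2,
                                padding="valid")
        with pytest.raises(ShapeError, match="up2"):
            output_shape(spec, _validated=True)


class TestAnisotropic:
    def test_level1_pool_preserves_z(self):
        trace = {name: (sp, c) for name, sp, c in shape_trace(s1_aniso())}
        assert trace["enc1_pool"][0] == (64, 64, 64)   # z untouched, y/x halved
        assert trace["enc2_pool"][0] == (32, 32, 32)   # 3D level halves z too

    def test_isotropic_pool_halves_all_axes(self):
        iso = s1_aniso(family="unet3d")
        trace = {name: (sp, c) for name, sp, c in shape_trace(iso)}
        assert trace["enc1_pool"][0] == (32, 64, 64)

    def test_aniso_has_strictly_fewer_parameters(self):
        assert count_parameters(s1_aniso()) < count_parameters(
            s1_aniso(family="unet3d"))

    def test_z_halved_only_at_3d_level_in_trace(self):
        zs = [sp[0] for name, sp, c in shape_trace(s1_aniso())
              if name.startswith("enc")]
        # z stays 64 through the whole 2D level, drops to 32 only after the
        # 3D level-2 pool
        assert zs[:len(zs) - 1].count(64) >= 6 and zs[-1] == 32


class TestParameterCount:
    def test_single_conv_closed_form(self, rng):
        from dlseg import nn
        conv = nn.Conv("c", 1, 8, (1, 3, 3), "same", rng)
        assert sum(p.value.size for p in conv.params()) == 3 * 3 * 1 * 8 + 8

    @pytest.mark.parametrize("family", ["unet2d", "unet3d", "unet3d_aniso",
                                        "segnet2d"])
    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_count_matches_built_model(self, family, depth):
        if family == "unet3d_aniso" and depth == 1:
            pytest.skip("anisotropic variant requires depth >= 2")
        patch = {"unet2d": (32, 32, 1, 1), "segnet2d": (32, 32, 1, 1),
                 "unet3d": (16, 16, 8, 2), "unet3d_aniso": (16, 16, 8, 2)}[family]
        if family in ("unet3d", "unet3d_aniso") and depth == 3:
            patch = (32, 32, 16, 2)
        spec = ArchitectureSpec(family, patch, 3, depth_levels=depth,
                                n_first_filters=4)
        model = build_network(spec, seed=0)
        assert count_parameters(spec) == sum(p.value.size
                                             for p in model.parameters())

    def test_width_scaling_quadratic_and_monotone(self):
        counts = [count_parameters(
            ArchitectureSpec("unet2d", (32, 32, 1, 1), 2, depth_levels=2,
                             n_first_filters=f)) for f in (8, 16, 32)]
        assert counts[0] < counts[1] < counts[2]
        assert 3.0 < counts[2] / counts[1] < 4.5


class TestForwardContract:
    def test_randomized_specs_forward_shape(self):
        rng = np.random.default_rng(77)
        for _ in range(12):
            spec = random_valid_spec(rng)
            model = build_network(spec, seed=0)
            h, w, d, c = spec.patch_size
            x = rng.normal(size=(1, c, d, h, w)).astype(np.float32)
            y = model.forward(x)
            assert y.shape == (1, spec.n_classes) + output_shape(spec)
            assert np.allclose(y.sum(axis=1), 1.0, atol=1e-5)

    def test_symbolic_trace_equals_measured_shapes(self):
        rng = np.random.default_rng(5)
        spec = random_valid_spec(rng)
        model = build_network(spec, seed=0)
        h, w, d, c = spec.patch_size
        x = rng.normal(size=(1, c, d, h, w)).astype(np.float32)
        names = model.layer_names()
        model.forward(x, capture=names)
        for name, spatial, ch in shape_trace(spec):
            got = model.captured[name].shape
            assert got == (1, ch) + tuple(spatial), name

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_forward_shape_property(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_valid_spec(rng)
        model = build_network(spec, seed=0)
        h, w, d, c = spec.patch_size
        y = model.forward(np.zeros((1, c, d, h, w), np.float32))
        assert y.shape == (1, spec.n_classes) + output_shape(spec)

    def test_valid_mode_translation_consistency(self):
        # predicting a (2**D-aligned) crop of a larger image must equal the
        # corresponding crop of the larger image's prediction
        spec = ArchitectureSpec("unet2d", (44, 44, 1, 1), 2, depth_levels=2,
                                n_first_filters=4, padding="valid")
        model = build_network(spec, seed=3)
        rng = np.random.default_rng(0)
        big = rng.normal(size=(1, 1, 1, 52, 52)).astype(np.float32)
        shift = 4  # one full pooling-grid period at depth 2
        y_big = model.forward(big)          # output 12x12
        y_crop = model.forward(big[:, :, :, shift:shift + 44, shift:shift + 44])
        assert np.allclose(y_big[:, :, :, shift:shift + 4, shift:shift + 4],
                           y_crop, atol=1e-5)
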