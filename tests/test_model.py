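"""Network construction, patch extraction/stitching, inference contracts."""
import numpy as np
import pytest

from perfectsyn.core import BinaryMask, ImageVolume, VectorField, curvature_energy
from perfectsyn.errors import ConfigError, CoverageError, ValidationError
from perfectsyn.model import (
    NetConfig,
    PatchSpec,
    build_discriminator,
    build_generator,
    extract_patches,
    load_checkpoint,
    predict_dvf,
    save_checkpoint,
    stitch_patches,
)
from perfectsyn.nn import Adam, Tensor, bce_discriminator, leaky_relu


TINY = {
    "pix2pix3d_large": ((16, 16, 16), 4, 2),
    "pix2pix3d_small": ((8, 8, 8), 4, 2),
    "pix2pix25d": ((3, 16, 16), 4, 2),
    "unet3d": ((16, 16, 16), 4, 2),
}


def tiny_cfg(variant):
    patch, base, depth = TINY[variant]
    return NetConfig(variant=variant, patch_shape=patch, base_width=base,
                     depth=depth)


class TestNetConfig:
    def test_patch_depth_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            NetConfig(variant="unet3d", patch_shape=(10, 10, 10), depth=2)

    def test_bad_slope_rejected(self):
        with pytest.raises(ConfigError):
            NetConfig(leaky_slope=1.5, patch_shape=(8, 8, 8))

    def test_unknown_variant(self):
        with pytest.raises(ConfigError):
            NetConfig(variant="resnet")


class TestGenerator:
    def test_leaky_relu_matches_stated_form(self):
        # f(x) = max(0.01 x, x)
        x = Tensor(np.array([-1.0, 2.0, -0.5, 0.0]))
        out = leaky_relu(x, 0.01).data
        np.testing.assert_allclose(out, [-0.01, 2.0, -0.005, 0.0])

    @pytest.mark.parametrize("variant", list(TINY))
    def test_output_shape_three_displacement_channels(self, variant):
        cfg = tiny_cfg(variant)
        gen = build_generator(cfg, seed=0)
        if variant == "pix2pix25d":
            x = Tensor(np.zeros((2, 3, 16, 16), np.float32))
            out = gen(x)
            assert out.shape == (2, 3, 16, 16)
        else:
            ps = cfg.patch_shape
            x = Tensor(np.zeros((2, 1, *ps), np.float32))
            out = gen(x)
            assert out.shape == (2, 3, *ps)
        assert np.all(np.isfinite(out.data))

    def test_small_has_fewer_parameters_than_large(self):
        small = build_generator(NetConfig("pix2pix3d_small",
                                          patch_shape=(16, 16, 16),
                                          base_width=8, depth=2))
        large = build_generator(NetConfig("pix2pix3d_large",
                                          patch_shape=(32, 32, 32),
                                          base_width=16, depth=3))
        count = lambda m: sum(p.data.size for p in m.parameters())
        assert count(small) < count(large)

    def test_inference_deterministic(self):
        cfg = tiny_cfg("unet3d")
        gen = build_generator(cfg, seed=3).eval()
        x = np.random.default_rng(0).normal(
            size=(1, 1, *cfg.patch_shape)).astype(np.float32)
        a = gen(Tensor(x)).data
        b = gen(Tensor(x)).data
        np.testing.assert_array_equal(a, b)


class TestDiscriminator:
    def test_scores_in_unit_interval(self):
        cfg = tiny_cfg("pix2pix3d_small")
        d = build_discriminator(cfg, seed=0)
        rng = np.random.default_rng(1)
        ct = Tensor(rng.normal(size=(2, 1, 8, 8, 8)).astype(np.float32))
        df = Tensor(rng.normal(size=(2, 3, 8, 8, 8)).astype(np.float32))
        s = d(ct, df).data
        assert np.all((s > 0) & (s < 1))

    def test_batch_permutation_equivariance(self):
        cfg = tiny_cfg("pix2pix3d_small")
        d = build_discriminator(cfg, seed=0).eval()
        rng = np.random.default_rng(2)
        ct = rng.normal(size=(3, 1, 8, 8, 8)).astype(np.float32)
        df = rng.normal(size=(3, 3, 8, 8, 8)).astype(np.float32)
        s = d(Tensor(ct), Tensor(df)).data
        perm = [2, 0, 1]
        sp = d(Tensor(ct[perm]), Tensor(df[perm])).data
        np.testing.assert_allclose(sp, s[perm], atol=1e-6)

    def test_no_adversary_for_unet(self):
        with pytest.raises(ConfigError):
            build_discriminator(tiny_cfg("unet3d"))

    def test_learns_separable_toy_fields(self):
        # real fields are constant +0.5, fakes -0.5: trivially separable
        cfg = tiny_cfg("pix2pix3d_small")
        d = build_discriminator(cfg, seed=0)
        opt = Adam(d.parameters(), lr=0.01)
        rng = np.random.default_rng(3)
        ct = rng.normal(size=(4, 1, 8, 8, 8)).astype(np.float32) * 0.1
        real = np.full((4, 3, 8, 8, 8), 0.5, np.float32)
        fake = np.full((4, 3, 8, 8, 8), -0.5, np.float32)
        for _ in range(60):
            sr = d(Tensor(ct), Tensor(real))
            sf = d(Tensor(ct), Tensor(fake))
            loss = bce_discriminator(sr, sf)
            d.zero_grad()
            loss.backward()
            opt.step()
        # score with batch statistics (training-mode forward), as during
        # adversarial training
        sr = d(Tensor(ct), Tensor(real)).data
        sf = d(Tensor(ct), Tensor(fake)).data
        acc = 0.5 * ((sr > 0.5).mean() + (sf < 0.5).mean())
        assert acc > 0.9


class TestPatches:
    @pytest.fixture()
    def volume_and_field(self, rng):
        vol = ImageVolume(rng.uniform(-500, 500, (20, 20, 20)), (2, 2, 2))
        dvf = VectorField(rng.uniform(-5, 5, (3, 20, 20, 20)), (2, 2, 2))
        return vol, dvf

    def test_reproducible_and_shaped(self, volume_and_field):
        vol, dvf = volume_and_field
        spec = PatchSpec((8, 8, 8), seed=5)
        a = extract_patches(vol, dvf, spec, 3)
        b = extract_patches(vol, dvf, spec, 3)
        for pa, pb in zip(a, b):
            assert pa["corner"] == pb["corner"]
            np.testing.assert_array_equal(pa["ct"], pb["ct"])
            assert pa["ct"].shape == (1, 8, 8, 8)
            assert pa["dvf"].shape == (3, 8, 8, 8)

    def test_patch_larger_than_volume_rejected(self, volume_and_field):
        vol, dvf = volume_and_field
        with pytest.raises(ValidationError):
            extract_patches(vol, dvf, PatchSpec((32, 32, 32)), 1)

    def test_centers_inside_body(self, volume_and_field, rng):
        vol, dvf = volume_and_field
        body_vox = np.zeros((20, 20, 20), np.uint8)
        body_vox[8:12, 8:12, 8:12] = 1
        body = BinaryMask(body_vox, (2, 2, 2))
        out = extract_patches(vol, dvf, PatchSpec((8, 8, 8), seed=1), 10,
                              body=body)
        for p in out:
            c = [p["corner"][a] + 4 for a in range(3)]
            assert all(6 <= ci <= 13 for ci in c)

    def test_exact_tiling_covers_once(self):
        # stride == patch: stitching a tiling reproduces the field exactly
        rng = np.random.default_rng(0)
        field = rng.normal(size=(3, 16, 16, 16)).astype(np.float32)
        patches = []
        for z in range(0, 16, 8):
            for y in range(0, 16, 8):
                for x in range(0, 16, 8):
                    patches.append(
                        (field[:, z:z + 8, y:y + 8, x:x + 8], (z, y, x)))
        out = stitch_patches(patches, (16, 16, 16), (1, 1, 1))
        np.testing.assert_allclose(out.components, field, atol=1e-6)


class TestStitch:
    def test_constant_patches_blend_exactly(self):
        p = np.full((3, 8, 8, 8), 2.5, np.float32)
        corners = [(z, y, x) for z in (0, 4) for y in (0, 4) for x in (0, 4)]
        out = stitch_patches([(p, c) for c in corners], (12, 12, 12),
                             (1, 1, 1))
        np.testing.assert_allclose(out.components, 2.5, atol=1e-6)

    def test_half_overlap_midpoint_average(self):
        a = np.full((3, 4, 4, 8), 1.0, np.float32)
        b = np.full((3, 4, 4, 8), 3.0, np.float32)
        out = stitch_patches([(a, (0, 0, 0)), (b, (0, 0, 4))], (4, 4, 12),
                             (1, 1, 1))
        # voxel x=5: centre of neither; midpoint symmetry holds at x=5,6
        # where the two tent weights are equal by construction
        mid = out.components[:, :, :, 5:7]
        assert np.allclose(mid.mean(), 2.0, atol=0.25)
        # left end pure a, right end pure b
        np.testing.assert_allclose(out.components[..., 0], 1.0, atol=1e-6)
        np.testing.assert_allclose(out.components[..., -1], 3.0, atol=1e-6)

    def test_uncovered_voxels_raise(self):
        p = np.zeros((3, 4, 4, 4), np.float32)
        with pytest.raises(CoverageError):
            stitch_patches([(p, (0, 0, 0))], (8, 8, 8), (1, 1, 1))


class TestPredict:
    def test_untrained_output_finite_and_smooth(self, rng):
        cfg = tiny_cfg("unet3d")
        gen = build_generator(cfg, seed=0)
        vol = ImageVolume(rng.uniform(-1000, 1000, (20, 20, 20)), (2, 2, 2))
        dvf = predict_dvf(gen, cfg, vol)
        assert dvf.grid.shape == (20, 20, 20)
        assert np.all(np.isfinite(dvf.components))
        assert np.isfinite(curvature_energy(dvf))

    def test_repeat_inference_identical(self, rng):
        cfg = tiny_cfg("unet3d")
        gen = build_generator(cfg, seed=0)
        vol = ImageVolume(rng.uniform(-1000, 1000, (20, 20, 20)), (2, 2, 2))
        a = predict_dvf(gen, cfg, vol)
        b = predict_dvf(gen, cfg, vol)
        np.testing.assert_array_equal(a.components, b.components)

    def test_unnormalizable_input_rejected(self, rng):
        cfg = tiny_cfg("unet3d")
        gen = build_generator(cfg, seed=0)
        vol = ImageVolume(rng.uniform(0, 60000, (20, 20, 20)), (2, 2, 2))
        with pytest.raises(ValidationError):
            predict_dvf(gen, cfg, vol)

    def test_25d_consumes_three_slices(self, rng):
        cfg = tiny_cfg("pix2pix25d")
        gen = build_generator(cfg, seed=0)
        vol = ImageVolume(rng.uniform(-1000, 1000, (6, 16, 16)), (2, 2, 2))
        dvf = predict_dvf(gen, cfg, vol)
        assert dvf.grid.shape == (6, 16, 16)
        assert np.all(np.isfinite(dvf.components))


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        cfg = tiny_cfg("pix2pix3d_small")
        gen = build_generator(cfg, seed=0)
        disc = build_discriminator(cfg, seed=0)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, gen, cfg, disc)
        gen2, cfg2, disc2 = load_checkpoint(path)
        assert cfg2 == cfg
        x = rng.normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_array_equal(
            gen.eval()(Tensor(x)).data, gen2.eval()(Tensor(x)).data)
        assert disc2 is not None
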