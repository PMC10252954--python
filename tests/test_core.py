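"""Warping, curvature regularizer and virtual-couch geometry."""
import numpy as np
import pytest

from perfectsyn.core import (
    AIR_HU,
    BinaryMask,
    CouchModel,
    ImageVolume,
    StructureSet,
    VectorField,
    add_virtual_couch,
    curvature_energy,
    warp_image,
    warp_structures,
)
from perfectsyn.errors import GridMismatchError, PlacementError, ValidationError

from conftest import random_field, random_mask, random_volume


SPACING = (2.0, 1.5, 1.0)


def constant_field(shape, spacing, vec):
    comps = np.zeros((3, *shape), np.float32)
    for a in range(3):
        comps[a] = vec[a]
    return VectorField(comps, spacing)


class TestWarpImage:
    @pytest.mark.parametrize("interp", ["trilinear", "nearest"])
    def test_zero_field_is_identity(self, rng, interp):
        vol = random_volume(rng)
        out = warp_image(vol, VectorField.zeros(vol.grid), interp)
        assert np.max(np.abs(out.voxels - vol.voxels)) <= 1e-4

    def test_constant_shift_of_linear_ramp(self):
        # I(x) = x * spacing_x; shifting the sampling point by +2 voxels along
        # x must reproduce the ramp evaluated 2 voxels further
        shape = (4, 5, 12)
        x = np.arange(shape[2], dtype=np.float32) * SPACING[2]
        vol = ImageVolume(np.broadcast_to(x, shape).copy(), SPACING)
        dvf = constant_field(shape, SPACING, (0.0, 0.0, 2.0 * SPACING[2]))
        out = warp_image(vol, dvf, "trilinear")
        interior = out.voxels[:, :, : shape[2] - 2]
        expected = vol.voxels[:, :, 2:]
        np.testing.assert_allclose(interior, expected, atol=1e-4)

    def test_trilinear_bounded_by_input_range(self, rng):
        vol = random_volume(rng)
        vol.voxels[0, 0, 0] = -1000.0  # air present, so the fill is in range
        dvf = random_field(rng, amp=4.0)
        out = warp_image(vol, dvf, "trilinear")
        assert out.voxels.min() >= vol.voxels.min() - 1e-3
        assert out.voxels.max() <= vol.voxels.max() + 1e-3

    def test_out_of_field_returns_air(self):
        shape = (4, 4, 4)
        vol = ImageVolume(np.full(shape, 500.0, np.float32), SPACING)
        dvf = constant_field(shape, SPACING, (0.0, 0.0, 100.0))
        out = warp_image(vol, dvf)
        assert np.all(out.voxels == AIR_HU)

    def test_nearest_preserves_value_set(self, rng):
        mask = (rng.random((6, 6, 6)) < 0.5).astype(np.float32)
        vol = ImageVolume(mask, SPACING)
        dvf = random_field(rng, shape=(6, 6, 6), amp=2.0)
        out = warp_image(vol, dvf, "nearest", fill_value=0.0)
        assert set(np.unique(out.voxels)) <= {0.0, 1.0}

    def test_constant_field_composition(self, rng):
        vol = random_volume(rng, shape=(10, 10, 10))
        # integer-voxel shifts: interpolation is then exact and the
        # composition identity holds without smoothing error
        u1 = (2.0, -1.5, 1.0)
        u2 = (-2.0, 3.0, 2.0)
        d1 = constant_field(vol.grid.shape, SPACING, u1)
        d2 = constant_field(vol.grid.shape, SPACING, u2)
        d12 = constant_field(vol.grid.shape, SPACING, np.add(u1, u2))
        two_step = warp_image(warp_image(vol, d1), d2)
        one_step = warp_image(vol, d12)
        c = slice(2, -2)
        np.testing.assert_allclose(
            two_step.voxels[c, c, c], one_step.voxels[c, c, c], atol=1e-3
        )

    def test_grid_mismatch_raises(self, rng):
        vol = random_volume(rng)
        bad = random_field(rng, shape=(5, 5, 5))
        with pytest.raises(GridMismatchError):
            warp_image(vol, bad)

    def test_non_finite_displacement_rejected(self):
        comps = np.zeros((3, 4, 4, 4), np.float32)
        comps[0, 0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            VectorField(comps, SPACING)


class TestWarpStructures:
    def test_zero_field_identity_and_names(self, rng):
        structs = StructureSet({
            "a": random_mask(rng), "b": random_mask(rng, p=0.1),
        })
        out = warp_structures(structs, VectorField.zeros(structs.grid))
        assert set(out) == {"a", "b"}
        for name in out:
            np.testing.assert_array_equal(out[name].voxels, structs[name].voxels)

    def test_integer_voxel_shift_matches_bruteforce(self, rng):
        mask = random_mask(rng, shape=(8, 8, 8), spacing=SPACING)
        structs = StructureSet({"m": mask})
        shift = (1, -2, 3)  # voxels
        mm = tuple(shift[a] * SPACING[a] for a in range(3))
        out = warp_structures(structs, constant_field((8, 8, 8), SPACING, mm))
        # brute-force voxel relocation oracle (pull-back: out[v] = in[v+shift])
        expected = np.zeros_like(mask.voxels)
        for z, y, x in zip(*np.nonzero(mask.voxels)):
            zz, yy, xx = z - shift[0], y - shift[1], x - shift[2]
            if 0 <= zz < 8 and 0 <= yy < 8 and 0 <= xx < 8:
                expected[zz, yy, xx] = 1
        np.testing.assert_array_equal(out["m"].voxels, expected)

    def test_empty_mask_stays_empty(self, rng):
        structs = StructureSet({"e": BinaryMask(np.zeros((6, 6, 6), np.uint8), SPACING)})
        out = warp_structures(structs, random_field(rng, shape=(6, 6, 6)))
        assert out["e"].count() == 0


def bruteforce_curvature(field: VectorField) -> float:
    """Independent loop-based oracle for the curvature energy."""
    comps = field.components.astype(np.float64)
    sp = field.spacing
    nz, ny, nx = comps.shape[1:]
    total, n = 0.0, 0
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                for c in range(3):
                    u = comps[c]
                    lap = (
                        (u[z + 1, y, x] - 2 * u[z, y, x] + u[z - 1, y, x]) / sp[0] ** 2
                        + (u[z, y + 1, x] - 2 * u[z, y, x] + u[z, y - 1, x]) / sp[1] ** 2
                        + (u[z, y, x + 1] - 2 * u[z, y, x] + u[z, y, x - 1]) / sp[2] ** 2
                    )
                    total += lap * lap
                n += 1
    return total / n


class TestCurvatureEnergy:
    def test_constant_field_is_zero(self):
        assert curvature_energy(constant_field((5, 5, 5), SPACING, (3, -2, 1))) == 0.0

    def test_affine_fields_are_zero(self, rng):
        # u(pos) = A pos + b has vanishing second derivatives
        for _ in range(25):
            A = rng.uniform(-0.2, 0.2, (3, 3))
            b = rng.uniform(-5, 5, 3)
            shape = (6, 5, 7)
            grid = np.stack(np.meshgrid(
                *[np.arange(shape[a]) * SPACING[a] for a in range(3)], indexing="ij"
            ))
            comps = np.einsum("ij,jzyx->izyx", A, grid) + b[:, None, None, None]
            e = curvature_energy(VectorField(comps.astype(np.float32), SPACING))
            assert e <= 1e-6

    def test_quadratic_field_analytic_value(self):
        # u_x = x^2 in voxel units at unit spacing: Laplacian = 2 everywhere
        # on the interior, so the energy is 4 per interior voxel
        shape = (5, 5, 8)
        comps = np.zeros((3, *shape), np.float32)
        comps[2] = (np.arange(shape[2], dtype=np.float32) ** 2)[None, None, :]
        e = curvature_energy(VectorField(comps, (1.0, 1.0, 1.0)))
        assert abs(e - 4.0) < 1e-9

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            f = random_field(rng, shape=(6, 7, 5), amp=5.0)
            assert abs(curvature_energy(f) - bruteforce_curvature(f)) < 1e-9

    def test_invariant_under_added_affine(self, rng):
        f = random_field(rng, shape=(6, 6, 6), spacing=SPACING)
        A = rng.uniform(-0.1, 0.1, (3, 3))
        b = rng.uniform(-3, 3, 3)
        grid = np.stack(np.meshgrid(
            *[np.arange(6) * SPACING[a] for a in range(3)], indexing="ij"
        ))
        affine = np.einsum("ij,jzyx->izyx", A, grid) + b[:, None, None, None]
        g = VectorField(f.components + affine.astype(np.float32), SPACING)
        assert abs(curvature_energy(f) - curvature_energy(g)) < 1e-5

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValidationError):
            curvature_energy(constant_field((2, 5, 5), SPACING, (0, 0, 0)))


def ellipsoid_body(shape=(8, 20, 20), r_post=13):
    """Body mask whose most posterior occupied row is exactly r_post."""
    z, y, x = np.mgrid[: shape[0], : shape[1], : shape[2]]
    body = ((y - 8) ** 2 / (r_post - 8 + 0.5) ** 2 + (x - 10) ** 2 / 36) <= 1.0
    m = BinaryMask(body.astype(np.uint8), (2.0, 2.0, 2.0))
    assert np.nonzero(m.voxels.any(axis=(0, 2)))[0].max() == r_post
    return m


class TestVirtualCouch:
    def test_top_surface_tangent_to_body(self):
        body = ellipsoid_body()
        img = ImageVolume(np.where(body.voxels, 40.0, -1000.0), body.spacing)
        couch = CouchModel(thickness_mm=6.0, top_thickness_mm=2.0, width_mm=30.0)
        out = add_virtual_couch(img, body, couch)
        r_post = 13
        changed = np.abs(out.voxels - img.voxels) > 0
        rows = np.nonzero(changed.any(axis=(0, 2)))[0]
        assert rows.min() == r_post + 1
        assert np.all(out.voxels[:, r_post + 1, 7:14] == couch.top_hu)

    def test_body_voxels_untouched_and_local(self):
        body = ellipsoid_body()
        vox = np.where(body.voxels, 40.0, -1000.0).astype(np.float32)
        vox[:, 16:18, :] = 200.0  # stale couch-like HU posterior to the body
        img = ImageVolume(vox, body.spacing)
        out = add_virtual_couch(img, body, CouchModel(thickness_mm=6.0, width_mm=30.0))
        assert np.array_equal(out.voxels[body.as_bool()], img.voxels[body.as_bool()])
        # anterior half of the grid untouched
        np.testing.assert_array_equal(out.voxels[:, :8, :], img.voxels[:, :8, :])

    def test_body_touching_posterior_boundary_raises(self):
        vox = np.zeros((4, 6, 6), np.uint8)
        vox[:, 2:, 2:4] = 1
        body = BinaryMask(vox, (2.0, 2.0, 2.0))
        img = ImageVolume(np.where(vox, 40.0, -1000.0), body.spacing)
        with pytest.raises(PlacementError):
            add_virtual_couch(img, body, CouchModel())

    def test_empty_body_rejected(self):
        body = BinaryMask(np.zeros((4, 6, 6), np.uint8), (2.0, 2.0, 2.0))
        img = ImageVolume(np.full((4, 6, 6), -1000.0), body.spacing)
        with pytest.raises(ValidationError):
            add_virtual_couch(img, body, CouchModel())
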