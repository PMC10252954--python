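"""Couch removal, segmentation, rigid alignment, deformable registration."""
import itertools

import numpy as np
import pytest
from scipy import ndimage

from perfectsyn.core import BinaryMask, ImageVolume, warp_image
from perfectsyn.errors import ValidationError
from perfectsyn.phantom import PhantomSpec, generate_phantom_pair
from perfectsyn.preprocess import (
    abdominal_mask,
    deformable_register,
    remove_couch,
    resample,
    rigid_align_spine,
    segment_lungs,
    segment_spine,
)


def dice(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2.0 * np.sum(a & b) / s


@pytest.fixture(scope="module")
def prepared(default_pair):
    """Couch-removed dCT/pCT + masks of the shared fixture pair."""
    dimg, dbody = remove_couch(default_pair.dct)
    pimg, pbody = remove_couch(default_pair.pct)
    return default_pair, dimg, dbody, pimg, pbody


class TestRemoveCouch:
    def test_couch_voxels_removed_body_untouched(self, prepared):
        pair, dimg, dbody, _, _ = prepared
        # everything dense outside the true body (i.e. the couch) is gone
        outside = ~dbody.as_bool()
        assert np.all(dimg.voxels[outside] == -1000.0)
        inside = dbody.as_bool()
        np.testing.assert_array_equal(dimg.voxels[inside],
                                      pair.dct.voxels[inside])
        assert dice(dbody.voxels, pair.structs_d["body"].voxels) > 0.9

    def test_couch_free_volume_unchanged_inside(self, prepared):
        pair, _, _, pimg, pbody = prepared
        np.testing.assert_array_equal(
            pimg.voxels[pbody.as_bool()], pair.pct.voxels[pbody.as_bool()])

    def test_all_air_rejected(self):
        vol = ImageVolume(np.full((6, 6, 6), -1000.0), (2, 2, 2))
        with pytest.raises(ValidationError):
            remove_couch(vol)


class TestSegmentation:
    def test_spine_matches_truth(self, prepared):
        pair, dimg, dbody, _, _ = prepared
        spine = segment_spine(dimg, dbody)
        assert dice(spine.voxels, pair.structs_d["spine"].voxels) >= 0.8

    def test_no_bone_rejected(self):
        vox = np.full((6, 8, 8), -1000.0, np.float32)
        vox[:, 2:6, 2:6] = 40.0
        img = ImageVolume(vox, (2, 2, 2))
        body = BinaryMask((vox > -300).astype(np.uint8), (2, 2, 2))
        with pytest.raises(ValidationError):
            segment_spine(img, body)

    def test_posterior_rod_selected(self):
        # two bone rods; the posterior (larger) one must win
        vox = np.full((8, 24, 12), 40.0, np.float32)
        vox[:, 4:6, 5:7] = 700.0          # anterior rod
        vox[:, 18:22, 4:8] = 700.0        # posterior rod, larger
        img = ImageVolume(vox, (2, 2, 2))
        body = BinaryMask(np.ones_like(vox, np.uint8), (2, 2, 2))
        spine = segment_spine(img, body)
        assert spine.voxels[:, 18:22, 4:8].all()
        assert not spine.voxels[:, 4:6, 5:7].any()

    def test_lungs_match_truth_and_inside_body(self, prepared):
        pair, dimg, dbody, _, _ = prepared
        lungs = segment_lungs(dimg, dbody)
        assert dice(lungs.voxels, pair.structs_d["lungs"].voxels) >= 0.9
        assert not np.any(lungs.as_bool() & ~dbody.as_bool())

    def test_no_low_hu_interior_gives_empty_lungs(self):
        vox = np.full((6, 8, 8), 40.0, np.float32)
        img = ImageVolume(vox, (2, 2, 2))
        body = BinaryMask(np.ones_like(vox, np.uint8), (2, 2, 2))
        assert segment_lungs(img, body).count() == 0

    def test_abdominal_mask_slice_arithmetic(self):
        body = BinaryMask(np.ones((10, 6, 6), np.uint8), (2, 2, 2))
        lungs_vox = np.zeros((10, 6, 6), np.uint8)
        lungs_vox[:4, 2:4, 2:4] = 1  # lungs end at slice 3
        lungs = BinaryMask(lungs_vox, (2, 2, 2))
        abd = abdominal_mask(body, lungs)
        assert not abd.voxels[:4].any()
        assert abd.voxels[4:].all()

    def test_abdominal_mask_empty_lungs_is_body(self):
        body = BinaryMask(np.ones((6, 6, 6), np.uint8), (2, 2, 2))
        lungs = BinaryMask(np.zeros((6, 6, 6), np.uint8), (2, 2, 2))
        np.testing.assert_array_equal(abdominal_mask(body, lungs).voxels,
                                      body.voxels)

    def test_abdominal_mask_lungs_span_all_slices(self):
        body = BinaryMask(np.ones((6, 6, 6), np.uint8), (2, 2, 2))
        lungs = BinaryMask(np.ones((6, 6, 6), np.uint8), (2, 2, 2))
        assert abdominal_mask(body, lungs).count() == 0


def make_rigidly_moved(img, center, theta_deg, t_mm):
    """Oracle fixture: moving image whose alignment back onto ``img`` is
    exactly (theta, t) in the registration's parameterization."""
    th = np.deg2rad(-theta_deg)
    grids = [np.arange(n) * s for n, s in zip(img.grid.shape, img.spacing)]
    Z, Y, X = np.meshgrid(*grids, indexing="ij")
    cz, cy, cx = center
    tz, ty, tx = t_mm
    Yq, Xq = Y - ty, X - tx
    Yr = cy + np.cos(th) * (Yq - cy) - np.sin(th) * (Xq - cx)
    Xr = cx + np.sin(th) * (Yq - cy) + np.cos(th) * (Xq - cx)
    coords = [(Z - tz) / img.spacing[0], Yr / img.spacing[1], Xr / img.spacing[2]]
    mv = ndimage.map_coordinates(img.voxels.astype(np.float64), coords,
                                 order=1, mode="constant", cval=-1000)
    return ImageVolume(mv.astype(np.float32), img.spacing)


def spine_roi_center(img, spine):
    roi = ndimage.binary_dilation(
        spine.as_bool(), ndimage.generate_binary_structure(3, 1), iterations=3)
    m = int(np.ceil(24.0 / img.spacing[0]))
    roi[:m] = False
    roi[-m:] = False
    return tuple(np.argwhere(roi).mean(axis=0) * np.asarray(img.spacing))


class TestRigidAlign:
    def test_identity(self, prepared):
        _, dimg, dbody, _, _ = prepared
        spine = segment_spine(dimg, dbody)
        rt = rigid_align_spine(dimg, dimg, spine)
        assert abs(rt.rotation_deg) <= 0.1
        assert max(abs(v) for v in rt.translation_mm) <= 0.1

    @pytest.mark.parametrize("theta,t", [
        (0.0, (5.0, -3.0, 0.0)),
        (4.0, (0.0, 0.0, 0.0)),
        (-3.0, (0.0, 0.0, 0.0)),
    ])
    def test_recovers_injected_transform(self, prepared, theta, t):
        _, dimg, dbody, _, _ = prepared
        spine = segment_spine(dimg, dbody)
        center = spine_roi_center(dimg, spine)
        moving = make_rigidly_moved(dimg, center, theta, t)
        rt = rigid_align_spine(moving, dimg, spine)
        assert abs(rt.rotation_deg - theta) <= 0.5
        assert max(abs(g - w) for g, w in zip(rt.translation_mm, t)) <= 0.5

    def test_empty_spine_rejected(self, prepared):
        _, dimg, _, _, _ = prepared
        empty = BinaryMask(np.zeros(dimg.grid.shape, np.uint8), dimg.spacing)
        with pytest.raises(ValidationError):
            rigid_align_spine(dimg, dimg, empty)


class TestDeformable:
    @pytest.fixture(scope="class")
    def registered(self, prepared):
        pair, dimg, dbody, pimg, pbody = prepared
        spine = segment_spine(pimg, pbody)
        lungs = segment_lungs(pimg, pbody)
        abd = abdominal_mask(pbody, lungs)
        res = deformable_register(dimg, pimg, spine, lungs, abd)
        return pair, dimg, pimg, pbody, res

    def test_identity_pair_near_zero_field(self, prepared):
        _, dimg, dbody, _, _ = prepared
        spine = segment_spine(dimg, dbody)
        res = deformable_register(dimg, dimg, spine)
        assert float(res.dvf.magnitude().max()) <= 0.5

    def test_recovers_phantom_deformation(self, registered):
        pair, dimg, pimg, pbody, res = registered
        warped = warp_image(dimg, res.dvf)
        wb = ndimage.binary_fill_holes(warped.voxels > -300)
        assert dice(wb, pbody.voxels) >= 0.90
        err = np.sqrt(np.sum(
            (res.dvf.components - pair.gt_dvf.components) ** 2, axis=0))
        assert float(err[pbody.as_bool()].mean()) <= 2.0

    def test_spine_rigidity(self, registered):
        pair, _, _, _, res = registered
        sp = pair.structs_d["spine"].as_bool()
        assert float(res.dvf.magnitude()[sp].max()) <= 0.5

    def test_similarity_monotone_within_levels(self, registered):
        *_, res = registered
        for _, group in itertools.groupby(res.diagnostics,
                                          key=lambda d: d["level"]):
            sims = [g["similarity"] for g in group]
            assert all(b <= a + 1e-9 for a, b in zip(sims, sims[1:]))

    def test_abdominal_stage_improves_abdominal_similarity(self, registered):
        *_, res = registered
        abdomen = [d for d in res.diagnostics if d["level"].startswith("abdomen")]
        assert abdomen
        assert abdomen[-1]["similarity"] <= abdomen[0]["similarity"] + 1e-9


class TestResample:
    def test_same_spacing_identity(self, rng):
        vol = ImageVolume(rng.uniform(-100, 100, (6, 8, 10)), (2.0, 2.0, 2.0))
        out = resample(vol, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-5)

    def test_constant_stays_constant(self):
        vol = ImageVolume(np.full((8, 8, 8), 123.0), (1.0, 1.0, 1.0))
        out = resample(vol, (2.5, 2.5, 2.5))
        np.testing.assert_allclose(out.voxels, 123.0, atol=1e-5)

    def test_linear_ramp_closed_form(self):
        shape = (4, 4, 40)
        x = np.arange(shape[2], dtype=np.float64) * 1.0
        vol = ImageVolume(np.broadcast_to(x, shape).copy(), (1.0, 1.0, 1.0))
        out = resample(vol, (1.0, 1.0, 2.5))
        expected = np.arange(out.voxels.shape[2]) * 2.5
        interior = out.voxels[:, :, :-1]
        np.testing.assert_allclose(
            interior, np.broadcast_to(expected[:-1], interior.shape), atol=1e-6)

    def test_world_extent_preserved(self, rng):
        vol = ImageVolume(rng.uniform(-10, 10, (8, 8, 8)), (2.0, 2.0, 2.0))
        out = resample(vol, (1.0, 1.0, 1.0))
        assert out.voxels.shape == (16, 16, 16)
        assert out.origin == vol.origin

    def test_bad_spacing_rejected(self, rng):
        vol = ImageVolume(rng.uniform(-1, 1, (4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValidationError):
            resample(vol, (0.0, 1.0, 1.0))
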