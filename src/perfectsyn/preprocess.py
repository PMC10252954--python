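"""Data preparation: couch removal, spine/lung segmentation, spine-ROI rigid
alignment, and a two-stage rigidity-constrained deformable registration.

The deformable engine is a multi-resolution demons-style solver with
Gaussian field smoothing and a hard spine-rigidity projection (displacement
forced to zero inside the dilated spine mask, smoothly blended over ~5 mm).
Stage 1 matches the whole body; stage 2 refines inside the abdominal mask
with the lungs excluded, composed on top of the stage-1 field.  Updates are
accepted only when the masked mean-squared HU difference decreases, so the
recorded similarity trace is monotone within each resolution level.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .core import (
    AIR_HU,
    BinaryMask,
    Grid,
    ImageVolume,
    VectorField,
    warp_image,
)
from .errors import ConvergenceError, ValidationError

BODY_HU_THRESHOLD = -300.0
BONE_HU_THRESHOLD = 200.0
LUNG_HU_THRESHOLD = -400.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask, bool)
    sizes = ndimage.sum(mask, lab, range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def remove_couch(
    image: ImageVolume, threshold: float = BODY_HU_THRESHOLD
) -> Tuple[ImageVolume, BinaryMask]:
    """Strip everything but the patient: the body is the largest connected
    component above ``threshold`` HU after morphological closing (holes such
    as lungs and bowel gas are filled); all other voxels become air."""
    fg = image.voxels > threshold
    if not fg.any():
        raise ValidationError("remove_couch: no tissue above threshold")
    # pad before closing so border slices are not eroded away
    fgp = np.pad(fg, 1)
    fgp = ndimage.binary_closing(fgp, ndimage.generate_binary_structure(3, 1),
                                 iterations=1)
    fg = fgp[1:-1, 1:-1, 1:-1]
    body = _largest_component(fg)
    if not body.any():
        raise ValidationError("remove_couch: no connected tissue component")
    body = ndimage.binary_fill_holes(body)
    out = np.where(body, image.voxels, np.float32(AIR_HU))
    return (
        ImageVolume(out, image.spacing, image.origin),
        BinaryMask(body.astype(np.uint8), image.spacing, image.origin, "body"),
    )


def segment_spine(
    image: ImageVolume, body: BinaryMask, threshold: float = BONE_HU_THRESHOLD
) -> BinaryMask:
    """Spine as the bone component seeded in the posterior third of the body.

    The largest bony component inside the posterior third of the body
    bounding box serves as the seed; the full connected bone component
    containing it is returned (vertebral bodies extend anterior of the
    strict posterior-third window), morphologically closed."""
    if body.count() == 0:
        raise ValidationError("segment_spine: empty body mask")
    rows = np.nonzero(body.voxels.any(axis=(0, 2)))[0]
    bone = (image.voxels >= threshold) & body.as_bool()
    seed_region = np.zeros_like(bone)
    # posterior third of the body bounding box; widened to the posterior
    # half when a sagged posterior surface stretches the box past the spine
    for frac in (2 / 3, 1 / 2):
        y0 = rows.min() + int(np.ceil((rows.max() - rows.min() + 1) * frac))
        seed_region = bone.copy()
        seed_region[:, :y0, :] = False
        if seed_region.any():
            break
    if not seed_region.any():
        raise ValidationError("segment_spine: no bone voxels found")
    seed = _largest_component(seed_region)
    lab, _ = ndimage.label(bone)
    spine = np.isin(lab, np.unique(lab[seed & (lab > 0)]))
    spine = ndimage.binary_closing(
        np.pad(spine, 1), ndimage.generate_binary_structure(3, 1),
        iterations=1)[1:-1, 1:-1, 1:-1]
    return BinaryMask(spine.astype(np.uint8), image.spacing, image.origin, "spine")


def segment_lungs(
    image: ImageVolume, body: BinaryMask, threshold: float = LUNG_HU_THRESHOLD
) -> BinaryMask:
    """Up to two largest air-filled components strictly inside the body."""
    if body.count() == 0:
        raise ValidationError("segment_lungs: empty body mask")
    interior = ndimage.binary_erosion(
        body.as_bool(), ndimage.generate_binary_structure(3, 1))
    low = (image.voxels < threshold) & interior
    lab, n = ndimage.label(low)
    out = np.zeros_like(low)
    if n:
        sizes = ndimage.sum(low, lab, range(1, n + 1))
        order = np.argsort(sizes)[::-1]
        for i in order[:2]:
            if sizes[i] >= 5:  # ignore speckle
                out |= lab == (i + 1)
    return BinaryMask(out.astype(np.uint8), image.spacing, image.origin, "lungs")


def abdominal_mask(body: BinaryMask, lungs: BinaryMask) -> BinaryMask:
    """Body restricted to axial slices inferior to the lowest lung voxel
    (slice index increases toward the feet); equals the body when no lungs."""
    if body.count() == 0:
        raise ValidationError("abdominal_mask: empty body mask")
    out = body.as_bool().copy()
    if lungs.count():
        z_low = int(np.nonzero(lungs.voxels.any(axis=(1, 2)))[0].max())
        out[: z_low + 1] = False
    return BinaryMask(out.astype(np.uint8), body.spacing, body.origin, "abdomen")


# ---------------------------------------------------------------------------
# rigid spine alignment
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """z-axis rotation (degrees) + translation (mm, (z, y, x) order), applied
    about a stated centre in world mm."""

    rotation_deg: float
    translation_mm: Tuple[float, float, float]
    center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (-180.0 < self.rotation_deg <= 180.0):
            raise ValidationError("rotation must be in (-180, 180] degrees")


def _sample_rigid(moving: ImageVolume, grid: Grid, params, center_mm) -> np.ndarray:
    """Sample ``moving`` at rigidly transformed positions of ``grid``.

    params = (theta_deg, tz, ty, tx); pull-back: p_moving = R(p - c) + c + t.
    """
    theta = np.deg2rad(params[0])
    t = np.asarray(params[1:4])
    cz, cy, cx = center_mm
    zs = np.arange(grid.shape[0]) * grid.spacing[0] + grid.origin[0]
    ys = np.arange(grid.shape[1]) * grid.spacing[1] + grid.origin[1]
    xs = np.arange(grid.shape[2]) * grid.spacing[2] + grid.origin[2]
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    cosr, sinr = np.cos(theta), np.sin(theta)
    Yr = cy + cosr * (Y - cy) - sinr * (X - cx)
    Xr = cx + sinr * (Y - cy) + cosr * (X - cx)
    Zr = Z
    coords = [
        (Zr + t[0] - moving.origin[0]) / moving.spacing[0],
        (Yr + t[1] - moving.origin[1]) / moving.spacing[1],
        (Xr + t[2] - moving.origin[2]) / moving.spacing[2],
    ]
    sampled = ndimage.map_coordinates(
        moving.voxels.astype(np.float64), coords, order=1,
        mode="constant", cval=AIR_HU)
    valid = np.ones(sampled.shape, bool)
    for a in range(3):
        valid &= (coords[a] >= 0) & (coords[a] <= moving.grid.shape[a] - 1)
    return sampled, valid


def _downsample(vol: ImageVolume, factor: int) -> ImageVolume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.voxels.astype(np.float64), sigma=0.5 * factor)
    sub = sm[::factor, ::factor, ::factor]
    spacing = tuple(s * factor for s in vol.spacing)
    return ImageVolume(sub.astype(np.float32), spacing, vol.origin)


def rigid_align_spine(
    moving: ImageVolume,
    fixed: ImageVolume,
    spine_fixed: BinaryMask,
    dilate_mm: float = 12.0,
) -> RigidTransform:
    """Recover the z-rotation + translation aligning ``moving`` onto ``fixed``
    by minimizing the mean-squared HU difference inside the dilated spine ROI
    of the fixed image (the dCT is the fixed physical reference).

    Multi-resolution Powell search; raises :class:`ConvergenceError` when the
    final level ends with a worse similarity than it started."""
    if spine_fixed.count() == 0:
        raise ValidationError("rigid_align_spine: empty spine mask")
    it = max(1, int(round(dilate_mm / min(fixed.spacing))))
    roi = ndimage.binary_dilation(
        spine_fixed.as_bool(), ndimage.generate_binary_structure(3, 1),
        iterations=it)
    # trim the axial ends so the similarity domain stays inside the moving
    # image for the expected capture range (avoids domain-shrinkage bias)
    margin = int(np.ceil(24.0 / fixed.spacing[0]))
    if roi.shape[0] > 2 * margin + 4:
        roi[:margin] = False
        roi[-margin:] = False
    idx = np.argwhere(roi)
    center = tuple(
        idx.mean(axis=0) * np.asarray(fixed.spacing) + np.asarray(fixed.origin))

    # crop the fixed ROI bounding box (with margin) for speed
    lo = np.maximum(idx.min(axis=0) - 2, 0)
    hi = np.minimum(idx.max(axis=0) + 3, fixed.grid.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    roi_c = roi[sl]

    # smooth both images identically: raw trilinear MSE has a small but
    # systematic rotation bias from one-sided interpolation blur at sharp
    # bone edges; matching blur on both sides centres the optimum
    fixed_s = ndimage.gaussian_filter(fixed.voxels.astype(np.float64), 1.5)
    moving_s = ImageVolume(
        ndimage.gaussian_filter(moving.voxels.astype(np.float64), 1.5)
        .astype(np.float32), moving.spacing, moving.origin)

    params = np.zeros(4)
    history = []
    for factor in (2, 1):
        fx = fixed_s[sl]
        sel = roi_c
        if factor > 1:
            fx = fx[::factor, ::factor, ::factor]
            sel = roi_c[::factor, ::factor, ::factor]
        crop_grid = Grid(
            fx.shape,
            tuple(s * factor for s in fixed.spacing),
            tuple(fixed.origin[a] + lo[a] * fixed.spacing[a] for a in range(3)),
        )

        def cost(p):
            sampled, valid = _sample_rigid(moving_s, crop_grid, p, center)
            use = sel & valid
            if use.sum() < max(16, 0.25 * sel.sum()):
                return 1e12  # transform pushed the ROI out of the image
            d = sampled[use] - fx[use]
            return float(np.mean(d * d))

        if factor > 1:
            # exhaustive coarse translation search: vertebra-like periodic
            # structure creates aliased minima one period away, which a
            # local optimizer can fall into
            steps = np.arange(-20.0, 20.1, 4.0)
            best = (cost(params), tuple(params))
            for tz in steps:
                for ty in steps:
                    for tx in steps:
                        p = (params[0], tz, ty, tx)
                        c = cost(p)
                        if c < best[0]:
                            best = (c, p)
            params = np.asarray(best[1], float)
        start = cost(params)
        res = minimize(cost, params, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 80})
        params = res.x
        history.append((factor, start, float(res.fun)))
    if history[-1][2] > history[-1][1] + 1e-9:
        raise ConvergenceError(
            f"rigid_align_spine diverged: {history[-1][1]} -> {history[-1][2]}")
    theta = float((params[0] + 180.0) % 360.0 - 180.0)
    return RigidTransform(theta, tuple(float(v) for v in params[1:4]), center)


def apply_rigid(moving: ImageVolume, grid: Grid, transform: RigidTransform,
                order: int = 1) -> ImageVolume:
    """Resample ``moving`` through a rigid transform onto ``grid``."""
    p = (transform.rotation_deg, *transform.translation_mm)
    out, _ = _sample_rigid(moving, grid, p, transform.center_mm)
    if order == 0:  # label maps: round the trilinear result back to labels
        out = np.round(out)
    return ImageVolume(out.astype(np.float32), grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# deformable registration (demons-style with spine rigidity)
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    dvf: VectorField
    final_similarity: float
    iterations: int
    diagnostics: List[dict] = field(default_factory=list)


def _rigidity_blend(spine: np.ndarray, spacing, blend_mm: float = 12.0,
                    dilate_mm: float = 2.0) -> np.ndarray:
    """0 inside the (slightly dilated) spine, ramping smoothly to 1 over
    ``blend_mm``.  Threshold-based spine masks already overshoot the true
    cortical surface by a voxel or so, hence the small default dilation."""
    if not spine.any():
        return np.ones(spine.shape, np.float64)
    it = int(round(dilate_mm / min(spacing)))
    grown = ndimage.binary_dilation(
        spine, ndimage.generate_binary_structure(3, 1),
        iterations=it) if it >= 1 else spine
    dist = ndimage.distance_transform_edt(~grown, sampling=spacing)
    t = np.clip(dist / blend_mm, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _zoom_field(u: np.ndarray, shape) -> np.ndarray:
    out = np.empty((3, *shape))
    for c in range(3):
        out[c] = ndimage.zoom(
            u[c], [shape[a] / u.shape[1 + a] for a in range(3)], order=1)
    return out


def _demons_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    u: np.ndarray,
    spacing,
    sim_mask: np.ndarray,
    rigidity: np.ndarray,
    iterations: int,
    smooth_sigma_mm: float,
    step: float,
    diagnostics: List[dict],
    level_tag: str,
) -> np.ndarray:
    """Greedy demons iterations at one resolution; only improving updates
    are kept, so the recorded similarity is non-increasing."""
    sigma_vox = [smooth_sigma_mm / s for s in spacing]
    grad_f = np.stack(np.gradient(fixed, *spacing))
    idx = np.indices(fixed.shape).astype(np.float64)

    def warp_with(uf):
        coords = [idx[a] + uf[a] / spacing[a] for a in range(3)]
        return ndimage.map_coordinates(moving, coords, order=1,
                                       mode="constant", cval=AIR_HU)

    def sim(uf):
        d = (warp_with(uf) - fixed)[sim_mask]
        return float(np.mean(d * d))

    cur = sim(u)
    # normalization constant of the demons force (mean squared spacing),
    # which bounds the per-iteration displacement to ~half a voxel
    k_norm = float(np.mean(np.asarray(spacing) ** 2))
    step0 = step
    for it in range(iterations):
        warped = warp_with(u)
        diff = fixed - warped
        # symmetric forces: average of fixed and warped-moving gradients
        grad = 0.5 * (grad_f + np.stack(np.gradient(warped, *spacing)))
        gnorm2 = np.sum(grad * grad, axis=0)
        denom = gnorm2 + (diff * diff) / k_norm
        force = np.where(denom > 1e-9, diff / np.maximum(denom, 1e-9), 0.0)
        base = force[None] * grad * sim_mask[None]
        smoothed = np.stack(
            [ndimage.gaussian_filter(base[c], sigma_vox) for c in range(3)])
        accepted = False
        for _ in range(8):  # backtracking line search on the step length
            cand = (u + step * smoothed) * rigidity[None]
            new = sim(cand)
            if new < cur - 1e-12:
                u, cur = cand, new
                accepted = True
                step = min(step * 1.3, 4.0 * step0)
                break
            step *= 0.5
        diagnostics.append(
            {"level": level_tag, "iteration": it, "similarity": cur,
             "accepted": accepted})
        if not accepted and step < 1e-2 * step0:
            break
    return u


def _affine_initialize(
    fixed: ImageVolume, moving: ImageVolume, mask: np.ndarray,
    factor: int = 4,
) -> np.ndarray:
    """Coarse affine (in-plane linear + translation + axial scale) fit by
    Powell search on the masked MSE; returns the full-resolution field."""
    fx = _downsample(fixed, factor)
    mv = _downsample(moving, factor)
    m = mask[::factor, ::factor, ::factor]
    if m.sum() < 8:
        return np.zeros((3, *fixed.grid.shape))
    spacing = np.asarray(fx.spacing)
    idx = np.indices(fx.grid.shape).astype(np.float64)
    pos = idx * spacing[:, None, None, None]
    center = np.array([pos[a][m].mean() for a in range(3)])
    rel = pos - center[:, None, None, None]
    mvox = mv.voxels.astype(np.float64)
    fvox = fx.voxels.astype(np.float64)

    def field(p, rel):
        dzz, dyy, dyx, dxy, dxx, tz, ty, tx = p
        uz = dzz * rel[0] + tz
        uy = dyy * rel[1] + dyx * rel[2] + ty
        ux = dxy * rel[1] + dxx * rel[2] + tx
        return np.stack([uz, uy, ux])

    def cost(p):
        u = field(p, rel)
        coords = [idx[a] + u[a] / spacing[a] for a in range(3)]
        w = ndimage.map_coordinates(mvox, coords, order=1,
                                    mode="constant", cval=AIR_HU)
        d = (w - fvox)[m]
        return float(np.mean(d * d))

    res = minimize(cost, np.zeros(8), method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 120})
    full_idx = np.indices(fixed.grid.shape).astype(np.float64)
    full_pos = full_idx * np.asarray(fixed.spacing)[:, None, None, None]
    return field(res.x, full_pos - center[:, None, None, None])


def deformable_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    spine: BinaryMask,
    lungs: Optional[BinaryMask] = None,
    abdominal: Optional[BinaryMask] = None,
    iterations: Tuple[int, ...] = (80, 50, 30, 25),
    factors: Tuple[int, ...] = (4, 2, 1, 1),
    smoothing_mm: Tuple[float, ...] = (64.0, 32.0, 16.0, 12.0),
    step: float = 1.8,
) -> RegistrationResult:
    """Two-stage rigidity-constrained demons registration.

    Stage 1 drives the whole-body similarity; stage 2 restricts the update
    force and similarity to the abdominal mask minus lungs (when provided),
    initialized with the stage-1 field.  The spine-rigidity projection zeroes
    the field inside the dilated spine mask after every iteration.
    """
    if moving.grid.shape != fixed.grid.shape:
        raise ValidationError("deformable_register: grid mismatch")
    spacing = np.asarray(fixed.spacing)
    body_mask = np.ones(fixed.grid.shape, bool)
    stage2_mask = None
    if abdominal is not None and abdominal.count():
        stage2_mask = abdominal.as_bool().copy()
        if lungs is not None:
            stage2_mask &= ~lungs.as_bool()

    diagnostics: List[dict] = []
    # affine initialization captures the bulk posture change (scale/shear +
    # shift); the demons then only refines local residuals.  The spine
    # rigidity projection is applied immediately so the start point honours
    # the constraint.
    # the affine fit is evaluated over the whole grid: background voxels
    # anchor the solution against self-similar degenerate fits of the
    # near-elliptical body (large shears that map the body onto itself)
    u_full = _affine_initialize(fixed, moving, body_mask)
    u_full *= _rigidity_blend(spine.as_bool(), fixed.spacing)[None]
    u = None
    # stage 1 runs the full pyramid; stage 2 is a full-resolution polish of
    # the abdominal region (re-running coarse levels with a restricted
    # similarity domain would distort the already-converged global field)
    schedules = {
        "body": list(zip(factors, iterations, smoothing_mm)),
        "abdomen": [lv for lv in zip(factors, iterations, smoothing_mm)
                    if lv[0] == 1][-1:],
    }
    for stage, mask in (("body", body_mask), ("abdomen", stage2_mask)):
        if mask is None:
            continue
        for factor, iters, sig_mm in schedules[stage]:
            fx = _downsample(fixed, factor)
            mv = _downsample(moving, factor)
            m = mask[::factor, ::factor, ::factor]
            sp = spine.as_bool()[::factor, ::factor, ::factor]
            rig = _rigidity_blend(sp, fx.spacing)
            if u is None:
                u = _zoom_field(u_full, fx.grid.shape)
            elif u.shape[1:] != fx.grid.shape:
                u = _zoom_field(u, fx.grid.shape)
            u = _demons_level(
                fx.voxels.astype(np.float64), mv.voxels.astype(np.float64),
                u, fx.spacing, m, rig, iters, sig_mm, step,
                diagnostics, f"{stage}/{factor}x/{sig_mm:g}mm")
    if u is None or not np.all(np.isfinite(u)):
        raise ConvergenceError("deformable_register produced a non-finite field")
    dvf = VectorField(u.astype(np.float32), fixed.spacing, fixed.origin)
    final = diagnostics[-1]["similarity"] if diagnostics else float("nan")
    return RegistrationResult(dvf, final, len(diagnostics), diagnostics)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(image: ImageVolume, new_spacing) -> ImageVolume:
    """Trilinear resampling onto a grid with the requested spacing covering
    the same world extent; world positions of content are preserved."""
    new_spacing = tuple(float(s) for s in new_spacing)
    if any(s <= 0 for s in new_spacing):
        raise ValidationError("resample: spacing must be positive")
    old = image.grid
    new_shape = tuple(
        max(2, int(round(old.shape[a] * old.spacing[a] / new_spacing[a])))
        for a in range(3))
    coords = np.indices(new_shape).astype(np.float64)
    for a in range(3):
        coords[a] = coords[a] * new_spacing[a] / old.spacing[a]
    out = ndimage.map_coordinates(
        image.voxels.astype(np.float64), coords, order=1,
        mode="nearest")
    return ImageVolume(out.astype(np.float32), new_spacing, image.origin)
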