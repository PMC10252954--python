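"""Image-quality and geometry metrics, plus a paired permutation test.

All distances are in world millimetres (voxel index differences scaled by
spacing); no centre-of-mass or other pre-alignment is ever applied before
overlap or surface-distance computation — the metrics measure the raw
setup difference between two scans.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import BinaryMask, ImageVolume, _check_same_grid
from .errors import ValidationError


@dataclass
class EvalReport:
    """Flat container mirroring the per-case evaluation output."""

    rassd_hu: float
    dsc: Dict[str, float] = field(default_factory=dict)
    hausdorff_mm: Dict[str, float] = field(default_factory=dict)
    gtv_volume_diff_cc: Optional[float] = None
    min_distance_mm: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rassd_hu": self.rassd_hu,
            "dsc": self.dsc,
            "hausdorff_mm": self.hausdorff_mm,
            "gtv_volume_diff_cc": self.gtv_volume_diff_cc,
            "min_distance_mm": self.min_distance_mm,
        }


def rassd(a: ImageVolume, b: ImageVolume, region: BinaryMask) -> float:
    """Root-averaged squared sum of differences: RMS HU difference over a
    region (conventionally the union of the two body masks)."""
    _check_same_grid(a.grid, b.grid, "rassd")
    _check_same_grid(a.grid, region.grid, "rassd region")
    sel = region.as_bool()
    if not sel.any():
        raise ValidationError("rassd: empty evaluation region")
    d = a.voxels[sel].astype(np.float64) - b.voxels[sel].astype(np.float64)
    return float(np.sqrt(np.mean(d * d)))


def dsc(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); both-empty -> 1."""
    _check_same_grid(a.grid, b.grid, "dsc")
    sa, sb = a.count(), b.count()
    if sa + sb == 0:
        return 1.0
    inter = int(np.sum(a.as_bool() & b.as_bool()))
    return 2.0 * inter / (sa + sb)


def _boundary_points_mm(mask: BinaryMask) -> np.ndarray:
    """World-mm coordinates of boundary voxels (6-connectivity erosion)."""
    m = mask.as_bool()
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surf = m & ~eroded
    idx = np.argwhere(surf)
    return idx * np.asarray(mask.spacing)[None, :] + np.asarray(mask.origin)[None, :]


def hausdorff(a: BinaryMask, b: BinaryMask, percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance between mask surfaces in mm.

    ``percentile=100`` (default) is the true maximum; pass 95 for HD95.
    """
    _check_same_grid(a.grid, b.grid, "hausdorff")
    if a.count() == 0 or b.count() == 0:
        raise ValidationError("hausdorff: empty mask")
    pa, pb = _boundary_points_mm(a), _boundary_points_mm(b)
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    if percentile >= 100.0:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile),
                     np.percentile(d_ba, percentile)))


def min_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Minimum world-mm distance between the two mask surfaces; 0 on overlap."""
    _check_same_grid(a.grid, b.grid, "min_surface_distance")
    if a.count() == 0 or b.count() == 0:
        raise ValidationError("min_surface_distance: empty mask")
    if np.any(a.as_bool() & b.as_bool()):
        return 0.0
    pa, pb = _boundary_points_mm(a), _boundary_points_mm(b)
    return float(cKDTree(pb).query(pa, k=1)[0].min())


def volume_cc(mask: BinaryMask) -> float:
    """Mask volume in cubic centimetres."""
    voxel_mm3 = float(np.prod(mask.spacing))
    return mask.count() * voxel_mm3 / 1000.0


def permutation_test(
    x, y, n_perm: int = 10_000, seed: int | None = 0
) -> float:
    """Two-sided paired permutation (sign-flip) test on the mean difference.

    Returns the add-one estimator p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm
    + 1), which is never exactly zero; reproducible under ``seed``.
    """
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("permutation_test: samples must be equal-length 1-D")
    if x.size < 2:
        raise ValidationError("permutation_test: need at least 2 pairs")
    d = x - y
    t_obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, d.size))
    t_perm = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(t_perm >= t_obs - 1e-15)) / (n_perm + 1))


def evaluate_case(
    a: ImageVolume,
    b: ImageVolume,
    structs_a,
    structs_b,
    region: Optional[BinaryMask] = None,
) -> EvalReport:
    """Full per-case report: RASSD over the body union (or ``region``),
    per-structure DSC/HD, GTV volume difference and GTV-to-OAR minimum
    surface distances where those structures exist."""
    if region is None:
        if "body" in structs_a and "body" in structs_b:
            union = structs_a["body"].as_bool() | structs_b["body"].as_bool()
            region = BinaryMask(union.astype(np.uint8), a.spacing, a.origin, "body_union")
        else:
            region = BinaryMask(np.ones(a.grid.shape, np.uint8), a.spacing,
                                a.origin, "grid")
    report = EvalReport(rassd_hu=rassd(a, b, region))
    for name in structs_a:
        if name not in structs_b:
            continue
        ma, mb = structs_a[name], structs_b[name]
        report.dsc[name] = dsc(ma, mb)
        if ma.count() and mb.count():
            report.hausdorff_mm[name] = hausdorff(ma, mb)
    if "gtv" in structs_a and "gtv" in structs_b:
        report.gtv_volume_diff_cc = volume_cc(structs_a["gtv"]) - volume_cc(
            structs_b["gtv"])
        for oar in ("duodenum", "stomach", "bowel"):
            if oar in structs_a and structs_a[oar].count() \
                    and structs_a["gtv"].count():
                report.min_distance_mm[f"gtv_{oar}"] = min_surface_distance(
                    structs_a["gtv"], structs_a[oar])
    return report
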