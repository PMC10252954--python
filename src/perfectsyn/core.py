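"""Geometric substrate: volumes, displacement fields, masks, warping.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``(z, y, x)`` = (depth/slice, row, column).
* ``z`` increases toward the feet (inferior), ``y`` increases toward the
  patient's back (posterior), ``x`` is left-right.
* World coordinates are ``origin + index * spacing`` in millimetres
  (axis-aligned grids; oblique direction matrices are out of scope).
* Deformation vector fields (DVFs) follow the *pull-back* convention: the
  warped image at voxel ``v`` samples the source image at world position
  ``pos(v) + u(v)``.  Displacements are stored in millimetres, component
  order ``(u_z, u_y, u_x)`` matching the array axes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Literal, Tuple

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, PlacementError, ValidationError

AIR_HU = -1000.0

Spacing = Tuple[float, float, float]
Origin = Tuple[float, float, float]


def _as_triple(v) -> Tuple[float, float, float]:
    t = tuple(float(c) for c in v)
    if len(t) != 3:
        raise ValidationError(f"expected a 3-vector, got {v!r}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class Grid:
    """Shape + spacing + origin of a voxel lattice."""

    shape: Tuple[int, int, int]
    spacing: Spacing
    origin: Origin

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))
        if any(s < 2 for s in self.shape):
            raise ValidationError(f"grid shape must be >= 2 per axis, got {self.shape}")
        if any(sp <= 0 for sp in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")

    def world_coordinates(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates as a sparse open mesh (mm)."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore

    def same_as(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


def _check_same_grid(a: Grid, b: Grid, what: str) -> None:
    if not a.same_as(b):
        raise GridMismatchError(
            f"{what}: grids differ (shape {a.shape} vs {b.shape}, "
            f"spacing {a.spacing} vs {b.spacing}, origin {a.origin} vs {b.origin})"
        )


@dataclass
class ImageVolume:
    """A 3-D scalar grid of Hounsfield units."""

    voxels: np.ndarray
    spacing: Spacing
    origin: Origin = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValidationError("ImageVolume requires a 3-D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("ImageVolume contains non-finite HU values")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        self.grid  # validates shape/spacing

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return ImageVolume(voxels, self.spacing, self.origin)


@dataclass
class VectorField:
    """Per-voxel displacement in mm; ``components[c]`` is u along axis c (z,y,x)."""

    components: np.ndarray  # (3, D, H, W)
    spacing: Spacing
    origin: Origin = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=np.float32)
        if self.components.ndim != 4 or self.components.shape[0] != 3:
            raise ValidationError(
                f"VectorField requires a (3, D, H, W) array, got {self.components.shape}"
            )
        if not np.all(np.isfinite(self.components)):
            raise ValidationError("VectorField contains non-finite displacements")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        self.grid

    @property
    def grid(self) -> Grid:
        return Grid(self.components.shape[1:], self.spacing, self.origin)

    @classmethod
    def zeros(cls, grid: Grid) -> "VectorField":
        return cls(np.zeros((3, *grid.shape), np.float32), grid.spacing, grid.origin)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.components.astype(np.float64) ** 2, axis=0))


@dataclass
class BinaryMask:
    """A named 0/1 labelmap sharing its parent volume's grid."""

    voxels: np.ndarray
    spacing: Spacing
    origin: Origin = (0.0, 0.0, 0.0)
    name: str = "mask"

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValidationError("BinaryMask requires a 3-D array")
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask {self.name!r} has non-binary values {uniq[:5]}")
        self.voxels = v.astype(np.uint8)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        self.grid

    @property
    def grid(self) -> Grid:
        return Grid(self.voxels.shape, self.spacing, self.origin)

    def count(self) -> int:
        return int(self.voxels.sum())

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


class StructureSet:
    """Mapping of structure name -> BinaryMask on one shared grid."""

    def __init__(self, masks: Dict[str, BinaryMask] | None = None):
        self._masks: Dict[str, BinaryMask] = {}
        if masks:
            for name, m in masks.items():
                self.add(name, m)

    def add(self, name: str, mask: BinaryMask) -> None:
        if name in self._masks:
            raise ValidationError(f"duplicate structure name {name!r}")
        if self._masks:
            _check_same_grid(next(iter(self._masks.values())).grid, mask.grid,
                             f"structure {name!r}")
        mask.name = name
        self._masks[name] = mask

    def __getitem__(self, name: str) -> BinaryMask:
        return self._masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def items(self):
        return self._masks.items()

    @property
    def grid(self) -> Grid:
        return next(iter(self._masks.values())).grid


@dataclass
class CouchModel:
    """Flat treatment-couch slab: a thin dense top over a lighter interior."""

    top_hu: float = 300.0
    interior_hu: float = -600.0
    thickness_mm: float = 24.0
    top_thickness_mm: float = 4.0
    width_mm: float = 500.0

    def __post_init__(self):
        if self.thickness_mm <= 0 or self.width_mm <= 0:
            raise ValidationError("couch thickness and width must be positive")
        if not (0 < self.top_thickness_mm <= self.thickness_mm):
            raise ValidationError("couch top thickness must be in (0, thickness]")


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def _dvf_to_index_coords(dvf: VectorField) -> np.ndarray:
    """Sampling coordinates (index units) implementing the pull-back warp."""
    shape = dvf.grid.shape
    coords = np.empty((3, *shape), dtype=np.float64)
    for a in range(3):
        idx = np.arange(shape[a], dtype=np.float64).reshape(
            [-1 if i == a else 1 for i in range(3)]
        )
        coords[a] = idx + dvf.components[a].astype(np.float64) / dvf.spacing[a]
    return coords


def warp_image(
    image: ImageVolume,
    dvf: VectorField,
    interpolation: Literal["trilinear", "nearest"] = "trilinear",
    fill_value: float = AIR_HU,
) -> ImageVolume:
    """Resample ``image`` through ``dvf`` (pull-back convention).

    The output voxel at index ``v`` takes the value of ``image`` at world
    position ``pos(v) + dvf(v)``.  Samples falling outside the input grid
    return ``fill_value`` (default −1000 HU, air).  Trilinear interpolation
    never creates intensities outside the input range, which is the whole
    point of synthesizing displacement fields instead of intensities: the
    HU calibration of the source scan survives untouched.
    """
    _check_same_grid(image.grid, dvf.grid, "warp_image")
    if interpolation not in ("trilinear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    coords = _dvf_to_index_coords(dvf)
    order = 1 if interpolation == "trilinear" else 0
    out = ndimage.map_coordinates(
        image.voxels.astype(np.float64), coords, order=order,
        mode="constant", cval=float(fill_value),
    )
    return ImageVolume(out.astype(np.float32), image.spacing, image.origin)


def warp_structures(structs: StructureSet, dvf: VectorField) -> StructureSet:
    """Warp every mask with nearest-neighbour interpolation, keeping names."""
    _check_same_grid(structs.grid, dvf.grid, "warp_structures")
    coords = _dvf_to_index_coords(dvf)
    out = StructureSet()
    for name, m in structs.items():
        w = ndimage.map_coordinates(m.voxels, coords, order=0,
                                    mode="constant", cval=0)
        out.add(name, BinaryMask(w, m.spacing, m.origin, name))
    return out


# ---------------------------------------------------------------------------
# curvature regularizer
# ---------------------------------------------------------------------------

def _laplacian(comp: np.ndarray, spacing: Spacing) -> np.ndarray:
    """Spacing-aware 7-point Laplacian on interior voxels (interior shape)."""
    core = comp[1:-1, 1:-1, 1:-1].astype(np.float64)
    lap = np.zeros_like(core)
    sl = [slice(1, -1)] * 3
    for a in range(3):
        lo = list(sl); lo[a] = slice(0, -2)
        hi = list(sl); hi[a] = slice(2, None)
        lap += (
            comp[tuple(hi)].astype(np.float64)
            - 2.0 * core
            + comp[tuple(lo)].astype(np.float64)
        ) / spacing[a] ** 2
    return lap


def curvature_energy(dvf: VectorField) -> float:
    """Second-order (curvature) smoothness energy of a displacement field.

    Sum over the three components of the mean, over interior voxels, of the
    squared discrete Laplacian.  Vanishes on any affine field; always >= 0.
    Normalizing by the interior voxel count makes values comparable across
    grid sizes.
    """
    shape = dvf.grid.shape
    if any(s < 3 for s in shape):
        raise ValidationError(
            f"curvature_energy needs >= 3 voxels per axis, got {shape}"
        )
    n_interior = int(np.prod([s - 2 for s in shape]))
    total = 0.0
    for c in range(3):
        lap = _laplacian(dvf.components[c], dvf.spacing)
        total += float(np.sum(lap * lap))
    return total / n_interior


# ---------------------------------------------------------------------------
# virtual couch
# ---------------------------------------------------------------------------

def add_virtual_couch(
    image: ImageVolume, body: BinaryMask, couch: CouchModel
) -> ImageVolume:
    """Insert a flat couch slab tangent to the most posterior body voxel.

    The slab's anterior (top) surface lies in the first voxel row posterior
    to the body; body voxels are never modified.  Raises
    :class:`PlacementError` when the slab does not fit inside the grid.
    """
    _check_same_grid(image.grid, body.grid, "add_virtual_couch")
    if body.count() == 0:
        raise ValidationError("body mask is empty")
    rows = np.nonzero(body.voxels.any(axis=(0, 2)))[0]
    r_post = int(rows.max())
    ny = image.voxels.shape[1]
    top = r_post + 1
    n_thick = max(1, int(round(couch.thickness_mm / image.spacing[1])))
    if top + n_thick > ny:
        raise PlacementError(
            "virtual couch does not fit posterior to the body "
            f"(needs rows {top}..{top + n_thick - 1}, grid has {ny})"
        )
    n_top = max(1, int(round(couch.top_thickness_mm / image.spacing[1])))
    # lateral extent, centred on the body's lateral midline
    cols = np.nonzero(body.voxels.any(axis=(0, 1)))[0]
    cx = 0.5 * (cols.min() + cols.max())
    half_w = 0.5 * couch.width_mm / image.spacing[2]
    x0 = max(0, int(np.ceil(cx - half_w)))
    x1 = min(image.voxels.shape[2], int(np.floor(cx + half_w)) + 1)
    out = image.voxels.copy()
    out[:, top: top + n_thick, x0:x1] = couch.interior_hu
    out[:, top: top + min(n_top, n_thick), x0:x1] = couch.top_hu
    if np.any(body.as_bool() & (np.abs(out - image.voxels) > 0)):
        raise PlacementError("couch slab would overwrite body voxels")
    return ImageVolume(out, image.spacing, image.origin)
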