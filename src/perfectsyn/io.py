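"""NIfTI / MetaImage readers and writers (SimpleITK-backed).

Array convention is ``(z, y, x)`` (depth, row, column); SimpleITK returns
arrays in the same order but reports spacing/origin as ``(x, y, z)``, so
those are reversed on the way in and out.  Only axis-aligned (identity
direction) grids are supported; displacement fields travel as 3-component
vector images with mm components stored ``(x, y, z)`` per the format
convention and reordered to match the array axes in memory.
"""
from __future__ import annotations

from pathlib import Path
from typing import Tuple, Union

import numpy as np
import SimpleITK as sitk

from .core import BinaryMask, ImageVolume, VectorField
from .errors import ValidationError

SUPPORTED = (".nii", ".nii.gz", ".mha", ".mhd")

PathLike = Union[str, Path]


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in SUPPORTED):
        raise ValidationError(
            f"unsupported extension for {path.name!r}; supported formats: "
            + ", ".join(SUPPORTED))


def _check_direction(img: sitk.Image, path: Path) -> None:
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(d, np.eye(3), atol=1e-6):
        raise ValidationError(
            f"{path.name}: oblique direction matrices are not supported")


def read_volume(path: PathLike) -> ImageVolume:
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValidationError(f"{path.name}: expected a scalar image")
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return ImageVolume(arr.astype(np.float32), spacing, origin)


def write_volume(vol: ImageVolume, path: PathLike) -> None:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(vol.voxels)
    img.SetSpacing(tuple(reversed(vol.spacing)))
    img.SetOrigin(tuple(reversed(vol.origin)))
    sitk.WriteImage(img, str(path))


def read_mask(path: PathLike, name: str = "mask") -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask((vol.voxels > 0.5).astype(np.uint8), vol.spacing,
                      vol.origin, name)


def write_mask(mask: BinaryMask, path: PathLike) -> None:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(mask.voxels.astype(np.uint8))
    img.SetSpacing(tuple(reversed(mask.spacing)))
    img.SetOrigin(tuple(reversed(mask.origin)))
    sitk.WriteImage(img, str(path))


def read_dvf(path: PathLike) -> VectorField:
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise ValidationError(
            f"{path.name}: displacement fields need exactly 3 components, "
            f"got {img.GetNumberOfComponentsPerPixel()}")
    _check_direction(img, path)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3) components (x, y, z)
    comps = np.stack([arr[..., 2], arr[..., 1], arr[..., 0]])
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return VectorField(comps.astype(np.float32), spacing, origin)


def write_dvf(field: VectorField, path: PathLike) -> None:
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.stack([field.components[2], field.components[1],
                    field.components[0]], axis=-1)
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(reversed(field.spacing)))
    img.SetOrigin(tuple(reversed(field.origin)))
    sitk.WriteImage(img, str(path))
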