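"""Network configurations, patch extraction/stitching, whole-volume inference.

Four generator configurations are supported, mirroring the study design:

* ``pix2pix3d_large`` — 3-D conditional GAN, 128^3 patches
* ``pix2pix3d_small`` — 3-D conditional GAN, 32^3 patches
* ``pix2pix25d``      — 2.5-D conditional GAN, 3 adjacent 128^2 slices in,
  the middle slice's 3-component displacement out
* ``unet3d``          — plain 3-D U-Net (no adversary), 128^3 patches

All emit a 3-channel displacement field at input resolution through a
linear head (displacements are signed, unbounded).  Patch sizes and widths
are configurable so the same architectures run at desk scale on CPU.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import BinaryMask, ImageVolume, VectorField
from .errors import ConfigError, CoverageError, ValidationError
from .nn import PatchDiscriminator, Tensor, UNet

GAN_VARIANTS = ("pix2pix3d_large", "pix2pix3d_small", "pix2pix25d")
VARIANTS = GAN_VARIANTS + ("unet3d",)

DEFAULT_PATCH = {
    "pix2pix3d_large": (128, 128, 128),
    "pix2pix3d_small": (32, 32, 32),
    "pix2pix25d": (3, 128, 128),
    "unet3d": (128, 128, 128),
}

HU_CLIP = 1000.0       # HU normalized to [-1, 1] over [-1000, 1000]
DVF_NORM_MM = 20.0     # displacement normalizer (the augmentation range)


@dataclass
class NetConfig:
    variant: str = "pix2pix3d_small"
    patch_shape: Optional[Tuple[int, int, int]] = None
    base_width: int = 8
    depth: int = 2
    leaky_slope: float = 0.01
    normalization: str = "batch"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.patch_shape is None:
            self.patch_shape = DEFAULT_PATCH[self.variant]
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        if not (0.0 < self.leaky_slope < 1.0):
            raise ConfigError("leaky-ReLU slope must be in (0, 1)")
        spatial = self.patch_shape[1:] if self.variant == "pix2pix25d" \
            else self.patch_shape
        if any(s % 2 ** self.depth for s in spatial):
            raise ConfigError(
                f"patch shape {self.patch_shape} not divisible by 2^depth")
        if self.variant == "pix2pix25d" and self.patch_shape[0] != 3:
            raise ConfigError("the 2.5-D variant takes exactly 3 slices")

    @property
    def is_gan(self) -> bool:
        return self.variant in GAN_VARIANTS

    @property
    def rank(self) -> int:
        return 2 if self.variant == "pix2pix25d" else 3


@dataclass
class PatchSpec:
    patch_shape: Tuple[int, int, int] = (32, 32, 32)
    stride: Optional[Tuple[int, int, int]] = None
    seed: int = 0

    def __post_init__(self):
        self.patch_shape = tuple(int(s) for s in self.patch_shape)
        if self.stride is None:
            self.stride = tuple(max(1, s // 2) for s in self.patch_shape)
        self.stride = tuple(int(s) for s in self.stride)
        if any(st > ps for st, ps in zip(self.stride, self.patch_shape)):
            raise ConfigError("stride must not exceed the patch shape")


def build_generator(cfg: NetConfig, seed: int = 0):
    rng = np.random.default_rng(seed)
    if cfg.variant == "pix2pix25d":
        return UNet(rank=2, c_in=3, c_out=3, base=cfg.base_width,
                    depth=cfg.depth, slope=cfg.leaky_slope, rng=rng)
    return UNet(rank=3, c_in=1, c_out=3, base=cfg.base_width,
                depth=cfg.depth, slope=cfg.leaky_slope, rng=rng)


def build_discriminator(cfg: NetConfig, seed: int = 0):
    if not cfg.is_gan:
        raise ConfigError("the plain U-Net variant has no adversary")
    rng = np.random.default_rng(seed + 1)
    c_in = 6 if cfg.variant == "pix2pix25d" else 4  # CT channels + 3 DVF
    return PatchDiscriminator(rank=cfg.rank, c_in=c_in, base=cfg.base_width,
                              slope=cfg.leaky_slope, rng=rng)


def normalize_hu(voxels: np.ndarray) -> np.ndarray:
    return np.clip(voxels, -HU_CLIP, HU_CLIP).astype(np.float32) / HU_CLIP


def normalize_dvf(components: np.ndarray) -> np.ndarray:
    return np.asarray(components, np.float32) / DVF_NORM_MM


def denormalize_dvf(components: np.ndarray) -> np.ndarray:
    return np.asarray(components, np.float32) * DVF_NORM_MM


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def extract_patches(
    volume: ImageVolume,
    dvf: VectorField,
    spec: PatchSpec,
    n: int,
    body: Optional[BinaryMask] = None,
    extras: Optional[dict] = None,
) -> List[dict]:
    """Sample ``n`` aligned (CT, DVF) patch pairs at random corners.

    Patch centres fall inside the body mask when one is provided.  Any
    ``extras`` arrays (same grid) are cropped identically.  Intensities and
    displacements are returned in normalized units; the patch corner is
    recorded for stitching.  Reproducible under ``spec.seed``.
    """
    shape = volume.grid.shape
    ps = spec.patch_shape
    if any(p > s for p, s in zip(ps, shape)):
        raise ValidationError(f"patch {ps} larger than volume {shape}")
    rng = np.random.default_rng(spec.seed)
    ct = normalize_hu(volume.voxels)
    df = normalize_dvf(dvf.components)
    if body is not None and body.count() > 0:
        centers = np.argwhere(body.as_bool())
    else:
        centers = None
    out = []
    max_corner = [s - p for s, p in zip(shape, ps)]
    tries = 0
    while len(out) < n:
        tries += 1
        if centers is not None and tries <= 20 * n:
            c = centers[rng.integers(len(centers))]
            corner = [int(np.clip(c[a] - ps[a] // 2, 0, max_corner[a]))
                      for a in range(3)]
        else:
            corner = [int(rng.integers(0, m + 1)) for m in max_corner]
        sl = tuple(slice(corner[a], corner[a] + ps[a]) for a in range(3))
        item = {
            "corner": tuple(corner),
            "ct": ct[sl][None],                       # (1, *patch)
            "dvf": df[(slice(None),) + sl],           # (3, *patch)
        }
        if extras:
            for k, arr in extras.items():
                item[k] = np.asarray(arr)[sl][None]
        out.append(item)
    return out


def _tent_weights(shape: Sequence[int]) -> np.ndarray:
    ws = []
    for s in shape:
        t = 1.0 - np.abs(2.0 * np.arange(s) / max(s - 1, 1) - 1.0)
        ws.append(t * (1.0 - 1e-3) + 1e-3)  # strictly positive at edges
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    return w.astype(np.float64)


def stitch_patches(
    patches: List[Tuple[np.ndarray, Tuple[int, int, int]]],
    grid_shape: Tuple[int, int, int],
    spacing,
    origin=(0.0, 0.0, 0.0),
) -> VectorField:
    """Blend overlapping (3, *patch) displacement patches into a full field
    with separable tent weights, normalized to one at every voxel."""
    acc = np.zeros((3, *grid_shape), np.float64)
    wacc = np.zeros(grid_shape, np.float64)
    for arr, corner in patches:
        arr = np.asarray(arr)
        psh = arr.shape[1:]
        w = _tent_weights(psh)
        sl = tuple(slice(corner[a], corner[a] + psh[a]) for a in range(3))
        acc[(slice(None),) + sl] += arr * w[None]
        wacc[sl] += w
    if np.any(wacc == 0.0):
        raise CoverageError("stitch_patches: some voxels are not covered")
    return VectorField((acc / wacc[None]).astype(np.float32), spacing, origin)


def _tile_corners(shape, patch, stride):
    out = []
    for a in range(3):
        stops = list(range(0, shape[a] - patch[a] + 1, stride[a]))
        if stops[-1] != shape[a] - patch[a]:
            stops.append(shape[a] - patch[a])
        out.append(stops)
    return [(z, y, x) for z in out[0] for y in out[1] for x in out[2]]


def predict_dvf(
    generator,
    cfg: NetConfig,
    dct: ImageVolume,
    spec: Optional[PatchSpec] = None,
) -> VectorField:
    """Whole-volume displacement prediction: tile, run the generator in
    eval mode, blend the overlapping patch outputs, convert to mm."""
    if float(np.abs(dct.voxels).max()) > 4000.0:
        raise ValidationError(
            "input HU range looks unnormalized/implausible; expected a "
            "preprocessed CT in [-1000, ~2000] HU")
    spec = spec or PatchSpec(patch_shape=cfg.patch_shape)
    shape = dct.grid.shape
    ct = normalize_hu(dct.voxels)
    generator.eval()
    patches = []
    if cfg.variant == "pix2pix25d":
        # slide over axial slices: 3 neighbouring slices as channels
        ph, pw = spec.patch_shape[1:]
        if ph > shape[1] or pw > shape[2]:
            raise ValidationError("patch larger than volume")
        corners2d = _tile_corners((1, shape[1], shape[2]),
                                  (1, ph, pw), (1,) + tuple(spec.stride[1:]))
        for z in range(shape[0]):
            zs = [min(max(z + dz, 0), shape[0] - 1) for dz in (-1, 0, 1)]
            for _, y, x in corners2d:
                inp = ct[zs, y:y + ph, x:x + pw][None]  # (1, 3, ph, pw)
                pred = generator(Tensor(inp)).data[0]   # (3, ph, pw)
                patches.append((pred[:, None], (z, y, x)))
    else:
        ps = spec.patch_shape
        if any(p > s for p, s in zip(ps, shape)):
            raise ValidationError("patch larger than volume")
        for corner in _tile_corners(shape, ps, spec.stride):
            sl = tuple(slice(corner[a], corner[a] + ps[a]) for a in range(3))
            pred = generator(Tensor(ct[sl][None, None])).data[0]
            patches.append((pred, corner))
    field = stitch_patches(patches, shape, dct.spacing, dct.origin)
    return VectorField(denormalize_dvf(field.components), dct.spacing,
                       dct.origin)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, generator, cfg: NetConfig,
                    discriminator=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = {f"g.{k}": v for k, v in generator.named_state().items()}
    if discriminator is not None:
        state.update(
            {f"d.{k}": v for k, v in discriminator.named_state().items()})
    np.savez(path, **state)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)


def load_checkpoint(path):
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        cfg = NetConfig(**json.load(fh))
    state = dict(np.load(path if path.suffix == ".npz"
                         else path.with_suffix(".npz")))
    gen = build_generator(cfg)
    gen.load_state({k[2:]: v for k, v in state.items()
                    if k.startswith("g.")})
    disc = None
    if any(k.startswith("d.") for k in state):
        disc = build_discriminator(cfg)
        disc.load_state({k[2:]: v for k, v in state.items()
                         if k.startswith("d.")})
    return gen, cfg, disc
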