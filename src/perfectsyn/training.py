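"""Composite loss, rigid augmentation, optimization schedule, training loop.

The training objective is a weighted sum of four terms:

    loss = l1 * L_adv + l2 * L1(DVF) + l3 * L1(image) + l4 * R_smooth

* ``L_adv``  — conditional adversarial loss (GAN variants only); the
  discriminator maximizes E[log D(x, y)] + E[log(1 - D(x, G(x)))], the
  generator minimizes the non-saturating form -E[log D(x, G(x))].
* ``L1(DVF)``   — mean absolute difference between predicted and target
  displacement fields (normalized units).
* ``L1(image)`` — mean absolute intensity difference between the target
  scan and the source scan warped in place by the predicted field,
  restricted to the abdominal mask (normalized intensities).
* ``R_smooth``  — second-order curvature penalty of the predicted field.

Optimization uses Adam with the study schedule: starting learning rate
0.01 decayed exponentially by 0.97 after every epoch, beta1 = 0.5,
beta2 = 0.9, eps = 1e-8, 150 epochs at full scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ImageVolume, StructureSet, VectorField
from .errors import ConfigError, GridMismatchError, ValidationError
from .model import (
    NetConfig,
    PatchSpec,
    build_discriminator,
    build_generator,
    extract_patches,
    normalize_hu,
    save_checkpoint,
    DVF_NORM_MM,
)
from .nn import (
    Adam,
    Tensor,
    bce_discriminator,
    bce_generator,
    curvature_penalty,
    l1_loss,
    warp_l1_loss,
)
from .phantom import PhantomPair


@dataclass
class LossWeights:
    """Weights (l1..l4) of the adversarial, DVF-L1, image-L1 and curvature
    terms.  The plain U-Net variant has no adversary: l1 must be 0."""

    adversarial: float = 1.0
    dvf_l1: float = 100.0
    image_l1: float = 10.0
    curvature: float = 0.1

    def __post_init__(self):
        vals = (self.adversarial, self.dvf_l1, self.image_l1, self.curvature)
        if any(v < 0 for v in vals):
            raise ConfigError("loss weights must be non-negative")
        if not any(v > 0 for v in vals):
            raise ConfigError("at least one loss weight must be positive")


#: per-variant defaults: GAN variants use the full composite objective,
#: the U-Net baseline is DVF regression + smoothness only.  The GAN
#: weights were selected by validation experiments on held-out phantoms
#: (the image term needs weight comparable to the DVF term because its
#: raw magnitude is several times smaller)
PRESET_WEIGHTS = {
    "pix2pix3d_large": LossWeights(0.3, 100.0, 30.0, 0.1),
    "pix2pix3d_small": LossWeights(0.3, 100.0, 30.0, 0.1),
    "pix2pix25d": LossWeights(0.3, 100.0, 30.0, 0.1),
    "unet3d": LossWeights(0.0, 100.0, 0.0, 0.1),
}


@dataclass
class TrainConfig:
    epochs: int = 150
    lr: float = 0.01
    lr_decay: float = 0.97
    betas: Tuple[float, float] = (0.5, 0.9)
    eps: float = 1e-8
    batch_size: int = 2
    steps_per_epoch: int = 30
    patches_per_step: Optional[int] = None  # defaults to batch_size
    shift_mm: float = 20.0
    rotation_deg: float = 10.0
    augment_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigError("learning rate must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ConfigError("decay must be in (0, 1]")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


def lr_schedule(cfg: TrainConfig, epoch: int) -> float:
    """lr(k) = lr0 * decay^k, updated after each epoch."""
    if epoch < 0:
        raise ValidationError("epoch index must be >= 0")
    return cfg.lr * cfg.lr_decay ** epoch


# ---------------------------------------------------------------------------
# loss components (array API; the trainer uses the autodiff twins)
# ---------------------------------------------------------------------------

def loss_adversarial(d_real, d_fake) -> Tuple[float, float]:
    """(discriminator loss, non-saturating generator loss) from score
    arrays in (0, 1); scores are clamped away from {0, 1}."""
    r = np.clip(np.asarray(d_real, np.float64), 1e-7, 1 - 1e-7)
    f = np.clip(np.asarray(d_fake, np.float64), 1e-7, 1 - 1e-7)
    d_loss = -(np.mean(np.log(r)) + np.mean(np.log(1.0 - f)))
    g_loss = -np.mean(np.log(f))
    return float(d_loss), float(g_loss)


def loss_dvf_l1(pred: VectorField, target: VectorField) -> float:
    """Mean absolute displacement difference over all voxels/components."""
    if pred.grid.shape != target.grid.shape:
        raise GridMismatchError("loss_dvf_l1: grid mismatch")
    return float(np.mean(np.abs(pred.components - target.components)))


def loss_image_l1(warped: ImageVolume, target: ImageVolume,
                  abdominal: BinaryMask) -> float:
    """Mean absolute intensity difference over the abdominal mask, on the
    [-1000, 1000] HU -> [-1, 1] normalized scale."""
    if warped.grid.shape != target.grid.shape:
        raise GridMismatchError("loss_image_l1: grid mismatch")
    sel = abdominal.as_bool()
    if not sel.any():
        raise ValidationError("loss_image_l1: empty mask")
    a = normalize_hu(warped.voxels)[sel].astype(np.float64)
    b = normalize_hu(target.voxels)[sel].astype(np.float64)
    return float(np.mean(np.abs(a - b)))


def total_loss(w: LossWeights, g_adv: float, l_dvf: float, l_img: float,
               r_smooth: float) -> float:
    return (w.adversarial * g_adv + w.dvf_l1 * l_dvf
            + w.image_l1 * l_img + w.curvature * r_smooth)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def draw_augmentation(rng: np.random.Generator, shift_mm: float = 20.0,
                      rotation_deg: float = 10.0):
    """One (shift, z-rotation) draw, uniform in the closed ranges."""
    t = rng.uniform(-shift_mm, shift_mm, 3)
    theta = float(rng.uniform(-rotation_deg, rotation_deg))
    return t, theta


def _pad_amount(spacing, shift_mm, theta_deg, extent_mm):
    sweep = np.deg2rad(abs(theta_deg)) * 0.5 * max(extent_mm)
    pads = []
    for a in range(3):
        mm = abs(shift_mm[a]) + (sweep if a > 0 else 0.0)
        pads.append(int(np.ceil(mm / spacing[a])) + 1)
    return pads


def _rigid_coords(shape, spacing, theta_deg, t_mm, center_mm):
    th = np.deg2rad(theta_deg)
    grids = [np.arange(n) * s for n, s in zip(shape, spacing)]
    Z, Y, X = np.meshgrid(*grids, indexing="ij")
    cz, cy, cx = center_mm
    Yr = cy + np.cos(th) * (Y - cy) - np.sin(th) * (X - cx)
    Xr = cx + np.sin(th) * (Y - cy) + np.cos(th) * (X - cx)
    return [(Z + t_mm[0]) / spacing[0],
            (Yr + t_mm[1]) / spacing[1],
            (Xr + t_mm[2]) / spacing[2]], th


def augment(pair: PhantomPair, seed: int, shift_mm: float = 20.0,
            rotation_deg: float = 10.0) -> PhantomPair:
    """Apply one random rigid transform (3-D shift + z-rotation) jointly to
    both scans, all masks and — covariantly — the target displacement field.

    The canvas is padded first so body voxels are never cropped, whatever
    the draw.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    t, theta = draw_augmentation(rng, shift_mm, rotation_deg)

    spacing = pair.dct.spacing
    extent = [n * s for n, s in zip(pair.dct.grid.shape, spacing)]
    pads = _pad_amount(spacing, t, theta, extent)
    pad_width = [(p, p) for p in pads]

    def pad_img(v, cval):
        return np.pad(v.astype(np.float64), pad_width, constant_values=cval)

    shape_p = tuple(s + 2 * p for s, p in zip(pair.dct.grid.shape, pads))
    center = tuple(0.5 * (n - 1) * s for n, s in zip(shape_p, spacing))
    coords, th = _rigid_coords(shape_p, spacing, theta, t, center)

    def warp_scalar(vox, cval, order=1):
        return ndimage.map_coordinates(pad_img(vox, cval), coords,
                                       order=order, mode="constant",
                                       cval=cval).astype(np.float32)

    dct = ImageVolume(warp_scalar(pair.dct.voxels, -1000.0), spacing)
    pct = ImageVolume(warp_scalar(pair.pct.voxels, -1000.0), spacing)

    # covariant field: u'(x) = R^-1 u(g(x)) with g the sampling map above
    comps = [warp_scalar(pair.gt_dvf.components[c], 0.0) for c in range(3)]
    uz = comps[0]
    uy = np.cos(th) * comps[1] + np.sin(th) * comps[2]
    ux = -np.sin(th) * comps[1] + np.cos(th) * comps[2]
    dvf = VectorField(np.stack([uz, uy, ux]), spacing)

    def warp_structs(structs: StructureSet) -> StructureSet:
        out = StructureSet()
        for name, m in structs.items():
            w = warp_scalar(m.voxels.astype(np.float64), 0.0, order=0)
            out.add(name, BinaryMask(np.round(w).astype(np.uint8), spacing))
        return out

    sd = warp_structs(pair.structs_d)
    # guard the contract: the padded canvas must fully contain the body
    # (nearest-neighbour resampling may still shuffle a few boundary voxels)
    wb = sd["body"].as_bool()
    touches = (wb[0].any() or wb[-1].any() or wb[:, 0].any()
               or wb[:, -1].any() or wb[:, :, 0].any() or wb[:, :, -1].any())
    if touches or sd["body"].count() < pair.structs_d["body"].count() * 0.98:
        raise ValidationError("augmentation cropped body voxels")
    return PhantomPair(dct, pct, dvf, sd, warp_structs(pair.structs_p),
                       pair.spec)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _prepare_items(pairs: Sequence[PhantomPair]) -> List[dict]:
    items = []
    for p in pairs:
        items.append({
            "pair": p,
            "extras": {
                "pct": normalize_hu(p.pct.voxels),
                "abdomen": p.structs_d["abdomen"].voxels.astype(np.float32),
            },
        })
    return items


def train(
    cfg: TrainConfig,
    net: NetConfig,
    weights: LossWeights,
    dataset: Sequence[PhantomPair],
    out_dir: Optional[str] = None,
    checkpoint_every: int = 0,
):
    """Fit a generator (and, for GAN variants, a discriminator) on phantom
    or preprocessed pairs.  Returns ``(generator, history)`` where history
    is one dict per step with every loss component.

    Alternating updates (1:1) for GAN variants; generator-only otherwise.
    Aborts on non-finite loss, writing a diagnostic checkpoint when an
    output directory is given.
    """
    if net.variant == "unet3d" and weights.adversarial != 0.0:
        raise ConfigError("unet3d takes no adversarial term (l1 must be 0)")
    if net.variant == "pix2pix25d":
        raise ConfigError(
            "the 2.5-D variant is supported for inference experiments but "
            "not by this volumetric patch trainer")
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(net, seed=cfg.seed)
    disc = build_discriminator(net, seed=cfg.seed) if (
        net.is_gan and weights.adversarial > 0) else None
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas, eps=cfg.eps)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas,
                 eps=cfg.eps) if disc is not None else None

    items = _prepare_items(dataset)
    spacing = dataset[0].dct.spacing
    scale_vox = np.array([DVF_NORM_MM / s for s in spacing])
    history: List[dict] = []
    out_path = Path(out_dir) if out_dir else None

    for epoch in range(cfg.epochs):
        lr = lr_schedule(cfg, epoch)
        opt_g.lr = lr
        if opt_d is not None:
            opt_d.lr = lr
        for step in range(cfg.steps_per_epoch):
            batch = []
            for _ in range(cfg.batch_size):
                item = items[rng.integers(len(items))]
                pair = item["pair"]
                extras = item["extras"]
                if rng.random() < cfg.augment_prob:
                    aug = augment(pair, int(rng.integers(2 ** 31 - 1)),
                                  cfg.shift_mm, cfg.rotation_deg)
                    extras = {
                        "pct": normalize_hu(aug.pct.voxels),
                        "abdomen":
                            aug.structs_d["abdomen"].voxels.astype(np.float32),
                    }
                    pair = aug
                pspec = PatchSpec(net.patch_shape,
                                  seed=int(rng.integers(2 ** 31 - 1)))
                batch.extend(extract_patches(
                    pair.dct, pair.gt_dvf, pspec, 1,
                    body=pair.structs_d["body"], extras=extras))
            x = np.stack([b["ct"] for b in batch])
            y = np.stack([b["dvf"] for b in batch])
            pct = np.stack([b["pct"] for b in batch])
            abd = np.stack([b["abdomen"] for b in batch])

            # ---- generator update
            gen.train()
            xt = Tensor(x)
            pred = gen(xt)
            l_dvf_t = l1_loss(pred, y)
            r_smooth_t = curvature_penalty(pred)
            loss_t = weights.dvf_l1 * l_dvf_t + weights.curvature * r_smooth_t
            l_img_v = 0.0
            if weights.image_l1 > 0 and abd.sum() > 0:
                l_img_t = warp_l1_loss(pred, x, pct, abd, scale_vox)
                loss_t = loss_t + weights.image_l1 * l_img_t
                l_img_v = l_img_t.item()
            g_adv_v = 0.0
            if disc is not None:
                disc.train()
                scores_fake = disc(xt, pred)
                g_adv_t = bce_generator(scores_fake)
                loss_t = loss_t + weights.adversarial * g_adv_t
                g_adv_v = g_adv_t.item()
            gen.zero_grad()
            if disc is not None:
                disc.zero_grad()
            loss_t.backward()
            opt_g.step()

            # ---- discriminator update
            d_loss_v = float("nan")
            if disc is not None:
                sf = disc(Tensor(x), Tensor(pred.data))
                sr = disc(Tensor(x), Tensor(y))
                d_loss_t = bce_discriminator(sr, sf)
                disc.zero_grad()
                d_loss_t.backward()
                opt_d.step()
                d_loss_v = d_loss_t.item()

            row = {
                "epoch": epoch, "step": step, "lr": lr,
                "g_total": loss_t.item(), "l_dvf": l_dvf_t.item(),
                "l_img": l_img_v, "g_adv": g_adv_v,
                "r_smooth": r_smooth_t.item(), "d_loss": d_loss_v,
            }
            history.append(row)
            if not np.isfinite(row["g_total"]):
                if out_path:
                    save_checkpoint(out_path / "diverged.npz", gen, net, disc)
                raise ArithmeticError(
                    f"non-finite loss at epoch {epoch} step {step}")
        if out_path and checkpoint_every and (epoch + 1) % checkpoint_every == 0:
            save_checkpoint(out_path / f"epoch_{epoch + 1:04d}.npz",
                            gen, net, disc)
    if out_path:
        save_checkpoint(out_path / "final.npz", gen, net, disc)
    return gen, history
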