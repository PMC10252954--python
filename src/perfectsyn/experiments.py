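"""Desk-scale end-to-end synthesis study on phantom populations.

Simulates a training and a held-out test population, trains the plain
U-Net preset and the 3-D conditional-GAN preset at CPU scale, synthesizes
planning CTs for the test phantoms and measures body-contour overlap and
RMS intensity agreement against the known planning scans.  Used both by
the acceptance harness and the reproduction script.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .core import BinaryMask, ImageVolume, warp_image
from .evaluation import dsc, rassd, volume_cc
from .model import NetConfig, PatchSpec, predict_dvf
from .phantom import PhantomPair, PhantomSpec, sample_population
from .preprocess import (
    abdominal_mask,
    deformable_register,
    remove_couch,
    segment_lungs,
    segment_spine,
)
from .training import LossWeights, PRESET_WEIGHTS, TrainConfig, train

#: phantom grid used for the desk-scale study (a slightly smaller habitus
#: so the full population amplitude range fits the 48^3 field of view)
STUDY_SPEC = PhantomSpec(shape=(48, 48, 48), spacing=(4.0, 5.0, 5.0),
                         body_semiaxis_x=72.0, body_semiaxis_y=56.0,
                         body_center_y=112.0)

#: CPU-scale network presets: canonical architectures at reduced patch/width
STUDY_NETS = {
    "pix2pix3d_small": NetConfig("pix2pix3d_small", patch_shape=(20, 20, 20),
                                 base_width=8, depth=2),
    "unet3d": NetConfig("unet3d", patch_shape=(20, 20, 20), base_width=8,
                        depth=2),
}


@dataclass
class StudyResult:
    body_dsc_dct_pct: float
    body_dsc_sct_pct: Dict[str, float]
    rassd_sct_pct: Dict[str, float]
    rassd_dct_pct: float
    gtv_volume_diff_cc: Dict[str, float]
    per_case: Dict[str, List[dict]] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)


def _body_from_mask_warp(pair: PhantomPair, dvf) -> np.ndarray:
    fm = ImageVolume(pair.structs_d["body"].voxels.astype(np.float32),
                     pair.dct.spacing)
    return warp_image(fm, dvf, fill_value=0.0).voxels >= 0.5


def _mask(arr, spacing) -> BinaryMask:
    return BinaryMask(np.asarray(arr, np.uint8), spacing)


def _prepare_training_pair(pair: PhantomPair, targets: str) -> PhantomPair:
    """Couch-removed input + target field, mirroring the clinical chain:
    targets come from the rigidity-constrained deformable registration
    (``registered``, the default pipeline) or from the analytic truth
    (``ground_truth``)."""
    d_clean, _ = remove_couch(pair.dct)
    p_clean, p_body = remove_couch(pair.pct)
    if targets == "ground_truth":
        dvf = pair.gt_dvf
    else:
        spine = segment_spine(p_clean, p_body)
        lungs = segment_lungs(p_clean, p_body)
        abd = abdominal_mask(p_body, lungs)
        dvf = deformable_register(d_clean, p_clean, spine, lungs, abd).dvf
    return PhantomPair(d_clean, p_clean, dvf, pair.structs_d,
                       pair.structs_p, pair.spec)


def run_synthesis_study(
    seed: int = 1,
    n_train: int = 60,
    n_test: int = 20,
    epochs: int = 20,
    steps_per_epoch: int = 15,
    variants=("pix2pix3d_small", "unet3d"),
    base_spec: Optional[PhantomSpec] = None,
    targets: str = "registered",
) -> StudyResult:
    base = base_spec or STUDY_SPEC
    t0 = time.time()
    train_pop = sample_population(n_train, base_spec=base, seed=seed)
    test_pop = sample_population(n_test, base_spec=base, seed=seed + 10_000)
    t_sim = time.time() - t0
    t0 = time.time()
    train_pop = [_prepare_training_pair(p, targets) for p in train_pop]
    t_prep = time.time() - t0

    sp = base.spacing
    dsc_dp, rassd_dp = [], []
    for p in test_pop:
        dsc_dp.append(dsc(p.structs_d["body"], p.structs_p["body"]))
        union = p.structs_d["body"].as_bool() | p.structs_p["body"].as_bool()
        rassd_dp.append(rassd(p.dct, p.pct, _mask(union, sp)))

    result = StudyResult(
        body_dsc_dct_pct=float(np.mean(dsc_dp)),
        body_dsc_sct_pct={},
        rassd_sct_pct={},
        rassd_dct_pct=float(np.mean(rassd_dp)),
        gtv_volume_diff_cc={},
        timings={"simulate_s": t_sim, "prepare_s": t_prep},
    )

    for vi, variant in enumerate(variants):
        net = STUDY_NETS[variant]
        weights = PRESET_WEIGHTS[variant]
        cfg = TrainConfig(epochs=epochs, steps_per_epoch=steps_per_epoch,
                          batch_size=2, augment_prob=0.3,
                          seed=seed + 100 * vi)
        t0 = time.time()
        gen, history = train(cfg, net, weights, train_pop)
        result.timings[f"train_{variant}_s"] = time.time() - t0

        pspec = PatchSpec(net.patch_shape, stride=(14, 14, 14))
        rows = []
        t0 = time.time()
        for p in test_pop:
            d_clean, _ = remove_couch(p.dct)
            dvf = predict_dvf(gen, net, d_clean, pspec)
            sct = warp_image(d_clean, dvf)
            sbody = _body_from_mask_warp(p, dvf)
            pbody = p.structs_p["body"]
            union = sbody | pbody.as_bool()
            gtv_f = ImageVolume(p.structs_d["gtv"].voxels.astype(np.float32),
                                sp)
            gtv_s = warp_image(gtv_f, dvf, fill_value=0.0).voxels >= 0.5
            rows.append({
                "dsc_body": dsc(_mask(sbody, sp), pbody),
                "rassd": rassd(sct, p.pct, _mask(union, sp)),
                "gtv_diff_cc": abs(volume_cc(_mask(gtv_s, sp))
                                   - volume_cc(p.structs_p["gtv"])),
            })
        result.timings[f"infer_{variant}_s"] = time.time() - t0
        result.per_case[variant] = rows
        result.body_dsc_sct_pct[variant] = float(
            np.mean([r["dsc_body"] for r in rows]))
        result.rassd_sct_pct[variant] = float(
            np.mean([r["rassd"] for r in rows]))
        result.gtv_volume_diff_cc[variant] = float(
            np.mean([r["gtv_diff_cc"] for r in rows]))
    return result
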