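# Methods

`perfectsyn` synthesizes a treatment-setup ("planning") CT from a
diagnostic CT by predicting a dense deformation vector field (DVF) with a
conditional adversarial network and resampling the diagnostic scan through
it. Because only geometry is synthesized — never intensity — the HU
calibration of the source scan is preserved, which is the property that
makes the synthesized scan usable for dose calculation. This note records
the model, the numerical choices, and what the synthetic test bed does and
does not demonstrate.

## Geometry and conventions

Arrays are indexed `(z, y, x)`; `z` grows toward the feet, `y` toward the
patient's back (posterior), world position is `origin + index * spacing`
in mm (axis-aligned grids only). Displacement fields follow the
*pull-back* convention: the warped image at voxel `v` samples the source
at `pos(v) + u(v)`. Pull-back avoids holes and fold artifacts in the
output and is the standard convention for intensity resampling. Units of
`u` are millimetres, component order `(u_z, u_y, u_x)`. Out-of-field
samples return −1000 HU (air), physically neutral for body-site CT.
Trilinear resampling never produces intensities outside the input range,
so the HU-conservation claim holds at the resampling level exactly.

The curvature regularizer is the mean over interior voxels (sum over the
three components) of the squared 7-point spacing-aware discrete Laplacian.
It vanishes on affine fields, and the mean (rather than sum) normalization
makes values comparable across grid resolutions. The continuous form in
the registration literature leaves the discretization open; these are our
choices.

## Digital phantom pairs

No public paired diagnostic/planning abdominal CT exists, so all
quantitative checks run on digital phantoms that emulate the systematic
differences between the two acquisitions:

* **Couch sag** — the diagnostic scan's curved couch top indents the
  posterior body surface (default 24 mm at centre, population range
  18–30 mm); the planning scan has a flat back. The diagnostic scan also
  contains a curved couch object, rendered with an air gap below the body
  (clinically provided by gowns/padding and partial volume) so
  connected-component couch removal is well posed.
* **Breath-hold** — the planning-scan abdomen is expanded
  anteriorly/laterally (default 10 mm, range 7–13 mm) with a radial field
  attenuated at the spine, and the cross-section is reshaped by an
  area-preserving lateral stretch / AP thinning coupled to the amplitude
  (`1 + 0.034 × amplitude`). The area-preserving term is the main contour
  lever; because its Jacobian is 1 it deforms without compressing tissue.
  A mild inferior organ shift (25 % of the amplitude) emulates the lowered
  diaphragm.
* **Rigid spine** — a vertebral-column stand-in (cylinder + spinous and
  transverse processes, vertebra/disk HU banding along `z`) on which the
  ground-truth field is exactly zero; the field ramps in smoothly over
  ~12 mm outside an 8 mm margin. The processes and banding are what make
  axial rotation and `z` translation observable to intensity-based
  registration — a plain cylinder would be a rotational null space.
* **Quasi-rigid tumour** — the compressive field terms are frozen to
  their value at the tumour (fixed-point anchored in the deformed frame),
  so tumour volume is conserved by construction; the volume-preserving
  stretch is exempt. The blend shell is wide (60 mm) and the amplitudes
  moderate so the composite map stays fold-free; folding is what breaks
  the correspondence between warped masks and analytic pre-images.
* **Tissue classes and texture** — air/lung/fat/soft/bone/couch HU plus
  ~45 smooth HU bumps (vessels, bowel content) that deform with the
  anatomy, and independent additive Gaussian noise (12 HU) per scan.
  The texture gives intensity-based registration and the image-loss
  gradient information away from organ boundaries, as real parenchyma
  does.

The planning image is rendered by evaluating the diagnostic anatomy at
analytically displaced points, so `warp(dct, gt_dvf) ≈ pct` holds by
construction (verified at planning resolution to body-contour Dice
≥ 0.99). Population defaults are calibrated once so that the mean
diagnostic-vs-planning body Dice over 50 phantoms falls in the 0.55–0.80
band reported for clinical pairs of these two acquisitions; the defaults
were then frozen.

What the phantoms do *not* model: realistic organ texture, sliding
interfaces, contrast agents, breathing phases, weight change between
scans, metal artifacts, or truncated fields of view. Passing tests on
phantoms therefore demonstrates the correctness and internal consistency
of the pipeline, not clinical-grade accuracy.

## Preprocessing chain

1. **Couch removal** — body = largest connected component of HU > −300
   after closing, holes filled; everything else set to air. Thresholds
   (−300 body, 200 bone, −400 lung) are conventional CT values, all
   configurable.
2. **Spine segmentation** — seed = largest bony component in the
   posterior third of the body box (widened to the posterior half if the
   sagged surface stretches the box past the spine); the full connected
   bone component containing the seed is returned.
3. **Rigid spine alignment** — z-rotation + 3-D translation minimizing
   the masked MSE in the dilated spine ROI, Powell search at two
   resolutions. Both images are pre-smoothed identically (σ = 1.5 voxels)
   because one-sided interpolation blur at sharp bone edges otherwise
   biases the rotation optimum by ~1°; an exhaustive coarse translation
   search (±20 mm, 4 mm steps) guards against vertebra-periodicity
   aliasing. The ROI's axial ends are trimmed so the similarity domain
   stays inside the moving image over the capture range (a
   transform-dependent domain biases the optimum). The diagnostic scan is
   the fixed physical reference.
4. **Deformable registration** — self-contained multi-resolution
   demons-style solver (the original work used an external registration
   package): symmetric-force updates `diff·∇/(|∇|² + diff²/K)` with
   `K = mean squared spacing`, Gaussian fluid smoothing of each update,
   greedy acceptance (an update is kept only if the masked MSE drops, with
   backtracking on the step length), so recorded similarity is monotone
   per level. An 8-parameter affine initialization fitted at coarse
   resolution absorbs the bulk posture change; evaluating its cost over
   the whole grid (not the body only) anchors it against degenerate
   self-similar fits of the near-elliptical body. Spine rigidity is a hard
   projection — the field is multiplied by a weight that is zero on the
   (slightly dilated, +2 mm) spine mask and ramps to one over 12 mm — a
   deliberately stronger guarantee than a soft penalty, at the cost of not
   trading rigidity against similarity. Stage 1 registers the whole body
   over a 4-level pyramid (smoothing 64/32/16/12 mm); stage 2 polishes at
   full resolution with the similarity restricted to the abdominal mask
   minus the lungs (re-running coarse levels with a restricted domain was
   measured to distort the converged global field). Target fields for
   training can come from this registration (`--targets registered`) or,
   on phantoms, from the analytic truth (`--targets ground_truth`).

On 10 default phantoms the registration reaches warped-body Dice ≥ 0.95,
mean in-body field error ≈ 1.7–1.9 mm and exactly zero spine
displacement; the residual concentrates in the spine-attenuation annulus
and the strongly curved posterior sag region.

## Networks and training

Four generator configurations: a 3-D U-Net and three conditional-GAN
(Pix2Pix-style) variants — 3-D large-patch, 3-D small-patch, and a 2.5-D
variant that takes three adjacent axial slices as channels and emits the
middle slice's three displacement components. All use Conv → BatchNorm →
LeakyReLU(0.01) blocks, strided-conv downsampling, nearest-upsample +
conv decoding with skip concatenation, and a **linear** final projection:
displacements are signed, unbounded reals, so no squashing activation is
applied. The discriminator is a three-layer strided patch critic on the
concatenated (CT, DVF) pair with sigmoid scores. Channel widths, depths
and kernel sizes are free parameters here (the clinical model's are
unpublished); defaults are deliberately small for CPU use.

The layers are implemented on a minimal reverse-mode autodiff engine in
numpy (`perfectsyn.nn`) written for this package: eager, single-threaded,
seeded, with analytic gradients verified against central finite
differences to 1e-4 relative. Networks compute in float32; the engine
preserves float64 inputs so gradient checks run at full precision.

Training inputs are HU clipped to ±1000 and scaled to [−1, 1]; target
displacements are scaled by 20 mm (the augmentation range) — both
unstated in the original description and chosen as round, stable values.
Patches are sampled with centres inside the body; augmentation applies a
shared rigid transform (shifts uniform in ±20 mm, z-rotations in ±10°) to
both scans, every mask, and — covariantly, `u' = R⁻¹ u∘g` — the target
field, on a pre-padded canvas so body voxels are never cropped.

The loss is `l1·L_adv + l2·L1(DVF) + l3·L1(image) + l4·R_smooth` with
defaults (0.3, 100, 30, 0.1) for GAN variants and (0, 100, 0, 0.1) for
the U-Net baseline, which is thereby a pure DVF-regression reference —
the comparison against it isolates what the adversarial + image terms
add. The clinical weights were set by trial and error on training and
validation data and never published; we replicated that protocol on
held-out validation phantoms. The naive Pix2Pix-style assignment
(1, 100, 10, 0.1) under-weights the image term (its raw magnitude is
several times smaller than the DVF term's) and over-weights the
adversary, to the point where the GAN preset stopped outperforming the
regression baseline; the selected weights fix both. The image term warps the input patch
by the predicted field in-place (gradient via the moving-image spatial
gradient sampled at the warped positions, the standard first-order
approximation) and is evaluated on the abdominal mask. The generator uses
the non-saturating adversarial form; the printed minimax form is what the
discriminator maximizes. "Weighted Adam" is interpreted as Adam on the
weighted-sum loss. Adam runs with lr 0.01 decayed ×0.97 after each epoch,
β₁ = 0.5, β₂ = 0.9, ε = 1e−8; 150 epochs at full scale. D:G update ratio
is 1:1. Batch norm is retained even at small batch sizes.

## Desk-scale study

The end-to-end experiment (`perfectsyn.experiments.run_synthesis_study`)
simulates 60 training + 20 held-out phantoms on a 48³ grid
(4 × 5 × 5 mm, a slightly smaller habitus so the full amplitude range
fits the field of view), derives training target fields with the
deformable registration — the same chain the clinical pipeline uses;
with analytic ground-truth targets pure regression is unrealistically
well-posed and the GAN terms have nothing to add — trains the `unet3d`
and `pix2pix3d_small` presets at reduced patch size (20³) and width (8)
for 20 epochs × 15 steps × batch 2, then synthesizes planning CTs for
the test phantoms using couch-removed inputs, exactly as at inference.
These sizes are the package's standard desk-scale configuration; the
canonical 128³/32³ patch sizes remain the defaults of the respective
variants. Scores: body Dice between synthesized and true planning
contours versus the unwarped diagnostic baseline, and RMS HU error
(RASSD) over the body union. At this scale the expected orderings are
reproduced directionally: synthesis improves the setup match over the raw
diagnostic scan, and the adversarial preset beats the plain U-Net on
intensity error (it alone optimizes the warped-image term).

## Evaluation metrics

RASSD is formalized as the region-restricted RMS HU difference (the name
is used without a formula in the radiotherapy literature; body-union is
the default region). Dice uses the both-empty = 1 convention and never
applies centre-of-mass alignment. The Hausdorff distance is the true
maximum over boundary voxels (6-connectivity erosion surfaces, world mm);
HD95 is available behind a flag. The paired permutation test sign-flips
paired differences (mean-difference statistic, 10,000 permutations,
add-one estimator, seeded); sign-flipping is the standard paired form.
All metrics are verified against brute-force loop implementations.

## Known limitations

* The demons engine is a simplified stand-in for production registration
  software; its hard rigidity projection cannot trade rigidity against
  similarity, and accuracy on real, sliding, truncated anatomy is
  untested.
* The 2.5-D variant is wired for inference experiments but the volumetric
  patch trainer does not train it.
* Phantom realism limits (see above) mean clinical image-quality numbers
  are reproduced only directionally, not numerically.
* The numpy networks are orders of magnitude slower than GPU frameworks;
  they exist for correctness and reproducibility at test scale, not for
  training clinical-resolution models.
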