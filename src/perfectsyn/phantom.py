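"""Synthetic paired abdominal phantoms with known ground-truth deformations.

Each phantom pair emulates the systematic differences between a diagnostic
CT (dCT) and a treatment-planning CT (pCT) of the same patient:

* the dCT body sags posteriorly into a curved diagnostic couch, the pCT has
  a flat posterior surface (flat treatment couch);
* the pCT abdomen is expanded anteriorly/laterally by a breath-hold;
* the spine is rigid — the ground-truth field is exactly zero inside it;
* distinct HU tissue classes (air, lung, fat, soft tissue, bone, couch) and
  additive Gaussian acquisition noise.

The pCT is rendered by evaluating the dCT anatomy at analytically displaced
positions, so ``warp_image(dct, gt_dvf)`` reproduces the pCT by construction
(pull-back convention, see :mod:`perfectsyn.core`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Grid, ImageVolume, StructureSet, VectorField
from .errors import ValidationError

DEFAULT_TISSUE_HU: Dict[str, float] = {
    "air": -1000.0,
    "lung": -750.0,
    "fat": -100.0,
    "soft": 40.0,
    "bone": 700.0,
    "couch": 150.0,
}


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class OrganSpec:
    """An ellipsoidal organ blob: centre (z,y,x mm) + per-axis radii + HU."""

    center: Tuple[float, float, float]
    radii: Tuple[float, float, float]
    hu: float

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ValidationError("organ radii must be positive")

    def indicator(self, pz, py, px) -> np.ndarray:
        return (
            ((pz - self.center[0]) / self.radii[0]) ** 2
            + ((py - self.center[1]) / self.radii[1]) ** 2
            + ((px - self.center[2]) / self.radii[2]) ** 2
        ) <= 1.0


@dataclass
class PhantomSpec:
    """All knobs of one phantom pair.  Defaults are the package's standard
    study conditions; :func:`sample_population` randomizes a subset."""

    shape: Tuple[int, int, int] = (48, 64, 64)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    # body geometry (mm)
    body_semiaxis_x: float = 80.0
    body_semiaxis_y: float = 60.0
    body_center_y: float = 116.0
    fat_thickness: float = 10.0
    # deformation amplitudes (mm)
    couch_sag: float = 24.0
    breath_amplitude: float = 10.0
    axial_amplitude: float | None = None   # default: 0.3 * breath_amplitude
    # breath-hold also reshapes the cross-section: lateral stretch factor
    # 1 + stretch_per_mm * breath_amplitude, AP compressed reciprocally (J = 1)
    stretch_per_mm: float = 0.034
    # spine
    spine_radius: float = 11.0
    spine_offset_y: float = 27.0       # posterior of body centre
    spine_fin_half_width: float = 5.0
    spine_fin_length: float = 16.0
    spine_lateral_length: float = 14.0
    vertebra_period: float = 32.0
    # lungs
    lung_center_zfrac: float = 0.14
    lung_radius_zfrac: float = 0.13
    lung_offset_xfrac: float = 0.35
    # organs: filled by __post_init__ when left empty
    organs: Dict[str, OrganSpec] = field(default_factory=dict)
    tissue_hu: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    noise_sd: float = 12.0
    # soft-tissue texture: smooth HU bumps (vessels, bowel content,
    # parenchyma) that deform with the anatomy and give intensity-based
    # registration anchors away from organ boundaries
    n_texture: int = 45
    texture_radius: Tuple[float, float] = (6.0, 15.0)
    texture_amp_hu: float = 45.0
    # dCT couch rendering
    couch_gap: float = 12.0
    couch_shell: float = 10.0
    # population ranges used by sample_population
    sag_range: Tuple[float, float] = (18.0, 30.0)
    amplitude_range: Tuple[float, float] = (7.0, 13.0)
    organ_jitter: float = 8.0
    tumor_jitter: float = 4.0
    tumor_radius_range: Tuple[float, float] = (14.0, 18.0)
    seed: int = 0

    def __post_init__(self):
        if self.couch_sag < 0 or self.breath_amplitude < 0 or \
                (self.axial_amplitude is not None and self.axial_amplitude < 0):
            raise ValidationError("deformation amplitudes must be >= 0")
        if self.spine_radius <= 0:
            raise ValidationError("spine radius must be positive")
        if not self.organs:
            self.organs = self._default_organs()
        self._validate_geometry()

    # -- derived geometry ---------------------------------------------------
    @property
    def extent(self) -> Tuple[float, float, float]:
        return tuple(self.shape[a] * self.spacing[a] for a in range(3))  # type: ignore

    @property
    def center_x(self) -> float:
        return 0.5 * self.extent[2]

    @property
    def spine_center(self) -> Tuple[float, float]:
        return (self.body_center_y + self.spine_offset_y, self.center_x)

    @property
    def lung_bottom_z(self) -> float:
        return (self.lung_center_zfrac + self.lung_radius_zfrac) * self.extent[0]

    @property
    def effective_axial_amplitude(self) -> float:
        if self.axial_amplitude is not None:
            return self.axial_amplitude
        return 0.25 * self.breath_amplitude

    @property
    def stretch(self) -> float:
        return 1.0 + self.stretch_per_mm * self.breath_amplitude

    def _default_organs(self) -> Dict[str, OrganSpec]:
        # offsets scale with the body habitus so smaller phantoms keep all
        # organs safely inside the body under population jitter
        lz = self.extent[0]
        ys, cx = self.spine_center
        sy = self.body_semiaxis_y / 60.0
        sx = self.body_semiaxis_x / 80.0
        return {
            "gtv": OrganSpec((0.52 * lz, ys - 55.0 * sy, cx + 6.0 * sx),
                             (16.0, 16.0, 16.0), 90.0),
            "duodenum": OrganSpec((0.55 * lz, ys - 42.0 * sy, cx + 32.0 * sx),
                                  (16.0, 11.0, 11.0), 25.0),
            "stomach": OrganSpec((0.45 * lz, ys - 62.0 * sy, cx - 24.0 * sx),
                                 (16.0, 14.0, 18.0), -20.0),
            "bowel": OrganSpec((0.74 * lz, ys - 48.0 * sy, cx - 10.0 * sx),
                               (18.0, 13.0, 22.0), 10.0),
        }

    def _validate_geometry(self) -> None:
        ez, ey, ex = self.extent
        cx, cy = self.center_x, self.body_center_y
        # lateral expansion is weighted down to ~0.7 of the anterior amplitude
        reach = self.body_semiaxis_x * self.stretch + 0.7 * self.breath_amplitude
        if cx + reach > ex - 2.0 or cx - reach < 2.0:
            raise ValidationError(
                "breath-hold expansion would push the body outside the grid"
            )
        if cy - self.body_semiaxis_y - self.breath_amplitude < 2.0:
            raise ValidationError("anterior expansion exceeds the grid")
        if cy + self.body_semiaxis_y + self.couch_sag + self.couch_gap \
                + self.couch_shell > ey - 2.0:
            raise ValidationError("posterior sag + couch exceeds the grid")
        for name, o in self.organs.items():
            dy = (o.center[1] - cy) / self.body_semiaxis_y
            dx = (o.center[2] - cx) / self.body_semiaxis_x
            if dy * dy + dx * dx > 0.85 ** 2:
                raise ValidationError(f"organ {name!r} is not inside the body")

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, (0.0, 0.0, 0.0))


@dataclass
class PhantomPair:
    """One training/testing unit: matched dCT/pCT + truth field + contours."""

    dct: ImageVolume
    pct: ImageVolume
    gt_dvf: VectorField
    structs_d: StructureSet
    structs_p: StructureSet
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# analytic anatomy
# ---------------------------------------------------------------------------

class _Anatomy:
    """Vectorized analytic HU / indicator functions of the dCT anatomy."""

    def __init__(self, spec: PhantomSpec):
        self.s = spec
        # texture blob layout is part of the anatomy: drawn once from the
        # spec seed, identical (but deformed) in both scans of a pair
        rng = np.random.default_rng(10007 + spec.seed)
        s = spec
        n = s.n_texture
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = np.sqrt(rng.uniform(0, 1, n)) * 0.8
        self._tex_c = np.stack([
            rng.uniform(0.05, 0.95, n) * s.extent[0],
            s.body_center_y + rad * np.sin(ang) * s.body_semiaxis_y,
            s.center_x + rad * np.cos(ang) * s.body_semiaxis_x,
        ], axis=1)
        self._tex_r = rng.uniform(*s.texture_radius, n)
        self._tex_a = rng.uniform(-s.texture_amp_hu, s.texture_amp_hu, n)

    def texture(self, pz, py, px) -> np.ndarray:
        """Sum of smooth radial bumps; zero outside each blob's support."""
        out = np.zeros(np.broadcast(pz, py, px).shape)
        for (cz, cy, cx), r, a in zip(self._tex_c, self._tex_r, self._tex_a):
            q = ((pz - cz) ** 2 + (py - cy) ** 2 + (px - cx) ** 2) / r ** 2
            near = q < 1.0
            if near.any():
                out[near] += a * (1.0 - q[near]) ** 2
        return out

    # posterior couch-sag profile of the dCT body
    def _sag_offset(self, py, px):
        s = self.s
        xn = np.clip((px - s.center_x) / (1.15 * s.body_semiaxis_x), -1.0, 1.0)
        prof = np.cos(0.5 * np.pi * xn) ** 2
        ramp = _smoothstep((py - s.body_center_y) / (0.8 * s.body_semiaxis_y))
        return s.couch_sag * prof * ramp

    def body_quadric(self, pz, py, px):
        s = self.s
        y_eff = py - self._sag_offset(py, px)
        return (
            ((px - s.center_x) / s.body_semiaxis_x) ** 2
            + ((y_eff - s.body_center_y) / s.body_semiaxis_y) ** 2
        )

    def body(self, pz, py, px):
        return self.body_quadric(pz, py, px) <= 1.0

    def spine(self, pz, py, px):
        # vertebral column stand-in: cylinder + posterior spinous process +
        # lateral transverse processes (the asymmetry makes axial rotation
        # observable to intensity-based registration)
        s = self.s
        ys, cx = s.spine_center
        cyl = (py - ys) ** 2 + (px - cx) ** 2 <= s.spine_radius ** 2
        fin = (
            (np.abs(px - cx) <= s.spine_fin_half_width)
            & (py >= ys)
            & (py <= ys + s.spine_radius + s.spine_fin_length)
        )
        bar = (
            (np.abs(py - ys) <= s.spine_fin_half_width)
            & (np.abs(px - cx) <= s.spine_radius + s.spine_lateral_length)
        )
        return (cyl | fin | bar) & self.body(pz, py, px)

    def spine_hu(self, pz, py, px) -> np.ndarray:
        """Vertebra/disk alternation along z: dense bone in vertebral bands,
        lower HU in the intervertebral gaps."""
        s = self.s
        phase = np.mod(pz, s.vertebra_period) / s.vertebra_period
        band = phase < 0.72
        return np.where(band, s.tissue_hu["bone"], 0.55 * s.tissue_hu["bone"])

    def lungs(self, pz, py, px):
        s = self.s
        lz = s.extent[0]
        cz = s.lung_center_zfrac * lz
        rz = s.lung_radius_zfrac * lz
        out = np.zeros(np.broadcast(pz, py, px).shape, bool)
        for sx in (-1.0, 1.0):
            cxl = s.center_x + sx * s.lung_offset_xfrac * s.body_semiaxis_x
            cyl = s.body_center_y - 0.18 * s.body_semiaxis_y
            out |= (
                ((pz - cz) / rz) ** 2
                + ((py - cyl) / (0.42 * s.body_semiaxis_y)) ** 2
                + ((px - cxl) / (0.27 * s.body_semiaxis_x)) ** 2
            ) <= 1.0
        return out & self.body(pz, py, px)

    def abdomen(self, pz, py, px):
        shape = np.broadcast(pz, py, px).shape
        return self.body(pz, py, px) & np.broadcast_to(pz > self.s.lung_bottom_z, shape)

    def organ(self, name, pz, py, px):
        return self.s.organs[name].indicator(pz, py, px) & self.body(pz, py, px)

    def hu(self, pz, py, px) -> np.ndarray:
        pz, py, px = np.broadcast_arrays(pz, py, px)
        s, t = self.s, self.s.tissue_hu
        q = self.body_quadric(pz, py, px)
        shape = np.broadcast(pz, py, px).shape
        out = np.full(shape, t["air"], np.float64)
        body = q <= 1.0
        out[body] = t["fat"]
        # inner soft-tissue core (fat rind of roughly fat_thickness mm)
        frac = 1.0 - s.fat_thickness / (0.5 * (s.body_semiaxis_x + s.body_semiaxis_y))
        out[q <= frac ** 2] = t["soft"]
        out[self.lungs(pz, py, px)] = t["lung"]
        for name, o in s.organs.items():
            out[o.indicator(pz, py, px) & body] = o.hu
        if s.n_texture:
            tissue = body & ~self.lungs(pz, py, px)
            out[tissue] += self.texture(pz, py, px)[tissue]
        sp_mask = self.spine(pz, py, px)
        sp_hu = self.spine_hu(pz, py, px)
        out[sp_mask] = np.broadcast_to(sp_hu, shape)[sp_mask]
        return out

    def structure_names(self) -> List[str]:
        return ["body", "spine", "lungs", "abdomen", *self.s.organs.keys()]

    def structures(self, pz, py, px) -> Dict[str, np.ndarray]:
        pz, py, px = np.broadcast_arrays(pz, py, px)
        out = {
            "body": self.body(pz, py, px),
            "spine": self.spine(pz, py, px),
            "lungs": self.lungs(pz, py, px),
            "abdomen": self.abdomen(pz, py, px),
        }
        for name in self.s.organs:
            out[name] = self.organ(name, pz, py, px)
        return out


# ---------------------------------------------------------------------------
# analytic ground-truth displacement  (pCT grid -> dCT material position)
# ---------------------------------------------------------------------------

class _Deformation:
    """Smooth analytic pull-back field: sag removal + breath-hold expansion,
    attenuated to exactly zero inside (and just around) the spine."""

    def __init__(self, spec: PhantomSpec, anatomy: _Anatomy):
        self.s = spec
        self.an = anatomy
        self.rigid_margin = 8.0    # zero displacement within this distance of the spine
        self.falloff = 12.0

    def _spine_surface_distance(self, py, px):
        """In-plane distance to the spine surface (cylinder union fin box)."""
        s = self.s
        ys, cx = s.spine_center
        rho = np.sqrt((py - ys) ** 2 + (px - cx) ** 2)
        d_cyl = np.maximum(rho - s.spine_radius, 0.0)
        dx = np.maximum(np.abs(px - cx) - s.spine_fin_half_width, 0.0)
        dy = np.maximum(
            np.maximum(ys - py, py - (ys + s.spine_radius + s.spine_fin_length)), 0.0
        )
        d_fin = np.sqrt(dx * dx + dy * dy)
        bx = np.maximum(np.abs(px - cx) - (s.spine_radius + s.spine_lateral_length), 0.0)
        by = np.maximum(np.abs(py - ys) - s.spine_fin_half_width, 0.0)
        d_bar = np.sqrt(bx * bx + by * by)
        return np.minimum(np.minimum(d_cyl, d_fin), d_bar)

    def _rigidity_weight(self, py, px):
        d = self._spine_surface_distance(py, px)
        return _smoothstep((d - self.rigid_margin) / self.falloff)

    def _volume_preserving_part(self, pz, py, px):
        """Sag removal + area-preserving posture stretch (unit Jacobian in
        the abdomen, so it is exempt from tumour rigidification)."""
        s = self.s
        # posterior sag removal: flat pCT back samples the sagged dCT back
        u_sag_y = self.an._sag_offset(py, px)
        # breath-hold posture change: lateral widening with reciprocal
        # anterior-posterior thinning about the body centre
        stretch = s.stretch
        ux = (px - s.center_x) * (1.0 / stretch - 1.0)
        uy = u_sag_y + (py - s.body_center_y) * (stretch - 1.0)
        return np.zeros(np.broadcast(pz, py, px).shape), uy, ux

    def _compressive_part(self, pz, py, px):
        """Radial breath-hold expansion + inferior diaphragm shift; these
        change local volume and are frozen to a constant inside the tumour."""
        s = self.s
        ys, cx = s.spine_center
        dy, dx = py - ys, px - cx
        rho = np.sqrt(dy * dy + dx * dx)
        rho_safe = np.maximum(rho, 1e-9)
        aw = np.clip(0.5 * (1.0 - dy / rho_safe), 0.0, 1.0) ** 0.7
        r0 = s.spine_radius + self.rigid_margin
        r_ref = s.spine_offset_y + s.body_semiaxis_y + 18.0
        chi = _smoothstep((rho - r0) / (r_ref - r0))
        zeta = _smoothstep((pz - s.lung_bottom_z) / 25.0)
        u_r = -s.breath_amplitude * aw * chi * zeta
        lz = s.extent[0]
        tau = np.clip((pz - s.lung_bottom_z) / max(lz - s.lung_bottom_z, 1e-9),
                      0.0, 1.0)
        u_z = -s.effective_axial_amplitude * np.sin(np.pi * tau) * zeta
        shape = np.broadcast(pz, py, px).shape
        uz = np.broadcast_to(u_z * np.ones_like(rho), shape)
        uy = np.broadcast_to(u_r * dy / rho_safe, shape)
        ux = np.broadcast_to(u_r * dx / rho_safe, shape)
        return uz, uy, ux

    def _ambient(self, pz, py, px):
        """Field before spine attenuation and tumour rigidification."""
        a = self._volume_preserving_part(pz, py, px)
        b = self._compressive_part(pz, py, px)
        return tuple(x + y for x, y in zip(a, b))

    def _tumor_anchor(self):
        """Pre-image position of the tumour centre and the (constant)
        compressive displacement it carries: damped fixed-point iteration on
        x_c + u(x_c) = c."""
        c = np.asarray(self.s.organs["gtv"].center, float)
        xc = c.copy()
        for _ in range(80):
            pt = tuple(np.asarray(v) for v in xc)
            phi = xc + np.array([float(v) for v in self._volume_preserving_part(*pt)]) \
                     + np.array([float(v) for v in self._compressive_part(*pt)])
            step = phi - c
            if np.max(np.abs(step)) < 1e-8:
                break
            xc = xc - 0.5 * step
        pt = tuple(np.asarray(v) for v in xc)
        uc = np.array([float(v) for v in self._compressive_part(*pt)])
        return xc, uc

    def __call__(self, pz, py, px):
        s = self.s
        pz, py, px = np.broadcast_arrays(pz, py, px)
        ez, ey, ex = self._volume_preserving_part(pz, py, px)
        bz, by, bx = self._compressive_part(pz, py, px)

        if "gtv" in s.organs:
            # freeze the compressive part to its value at the tumour so the
            # tumour deforms with unit Jacobian (mass conserved); wide, gentle
            # blend shell to keep the composite map fold-free
            o = s.organs["gtv"]
            c = np.asarray(o.center, float)
            _, uc = self._tumor_anchor()
            d = np.sqrt((pz + ez + uc[0] - c[0]) ** 2
                        + (py + ey + uc[1] - c[1]) ** 2
                        + (px + ex + uc[2] - c[2]) ** 2)
            wg = _smoothstep((d - max(o.radii)) / 60.0)
            bz = wg * bz + (1.0 - wg) * uc[0]
            by = wg * by + (1.0 - wg) * uc[1]
            bx = wg * bx + (1.0 - wg) * uc[2]

        w = self._rigidity_weight(py, px)
        return w * (ez + bz), w * (ey + by), w * (ex + bx)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _grid_points(spec: PhantomSpec):
    pz = (np.arange(spec.shape[0]) * spec.spacing[0]).reshape(-1, 1, 1)
    py = (np.arange(spec.shape[1]) * spec.spacing[1]).reshape(1, -1, 1)
    px = (np.arange(spec.shape[2]) * spec.spacing[2]).reshape(1, 1, -1)
    return pz, py, px


def _couch_arc_hu(an: _Anatomy, pz, py, px) -> np.ndarray:
    """Curved diagnostic couch: a shell following the sagged posterior body
    surface, separated from it by a small air gap."""
    s = an.s
    xn = (px - s.center_x) / s.body_semiaxis_x
    inside = np.abs(xn) < 0.995
    y_surf = np.where(
        inside,
        s.body_center_y
        + s.body_semiaxis_y * np.sqrt(np.clip(1.0 - xn * xn, 0.0, 1.0))
        + an._sag_offset(
            np.broadcast_to(s.body_center_y + s.body_semiaxis_y, np.shape(xn)), px
        ),
        np.inf,
    )
    shell = (py >= y_surf + s.couch_gap) & (py <= y_surf + s.couch_gap + s.couch_shell)
    shape = np.broadcast(pz, py, px).shape
    return np.broadcast_to(shell, shape)


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Render one (dCT, pCT, ground-truth DVF, contours) phantom pair.

    Bit-reproducible for a fixed ``spec`` (including ``spec.seed``).
    """
    an = _Anatomy(spec)
    deform = _Deformation(spec, an)
    pz, py, px = _grid_points(spec)
    grid = spec.grid

    hu_d = an.hu(pz, py, px)
    couch = _couch_arc_hu(an, pz, py, px)
    hu_d = np.where(couch, spec.tissue_hu["couch"], hu_d)

    uz, uy, ux = deform(pz, py, px)
    dvf = VectorField(
        np.stack([uz, uy, ux]).astype(np.float32), spec.spacing, (0.0, 0.0, 0.0)
    )
    hu_p = an.hu(pz + uz, py + uy, px + ux)

    # light anti-aliasing of the piecewise-constant rasterization, then noise
    rng = np.random.default_rng(spec.seed)
    vols = []
    for hu in (hu_d, hu_p):
        sm = ndimage.gaussian_filter(hu, sigma=0.6)
        noisy = sm + rng.normal(0.0, spec.noise_sd, size=sm.shape)
        vols.append(ImageVolume(noisy.astype(np.float32), spec.spacing))
    dct, pct = vols

    structs_d = StructureSet()
    for name, ind in an.structures(pz, py, px).items():
        structs_d.add(name, BinaryMask(np.broadcast_to(ind, spec.shape).astype(np.uint8),
                                       spec.spacing))
    structs_p = StructureSet()
    for name, ind in an.structures(pz + uz, py + uy, px + ux).items():
        structs_p.add(name, BinaryMask(ind.astype(np.uint8), spec.spacing))

    return PhantomPair(dct, pct, dvf, structs_d, structs_p, spec)


def sample_population(
    n: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> List[PhantomPair]:
    """Draw ``n`` phantom pairs with randomized amplitudes and organ layout.

    Per pair, the couch sag and breath-hold amplitude are uniform in
    ``base_spec.sag_range`` / ``base_spec.amplitude_range``, organ centres
    are jittered by up to ``organ_jitter`` mm and the tumour radius is
    uniform in ``tumor_radius_range``.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ValidationError("population size must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        sag = rng.uniform(*base.sag_range)
        amp = rng.uniform(*base.amplitude_range)
        organs = {}
        for name, o in base.organs.items():
            amp_j = base.tumor_jitter if name == "gtv" else base.organ_jitter
            jitter = rng.uniform(-amp_j, amp_j, size=3)
            radii = o.radii
            if name == "gtv":
                r = rng.uniform(*base.tumor_radius_range)
                radii = (r, r, r)
            organs[name] = OrganSpec(tuple(np.add(o.center, jitter)), radii, o.hu)
        pair_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = replace(base, couch_sag=float(sag), breath_amplitude=float(amp),
                       organs=organs, seed=pair_seed)
        pairs.append(generate_phantom_pair(spec))
    return pairs
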