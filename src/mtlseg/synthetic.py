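"""Synthetic phantom cohorts with known ground truth.

Each phantom contains three adjacent star-shaped structures standing in for
the hippocampus (HP, a mildly curved elongated ellipsoid), amygdala (AM, an
ellipsoid adjacent to the HP head) and entorhinal cortex (EC, a flattened
curved slab placed inferior-medially). Structures are defined as radial
fields r(direction) about a center, which guarantees star-shapedness by
construction; population shape variability comes from low-order real
spherical-harmonic radial perturbations plus a random anisotropic scale and
shift, and patients additionally receive volumetric atrophy implemented as
a uniform radial shrink by factor**(1/3) (exactly hitting the target volume
fraction for a radial shape).

EC is given weaker boundary contrast than HP/AM (85 vs 70 against tissue at
100), emulating the empirical finding that EC is the hardest of the three
structures to segment.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .imaging import LabelVolume, STRUCTURE_CODES, STRUCTURES, Volume3D, BinaryMask
from .library import (
    DEFAULT_LEVEL,
    Template,
    TemplateLibrary,
    build_library,
    build_template,
    surface_from_label,
)
from .mesh import CorrespondedSurface


def real_sh_basis(dirs: np.ndarray) -> np.ndarray:
    """First 9 real spherical-harmonic basis functions (l = 0..2), (9, N).

    Normalization constants are irrelevant for random shape perturbation and
    are chosen so each function has unit range order of magnitude.
    """
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    return np.stack([
        np.ones_like(x),
        x, y, z,
        x * y, y * z, x * z,
        x * x - y * y,
        3 * z * z - 1.0,
    ])


@dataclass
class StructureGeometry:
    center: np.ndarray
    semiaxes: np.ndarray
    curvature: float  # coefficient of the d_x*d_y (HP) / d_x*d_z (EC) bend term
    curvature_axes: tuple[int, int]


_BASE_GEOMETRY = {
    "HP": StructureGeometry(np.array([30.0, 30.0, 30.0]),
                            np.array([5.0, 9.0, 4.5]), 0.25, (0, 1)),
    "AM": StructureGeometry(np.array([30.0, 46.0, 33.0]),
                            np.array([4.5, 4.0, 4.5]), 0.0, (0, 1)),
    "EC": StructureGeometry(np.array([21.0, 35.0, 22.0]),
                            np.array([6.5, 8.0, 3.2]), 0.15, (0, 2)),
}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    structure_intensity: dict = dc_field(
        default_factory=lambda: {"HP": 70.0, "AM": 70.0, "EC": 85.0}
    )
    tissue_intensity: float = 100.0
    surround_intensity: float = 30.0
    noise_sd: float = 5.0
    perturbation_sd: float = 0.06  # radial perturbation SD, fraction of radius
    scale_jitter: float = 0.05  # per-axis scale in U(1 +- jitter)
    shift_mm: float = 2.0  # per-axis center shift in U(+-shift)
    atrophy: dict = dc_field(default_factory=dict)  # structure -> volume fraction
    level: int = DEFAULT_LEVEL
    smooth_sigma_mm: float = 0.0

    def __post_init__(self) -> None:
        for name, f in self.atrophy.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"atrophy factor for {name} must be in (0, 1]")


class _RadialShape:
    """Analytic radial field r(dir) for one perturbed, jittered structure."""

    def __init__(self, geom: StructureGeometry, coeffs: np.ndarray,
                 scale: np.ndarray, shift: np.ndarray, atrophy: float):
        self.center = geom.center + shift
        self.geom = geom
        self.coeffs = coeffs
        self.scale = scale
        self.shrink = atrophy ** (1.0 / 3.0)

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        # anisotropic scale S about the center: r'(d) = r(u) * |S u|,
        # u = normalize(S^-1 d) — still a star shape.
        u = dirs / self.scale
        un = np.linalg.norm(u, axis=1, keepdims=True)
        u = u / np.maximum(un, 1e-12)
        a = self.geom.semiaxes
        base = 1.0 / np.sqrt(((u / a) ** 2).sum(axis=1))
        i, j = self.geom.curvature_axes
        bend = 1.0 + self.geom.curvature * u[:, i] * u[:, j]
        pert = 1.0 + (self.coeffs[:, None] * real_sh_basis(u)).sum(axis=0)
        pert = np.clip(pert, 0.3, 1.7)
        stretch = np.linalg.norm(u * self.scale, axis=1)
        return base * bend * pert * stretch * self.shrink

    def max_radius(self) -> float:
        return float(self.geom.semiaxes.max() * (1 + abs(self.geom.curvature))
                     * 1.7 * self.scale.max())


def _draw_shapes(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    shapes = {}
    for name in STRUCTURES:
        geom = _BASE_GEOMETRY[name]
        coeffs = rng.normal(0.0, spec.perturbation_sd, size=9)
        coeffs[0] *= 0.5  # keep the isotropic mode mild
        scale = 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter, size=3)
        shift = rng.uniform(-spec.shift_mm, spec.shift_mm, size=3)
        shapes[name] = _RadialShape(geom, coeffs, scale, shift,
                                    spec.atrophy.get(name, 1.0))
    return shapes


def _rasterize(spec: PhantomSpec, shapes: dict, affine: np.ndarray):
    """Voxelize the radial fields; returns (label data, overlap count)."""
    label = np.zeros(spec.shape, dtype=np.int16)
    claimed = np.zeros(spec.shape, dtype=np.int8)
    sp = spec.spacing_mm
    for name in STRUCTURES:
        shape_obj = shapes[name]
        rmax = shape_obj.max_radius() + 2 * sp
        lo = np.floor((shape_obj.center - rmax) / sp).astype(int)
        hi = np.ceil((shape_obj.center + rmax) / sp).astype(int) + 1
        lo = np.clip(lo, 0, np.asarray(spec.shape) - 1)
        hi = np.clip(hi, 0, np.asarray(spec.shape))
        grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                            indexing="ij")
        ijk = np.stack([g.ravel() for g in grids], axis=1)
        pts = ijk * sp  # affine is diag(spacing), origin 0
        delta = pts - shape_obj.center
        dist = np.linalg.norm(delta, axis=1)
        dirs = delta / np.maximum(dist, 1e-12)[:, None]
        inside = dist <= shape_obj.radius(dirs)
        sel = ijk[inside]
        flat = (sel[:, 0], sel[:, 1], sel[:, 2])
        label[flat] = STRUCTURE_CODES[name]
        claimed[flat] += 1
    return label, int(np.sum(claimed > 1))


def _head_mask(spec: PhantomSpec) -> np.ndarray:
    c = (np.asarray(spec.shape) - 1) / 2.0 * spec.spacing_mm
    radii = np.asarray(spec.shape) * spec.spacing_mm * np.array([0.42, 0.44, 0.42])
    ax = [np.arange(n) * spec.spacing_mm for n in spec.shape]
    grids = np.meshgrid(*ax, indexing="ij")
    q = sum(((g - ci) / ri) ** 2 for g, ci, ri in zip(grids, c, radii))
    return q <= 1.0


def make_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[Volume3D, LabelVolume, CorrespondedSurface]:
    """Generate one phantom; identical seeds give bit-identical outputs."""
    rng = np.random.default_rng(seed)
    affine = np.diag([spec.spacing_mm] * 3 + [1.0])
    label_data = None
    for _ in range(10):
        shapes = _draw_shapes(spec, rng)
        candidate, overlap = _rasterize(spec, shapes, affine)
        ok = overlap == 0
        if ok:
            for name in STRUCTURES:
                mask = candidate == STRUCTURE_CODES[name]
                if mask.sum() < 30 or ndimage.label(mask)[1] != 1:
                    ok = False
                    break
        if ok:
            label_data = candidate
            break
    if label_data is None:
        raise RuntimeError(
            "phantom generation failed star-shape/overlap validation 10 times"
        )
    label = LabelVolume(data=label_data, affine=affine)

    intensity = np.where(_head_mask(spec), spec.tissue_intensity,
                         spec.surround_intensity)
    for name in STRUCTURES:
        intensity = np.where(label_data == STRUCTURE_CODES[name],
                             spec.structure_intensity[name], intensity)
    if spec.smooth_sigma_mm > 0:
        intensity = ndimage.gaussian_filter(
            intensity, spec.smooth_sigma_mm / spec.spacing_mm
        )
    noise = rng.normal(0.0, spec.noise_sd, size=spec.shape) if spec.noise_sd > 0 \
        else 0.0
    volume = Volume3D(data=intensity + noise, affine=affine)
    surface = surface_from_label(label, spec.level)
    return volume, label, surface


def brain_mask(spec: PhantomSpec, affine: np.ndarray | None = None) -> BinaryMask:
    """Head-analogue mask (the phantom's non-air region) for normalization."""
    if affine is None:
        affine = np.diag([spec.spacing_mm] * 3 + [1.0])
    return BinaryMask(data=_head_mask(spec), affine=affine)


@dataclass
class CohortSpec:
    n_templates: int = 25
    n_test_controls: int = 10
    n_test_patients: int = 10
    template_patient_fraction: float = 0.4
    patient_atrophy: dict = dc_field(
        default_factory=lambda: {"HP": 0.70, "EC": 0.85}
    )
    seed: int = 0
    phantom: PhantomSpec = dc_field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if min(self.n_templates, self.n_test_controls, self.n_test_patients) < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass
class TestSubject:
    id: str
    group: str  # "control" or "patient"
    volume: Volume3D
    truth_label: LabelVolume
    truth_surface: CorrespondedSurface
    seed: int

    @property
    def truth_volumes(self) -> dict:
        return {s: self.truth_label.structure_volume(s) for s in STRUCTURES}


@dataclass
class Cohort:
    library: TemplateLibrary
    tests: list[TestSubject]
    manifest: dict

    @property
    def test_controls(self) -> list[TestSubject]:
        return [t for t in self.tests if t.group == "control"]

    @property
    def test_patients(self) -> list[TestSubject]:
        return [t for t in self.tests if t.group == "patient"]


def _subject_seed(master: int, tag: str, index: int) -> int:
    import zlib

    tag_hash = zlib.crc32(tag.encode()) % (2**31)
    ss = np.random.SeedSequence([int(master) % (2**31), tag_hash, index])
    return int(ss.generate_state(1)[0] % (2**31))


def _patient_spec(spec: CohortSpec) -> PhantomSpec:
    import dataclasses

    return dataclasses.replace(spec.phantom, atrophy=dict(spec.patient_atrophy))


def make_cohort(
    spec: CohortSpec,
    max_samples_per_radius: int | None = None,
    fast_inside: bool = False,
) -> Cohort:
    """Templates and test subjects from one shape-variability distribution.

    A fraction of templates are patient-like (atrophied), so the library
    spans the shape range of both groups; test patients receive the same
    atrophy factors. The manifest records every seed for reproducibility.
    """
    manifest: dict = {"seed": spec.seed, "templates": [], "tests": []}
    patient_spec = _patient_spec(spec)
    n_pat_templates = int(round(spec.template_patient_fraction * spec.n_templates))
    templates: list[Template] = []
    for i in range(spec.n_templates):
        is_patient = i < n_pat_templates
        pspec = patient_spec if is_patient else spec.phantom
        seed = _subject_seed(spec.seed, "template", i)
        vol, lab, surf = make_phantom(pspec, seed)
        group = "patient" if is_patient else "control"
        tid = f"tmpl{i:03d}"
        templates.append(
            build_template(tid, vol, lab, level=spec.phantom.level, group=group,
                           surface=surf,
                           max_samples_per_radius=max_samples_per_radius,
                           check_voxelization=False, fast_inside=fast_inside)
        )
        manifest["templates"].append({"id": tid, "group": group, "seed": seed})
    library = build_library(templates)

    tests: list[TestSubject] = []
    for i in range(spec.n_test_controls):
        seed = _subject_seed(spec.seed, "test_control", i)
        vol, lab, surf = make_phantom(spec.phantom, seed)
        sid = f"ctrl{i:03d}"
        tests.append(TestSubject(sid, "control", vol, lab, surf, seed))
        manifest["tests"].append({"id": sid, "group": "control", "seed": seed})
    for i in range(spec.n_test_patients):
        seed = _subject_seed(spec.seed, "test_patient", i)
        vol, lab, surf = make_phantom(patient_spec, seed)
        sid = f"pat{i:03d}"
        tests.append(TestSubject(sid, "patient", vol, lab, surf, seed))
        manifest["tests"].append({"id": sid, "group": "patient", "seed": seed})
    return Cohort(library=library, tests=tests, manifest=manifest)
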