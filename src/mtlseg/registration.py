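"""Boundary-weighted non-linear registration of a template to a test image.

The deformation is a control-point lattice of 3D displacement vectors (mm)
with trilinear interpolation between nodes — a self-contained free-form
model. The field is parameterized backward: a test-space point x samples
the template at x + d(x). Surfaces are carried forward with a fixed-point
inversion of d.

The registration cost is hybrid:

    O_hybrid = O_vol + w_surf_reg * O_surf - lambda * O_smooth

* O_vol: Pearson correlation of template and test intensities over the
  registration mask (library union label dilated 5x);
* O_surf: Pearson correlation, across surface vertices, between the
  relative-intensity (RI) feature on the true template surface over the
  template image and RI on the deformed surface over the test image,
  evaluated at a single 5 mm radius from a rigidly attached, trilinearly
  interpolated ball quadrature (continuous in the deformation);
* O_smooth: mean squared discrete Laplacian of the lattice displacements.

Optimization is a deterministic raster sweep over lattice nodes; each
node's three displacement components are optimized with derivative-free
Nelder-Mead while all other nodes are frozen. A node move is accepted only
if it improves the objective; within the node's evaluations nearby
vertices shift with the local linearization of the forward map, an
accepted move recomputes their positions exactly, and a sweep whose exact
end-of-sweep cost decreased is reverted — so accepted cost is monotone
non-decreasing. Node displacements are capped (0.4x the lattice spacing;
in a coarse-to-fine schedule the cap follows the coarsest level), which
keeps the per-level field locally invertible (positive Jacobian).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .features import relative_intensity_interp
from .imaging import BinaryMask, LabelVolume, Volume3D
from .library import Template
from .mesh import CorrespondedSurface, RadialSurfaceState

CAP_FRACTION = 0.4


@dataclass
class RegistrationConfig:
    w_surf_reg: float = 1.1
    smoothness_weight: float = 0.02
    lattice_spacings: tuple = (8.0, 4.0)  # mm, coarse to fine
    nm_maxiter: int = 60  # Nelder-Mead iterations per node
    # one count for every level, or a per-level tuple (coarse first)
    sweeps_per_level: int | tuple = 3
    tol: float = 1e-4  # sweep-to-sweep cost gain threshold
    ri_radius_mm: float = 5.0
    # the registration RI term uses a rigidly attached, trilinearly
    # interpolated ball of this many sample points (continuous in the
    # deformation); see the methods note
    ri_n_points: int = 64
    # the template-side RI vector is computed once, so it affords a denser
    # quadrature (less noise for the correlation target); None matches
    # ri_n_points, which makes registration of an image to itself an exact
    # fixed point of the surface term
    ri_template_points: int | None = None
    # correlate RI across the concatenated surface (the printed
    # formulation); optionally per structure, averaged
    per_structure_corr: bool = False
    # optional per-level surface weights (coarse first); None: w_surf_reg
    # at every level
    w_surf_reg_per_level: tuple | None = None
    max_ri_samples: int | None = None  # retained for API compatibility
    # vertices within f*spacing of the node take part in its local surface
    # term; beyond 1.0 the trilinear basis weight is zero anyway
    surface_refresh_radius_factor: float = 1.0
    # optimize the correlation over every k-th mask voxel (k=1: all); the
    # reported cost always uses the subsample it was optimized on
    mask_subsample: int = 1
    # skip lattice nodes with fewer supporting mask voxels than this
    min_support: int = 8

    def __post_init__(self) -> None:
        sp = list(self.lattice_spacings)
        if any(b >= a for a, b in zip(sp, sp[1:])):
            raise ValueError("lattice spacings must be strictly decreasing")
        if self.smoothness_weight < 0:
            raise ValueError("smoothness weight must be >= 0")


@dataclass
class DeformationField:
    """Control-lattice displacement field over the test volume."""

    origin: np.ndarray  # world mm of lattice node (0,0,0)
    spacing: float  # isotropic lattice spacing, mm
    disp: np.ndarray  # (nx, ny, nz, 3) node displacements, mm
    target_affine: np.ndarray  # test-image geometry the field lives on
    target_shape: tuple
    # displacement cap; defaults to 0.4x the lattice spacing. In a
    # coarse-to-fine schedule the cap is tied to the coarsest spacing so
    # refinement levels cannot lose displacement recovered earlier.
    cap_mm: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.disp = np.asarray(self.disp, dtype=float)

    @property
    def cap(self) -> float:
        if self.cap_mm is not None:
            return self.cap_mm
        return CAP_FRACTION * self.spacing

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Dense displacement at world points by trilinear lattice interpolation."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        g = (pts - self.origin) / self.spacing
        out = np.empty_like(pts)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.disp[..., c], g.T, order=1, mode="nearest"
            )
        return out

    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.disp.reshape(-1, 3), axis=1).max())


def zero_field(test: Volume3D, mask: BinaryMask, spacing: float,
               cap_mm: float | None = None) -> DeformationField:
    """Zero lattice covering the mask bounding box with a one-node margin."""
    idx = np.argwhere(mask.data)
    lo_w = test.voxel_to_world(idx.min(axis=0))[0] - spacing
    hi_w = test.voxel_to_world(idx.max(axis=0))[0] + spacing
    n = np.ceil((hi_w - lo_w) / spacing).astype(int) + 2
    return DeformationField(
        origin=lo_w, spacing=spacing, disp=np.zeros((*n, 3)),
        target_affine=test.affine, target_shape=test.data.shape, cap_mm=cap_mm,
    )


def smoothness_penalty(field: DeformationField) -> float:
    """Mean over nodes of the squared discrete Laplacian of the displacement."""
    d = field.disp
    lap = np.zeros_like(d)
    count = np.zeros(d.shape[:3])
    for ax in range(3):
        for shift in (-1, 1):
            rolled = np.roll(d, shift, axis=ax)
            valid = np.ones(d.shape[:3], dtype=bool)
            if shift == 1:
                idx = [slice(None)] * 3
                idx[ax] = 0
                valid[tuple(idx)] = False
            else:
                idx = [slice(None)] * 3
                idx[ax] = -1
                valid[tuple(idx)] = False
            lap += np.where(valid[..., None], rolled - d, 0.0)
            count += valid
    sq = (lap**2).sum(axis=-1)
    return float(sq.mean())


def o_vol_reg(warped_template: Volume3D, test: Volume3D, mask: BinaryMask) -> float:
    """Pearson correlation of masked intensities (offset/scale invariant)."""
    from .selection import cross_correlation

    return cross_correlation(warped_template.data[mask.data], test.data[mask.data])


def o_surf_reg(f_template: np.ndarray, f_deformed: np.ndarray,
               struct_idx: np.ndarray | None = None) -> float:
    """Pearson correlation of the two RI vectors across surface vertices.

    With `struct_idx` the correlation is computed per structure and
    averaged: the between-structure contrast pattern (EC boundaries are
    fainter than HP/AM by design) would otherwise dominate the coefficient
    and mask the within-structure alignment signal.
    """
    a = np.asarray(f_template, dtype=float)
    b = np.asarray(f_deformed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RI vectors must have equal length")

    def _corr(x, y):
        sx, sy = x.std(), y.std()
        if sx < 1e-12 or sy < 1e-12:
            raise ValueError("zero variance in an RI vector")
        return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))

    if struct_idx is None:
        return _corr(a, b)
    return float(np.mean([
        _corr(a[struct_idx == k], b[struct_idx == k]) for k in range(3)
    ]))


def apply_to_volume(
    field: DeformationField, vol: Volume3D | LabelVolume, order: int = 1
) -> Volume3D | LabelVolume:
    """Resample `vol` onto the test grid through the backward field."""
    shape = field.target_shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    aff = field.target_affine
    world = ijk @ aff[:3, :3].T + aff[:3, 3]
    src = world + field.displacement_at(world)
    inv = np.linalg.inv(vol.affine)
    vox = src @ inv[:3, :3].T + inv[:3, 3]
    data = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), vox.T, order=order,
        mode="constant", cval=0.0,
    ).reshape(shape)
    if isinstance(vol, LabelVolume):
        return LabelVolume(data=np.rint(data).astype(np.int16),
                           affine=field.target_affine)
    return Volume3D(data=data, affine=field.target_affine)


def forward_map(
    field: DeformationField, points: np.ndarray,
    tol: float = 0.01, max_iter: int = 20,
) -> tuple[np.ndarray, int]:
    """Invert the backward field at given points by fixed-point iteration.

    Solves y + d(y) = p for y. Returns (mapped points, number of points that
    did not converge — those keep the last fixed-point estimate).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    y = p - field.displacement_at(p)
    n_fail = 0
    for _ in range(max_iter):
        y_new = p - field.displacement_at(y)
        move = np.linalg.norm(y_new - y, axis=1)
        y = y_new
        if move.max() < tol:
            break
    else:
        n_fail = int((np.linalg.norm(field.displacement_at(y) + y - p, axis=1)
                      > tol).sum())
    return y, n_fail


def apply_to_surface(
    field: DeformationField, surface: CorrespondedSurface
) -> CorrespondedSurface:
    """Carry a template surface into test space via the inverted field."""
    verts, _ = forward_map(field, surface.vertices)
    return surface.with_vertices(verts)


def hybrid_cost(
    warped: Volume3D,
    test: Volume3D,
    mask: BinaryMask,
    field: DeformationField,
    cfg: RegistrationConfig,
    f_template: np.ndarray | None = None,
    f_deformed: np.ndarray | None = None,
) -> float:
    val = o_vol_reg(warped, test, mask)
    if cfg.w_surf_reg > 0 and f_template is not None:
        val += cfg.w_surf_reg * o_surf_reg(f_template, f_deformed)
    return val - cfg.smoothness_weight * smoothness_penalty(field)


class _NodeObjective:
    """Incremental global objective for one lattice node.

    The masked Pearson correlation and the surface RI correlation are
    updated incrementally: only the voxels in the node's trilinear support
    and the surface vertices it carries are recomputed per evaluation. The
    smoothness change is a closed-form quadratic in the node displacement.
    """

    def __init__(self, reg: "_Registration", node: tuple):
        self.reg = reg
        self.node = node
        r = reg
        # support voxels: trilinear basis weight of this node > 0
        node_pos = r.field.origin + np.array(node) * r.field.spacing
        rel = (r.mask_world - node_pos) / r.field.spacing
        w = np.prod(np.clip(1.0 - np.abs(rel), 0.0, None), axis=1)
        self.vox_sel = np.nonzero(w > 1e-9)[0]
        self.basis = w[self.vox_sel][:, None]
        self.d0 = r.field.disp[node].copy()
        self.base_src = (
            r.mask_world[self.vox_sel]
            + r.disp_at_mask[self.vox_sel]
            - self.basis * self.d0
        )
        self.skip = len(self.vox_sel) < r.cfg.min_support
        if self.skip:
            return
        self.w_old = r.warped_vals[self.vox_sel]
        self.t_loc = r.test_vals[self.vox_sel]
        # surface vertices within the node's support
        if r.use_surface:
            dist = np.linalg.norm(r.warped_verts - node_pos, axis=1)
            self.v_sel = np.nonzero(
                dist <= r.cfg.surface_refresh_radius_factor * r.field.spacing
            )[0]
            self.v_struct = r.struct_idx[self.v_sel]
        else:
            self.v_sel = np.array([], dtype=int)
        if len(self.v_sel):
            vrel = (r.warped_verts[self.v_sel] - node_pos) / r.field.spacing
            self.v_basis = np.prod(
                np.clip(1.0 - np.abs(vrel), 0.0, None), axis=1
            )[:, None]
        # smoothness: affected Laplacian terms as a quadratic in delta
        self._setup_smooth()

    def _exact_ri(self, positions: np.ndarray) -> np.ndarray:
        r = self.reg
        return relative_intensity_interp(
            r.test, r.surf_state, positions, r.struct_idx[self.v_sel],
            radius=r.cfg.ri_radius_mm, n_points=r.cfg.ri_n_points,
        )

    def _setup_smooth(self) -> None:
        r = self.reg
        d = r.field.disp
        shape = d.shape[:3]
        node = self.node
        offs = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                (0, 0, -1))
        nbs = [
            tuple(np.add(node, o))
            for o in offs
            if all(0 <= node[a] + o[a] < shape[a] for a in range(3))
        ]
        self._S_n = sum((d[nb] for nb in nbs), np.zeros(3))
        self._k_n = len(nbs)
        sumC = np.zeros(3)
        sumC2 = 0.0
        for m in nbs:
            mn = [
                tuple(np.add(m, o))
                for o in offs
                if all(0 <= m[a] + o[a] < shape[a] for a in range(3))
            ]
            C_m = sum((d[p] for p in mn if p != node), np.zeros(3)) \
                - len(mn) * d[m]
            sumC += C_m
            sumC2 += float((C_m**2).sum())
        self._sumC = sumC
        self._sumC2 = sumC2
        self._n_nodes = int(np.prod(shape))
        terms0 = self._smooth_terms(self.d0)
        self._smooth_rest = r._smooth_cache * self._n_nodes - terms0

    def _smooth_terms(self, delta: np.ndarray) -> float:
        lap_n = self._S_n - self._k_n * delta
        return float(
            (lap_n**2).sum()
            + self._sumC2
            + 2.0 * (self._sumC * delta).sum()
            + self._k_n * (delta**2).sum()
        )

    def smooth_value(self, delta: np.ndarray) -> float:
        return (self._smooth_rest + self._smooth_terms(delta)) / self._n_nodes

    def __call__(self, delta: np.ndarray) -> float:
        r = self.reg
        if np.abs(delta).max() > r.field.cap:
            return 1e6 + float(np.abs(delta).max())
        # --- volume term (incremental Pearson over the full mask)
        src = self.base_src + self.basis * delta
        w_new = r.sample_template(src)
        n = r.n_mask
        sw = r.sum_w - self.w_old.sum() + w_new.sum()
        sww = r.sum_ww - (self.w_old**2).sum() + (w_new**2).sum()
        swt = r.sum_wt - (self.w_old * self.t_loc).sum() + (w_new * self.t_loc).sum()
        var_w = sww / n - (sw / n) ** 2
        if var_w < 1e-12:
            return 1e6
        cov = swt / n - (sw / n) * (r.sum_t / n)
        val = cov / np.sqrt(var_w * r.var_t)
        # --- surface term: exact RI at the shifted vertex positions
        if len(self.v_sel):
            pos = r.warped_verts[self.v_sel] - self.v_basis * (delta - self.d0)
            f_new = self._exact_ri(pos)
            f_old = r.f_def[self.v_sel]
            ks = self.v_struct
            a_sel = r.f_tmpl[self.v_sel]
            sb = r.sum_b.copy()
            sbb = r.sum_bb.copy()
            sab = r.sum_ab.copy()
            np.add.at(sb, ks, f_new - f_old)
            np.add.at(sbb, ks, f_new**2 - f_old**2)
            np.add.at(sab, ks, a_sel * (f_new - f_old))
            val += r.cfg.w_surf_reg * r.surface_corr(sb, sbb, sab)
        # --- smoothness
        val -= r.cfg.smoothness_weight * self.smooth_value(delta)
        return -val

    def accept(self, delta: np.ndarray) -> None:
        """Commit an accepted node move into the registration state."""
        r = self.reg
        src = self.base_src + self.basis * delta
        w_new = r.sample_template(src)
        r.sum_w += w_new.sum() - self.w_old.sum()
        r.sum_ww += (w_new**2).sum() - (self.w_old**2).sum()
        r.sum_wt += (w_new * self.t_loc).sum() - (self.w_old * self.t_loc).sum()
        r.warped_vals[self.vox_sel] = w_new
        r.disp_at_mask[self.vox_sel] = src - r.mask_world[self.vox_sel]
        r.field.disp[self.node] = delta
        r._smooth_cache = self.smooth_value(delta)
        if len(self.v_sel):
            # exact forward-map positions for the committed field (the
            # linearized shift inside the NM evaluations would otherwise
            # accumulate drift across the sweep)
            pos, _ = forward_map(
                r.field, r.template.surface.vertices[self.v_sel])
            f_new = self._exact_ri(pos)
            f_old = r.f_def[self.v_sel]
            np.add.at(r.sum_b, self.v_struct, f_new - f_old)
            np.add.at(r.sum_bb, self.v_struct, f_new**2 - f_old**2)
            np.add.at(r.sum_ab, self.v_struct,
                      r.f_tmpl[self.v_sel] * (f_new - f_old))
            r.f_def[self.v_sel] = f_new
            r.warped_verts[self.v_sel] = pos


class _Registration:
    """Mutable state for one template-to-test registration."""

    def __init__(self, template: Template, test: Volume3D, mask: BinaryMask,
                 cfg: RegistrationConfig):
        self.cfg = cfg
        self.test = test
        self.template = template
        self.use_surface = cfg.w_surf_reg > 0
        idx = np.argwhere(mask.data)
        if cfg.mask_subsample > 1:
            idx = idx[:: cfg.mask_subsample]
        self.mask_world = test.voxel_to_world(idx)
        self.test_vals = test.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        self.n_mask = len(self.test_vals)
        self.sum_t = float(self.test_vals.sum())
        self.var_t = float(self.test_vals.var())
        if self.var_t < 1e-12:
            raise ValueError("test image constant within the registration mask")
        self._tmpl_inv = np.linalg.inv(template.volume.affine)
        self._tmpl_data = np.asarray(template.volume.data, dtype=float)
        if self.use_surface:
            state = RadialSurfaceState(template.surface)
            self.n_per = template.surface.n_per_structure
            self.struct_idx = np.repeat(np.arange(3), self.n_per)
            self.f_tmpl = relative_intensity_interp(
                template.volume, state, template.surface.vertices,
                self.struct_idx, radius=cfg.ri_radius_mm,
                n_points=cfg.ri_template_points or cfg.ri_n_points,
            )
            # per-structure sums: the surface term averages the three
            # within-structure correlations
            self.sum_a = np.array([
                self.f_tmpl[self.struct_idx == k].sum() for k in range(3)])
            self.var_a = np.array([
                self.f_tmpl[self.struct_idx == k].var() for k in range(3)])
            self._var_a_all = float(self.f_tmpl.var())

    def sample_template(self, world_pts: np.ndarray) -> np.ndarray:
        vox = world_pts @ self._tmpl_inv[:3, :3].T + self._tmpl_inv[:3, 3]
        return ndimage.map_coordinates(self._tmpl_data, vox.T, order=1,
                                       mode="constant", cval=0.0)

    def refresh_surface(self) -> None:
        """Exact per-sweep refresh of the deformed surface and RI features."""
        warped_surf = apply_to_surface(self.field, self.template.surface)
        self.warped_verts = warped_surf.vertices.copy()
        self.surf_state = RadialSurfaceState(warped_surf)
        self.f_def = relative_intensity_interp(
            self.test, self.surf_state, self.warped_verts, self.struct_idx,
            radius=self.cfg.ri_radius_mm, n_points=self.cfg.ri_n_points,
        )
        self.sum_b = np.zeros(3)
        self.sum_bb = np.zeros(3)
        self.sum_ab = np.zeros(3)
        for k in range(3):
            sel = self.struct_idx == k
            self.sum_b[k] = self.f_def[sel].sum()
            self.sum_bb[k] = (self.f_def[sel] ** 2).sum()
            self.sum_ab[k] = (self.f_tmpl[sel] * self.f_def[sel]).sum()

    def surface_corr(self, sum_b, sum_bb, sum_ab) -> float:
        """Surface RI correlation from per-structure running sums."""
        if not self.cfg.per_structure_corr:
            m = 3 * self.n_per
            sb, sbb, sab = sum_b.sum(), sum_bb.sum(), sum_ab.sum()
            var_b = sbb / m - (sb / m) ** 2
            if var_b <= 1e-12 or self._var_a_all <= 1e-12:
                return 0.0
            cov = sab / m - (sb / m) * (self.sum_a.sum() / m)
            return cov / np.sqrt(var_b * self._var_a_all)
        m = self.n_per
        total = 0.0
        for k in range(3):
            var_b = sum_bb[k] / m - (sum_b[k] / m) ** 2
            if var_b > 1e-12 and self.var_a[k] > 1e-12:
                cov = sum_ab[k] / m - (sum_b[k] / m) * (self.sum_a[k] / m)
                total += cov / np.sqrt(var_b * self.var_a[k])
        return total / 3.0

    def refresh_volume(self) -> None:
        self.disp_at_mask = self.field.displacement_at(self.mask_world)
        self.warped_vals = self.sample_template(
            self.mask_world + self.disp_at_mask
        )
        self.sum_w = float(self.warped_vals.sum())
        self.sum_ww = float((self.warped_vals**2).sum())
        self.sum_wt = float((self.warped_vals * self.test_vals).sum())

    def global_cost(self) -> float:
        n = self.n_mask
        var_w = self.sum_ww / n - (self.sum_w / n) ** 2
        if var_w < 1e-12:
            raise ValueError("warped template constant within the mask")
        cov = self.sum_wt / n - (self.sum_w / n) * (self.sum_t / n)
        val = cov / np.sqrt(var_w * self.var_t)
        if self.use_surface:
            val += self.cfg.w_surf_reg * self.surface_corr(
                self.sum_b, self.sum_bb, self.sum_ab)
        self._smooth_cache = smoothness_penalty(self.field)
        return val - self.cfg.smoothness_weight * self._smooth_cache

    def active_nodes(self) -> list[tuple]:
        """Lattice nodes whose trilinear support intersects the mask."""
        g = (self.mask_world - self.field.origin) / self.field.spacing
        lo = np.floor(g).astype(int)
        nodes = set()
        for off in np.ndindex(2, 2, 2):
            pts = lo + np.array(off)
            ok = np.all((pts >= 0)
                        & (pts < np.array(self.field.disp.shape[:3])), axis=1)
            nodes.update(map(tuple, pts[ok]))
        return sorted(nodes)


def register_hybrid(
    template: Template,
    test: Volume3D,
    mask: BinaryMask,
    cfg: RegistrationConfig | None = None,
) -> tuple[DeformationField, dict]:
    """Estimate the backward deformation aligning a template to the test image.

    Returns the field and an info dict with the per-level cost trace.
    Accepted cost is monotone: the final cost is never below the initial one.
    """
    cfg = cfg or RegistrationConfig()
    if not test.same_geometry(mask):
        raise ValueError("mask geometry must match the test image")
    if not mask.data.any():
        raise ValueError("empty registration mask")
    reg = _Registration(template, test, mask, cfg)
    info = {"levels": []}
    prev_field = None
    cap_mm = CAP_FRACTION * cfg.lattice_spacings[0]
    sweeps = cfg.sweeps_per_level
    if np.isscalar(sweeps):
        sweeps = (int(sweeps),) * len(cfg.lattice_spacings)
    w_levels = cfg.w_surf_reg_per_level
    if w_levels is None:
        w_levels = (cfg.w_surf_reg,) * len(cfg.lattice_spacings)
    import dataclasses as _dc
    base_cfg = cfg
    for level_i, spacing in enumerate(cfg.lattice_spacings):
        cfg = _dc.replace(base_cfg, w_surf_reg=w_levels[level_i])
        reg.cfg = cfg
        reg.use_surface = base_cfg.w_surf_reg > 0 and cfg.w_surf_reg > 0
        field = zero_field(test, mask, spacing, cap_mm=cap_mm)
        if prev_field is not None:
            nodes = np.stack(
                np.meshgrid(*[np.arange(s) for s in field.disp.shape[:3]],
                            indexing="ij"), axis=-1
            ).reshape(-1, 3)
            world = field.origin + nodes * spacing
            d = prev_field.displacement_at(world)
            field.disp = np.clip(
                d.reshape(*field.disp.shape[:3], 3), -cap_mm, cap_mm
            )
        reg.field = field
        reg.refresh_volume()
        if reg.use_surface:
            reg.refresh_surface()
        cost = reg.global_cost()
        level_info = {"spacing": spacing, "costs": [cost]}
        active = reg.active_nodes()
        for _ in range(sweeps[level_i]):
            disp_snapshot = reg.field.disp.copy()
            for node in active:
                obj = _NodeObjective(reg, node)
                if obj.skip:
                    continue
                d0 = reg.field.disp[node].copy()
                f0 = obj(d0)
                step = 0.25 * spacing
                simplex = np.vstack([d0, d0 + np.eye(3) * step])
                res = minimize(
                    obj, d0, method="Nelder-Mead",
                    options={"maxiter": cfg.nm_maxiter,
                             "initial_simplex": simplex,
                             "xatol": 0.02, "fatol": 1e-7},
                )
                if res.fun < f0 - 1e-12 and np.abs(res.x).max() <= reg.field.cap:
                    obj.accept(res.x)
            # exact refresh once per sweep
            reg.refresh_volume()
            if reg.use_surface:
                reg.refresh_surface()
            new_cost = reg.global_cost()
            if new_cost < cost - 1e-12:
                # the sweep hurt the exact objective: revert it (keeps the
                # accepted cost monotone even under the surrogate terms)
                reg.field.disp = disp_snapshot
                reg.refresh_volume()
                if reg.use_surface:
                    reg.refresh_surface()
                reg.global_cost()
                level_info["costs"].append(cost)
                break
            gain = new_cost - cost
            cost = new_cost
            level_info["costs"].append(new_cost)
            if gain < cfg.tol:
                break
        info["levels"].append(level_info)
        prev_field = reg.field
    info["final_cost"] = cost
    info["initial_cost"] = info["levels"][0]["costs"][0]
    return reg.field, info
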