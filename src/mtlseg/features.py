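"""Vertex-wise texture features over inner/outer spherical neighbourhoods.

At each surface vertex three spherical neighbourhoods of 3, 5 and 7 mm
radius are split into an inner region (IR, voxel centers inside the
structure boundary) and an outer region (OR, outside). Per radius:

* NI (normalized intensity) = mean(IR) / SD(IR) — internal tissue homogeneity;
* RI (relative intensity)   = 2 (mean(OR) - mean(IR)) / (mean(OR) + mean(IR))
  — boundary contrast, antisymmetric in IR/OR and bounded by [-2, 2] for
  positive intensities;
* IG (intensity gradient)   = mean gradient magnitude over the whole sphere,
  from central finite differences with spacing-aware denominators (mm^-1
  intensity units).

This gives the 9-component feature vector (3 NI + 3 RI + 3 IG) used for
template selection and weighted fusion. NI uses the inner region only,
matching the printed 9-feature total. Intensities are sampled at voxel
centers; samples whose center falls outside the grid take the fill value 0
and count as outside the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .imaging import LabelVolume, STRUCTURE_CODES, STRUCTURES, Volume3D
from .mesh import CorrespondedSurface, RadialSurfaceState

RADII_MM = (3.0, 5.0, 7.0)
FEATURE_NAMES = tuple(
    f"{kind}_{int(r)}mm" for kind in ("NI", "RI", "IG") for r in RADII_MM
)
SD_FLOOR = 1e-6


@dataclass
class FeatureMatrix:
    """V_total x 9 feature array with provenance."""

    values: np.ndarray
    provenance: str  # "true" (on template) or "estimated" (on test)
    flags: np.ndarray = field(default=None)  # True where a region was empty

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 9:
            raise ValueError("feature matrix must be (V, 9)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.flags is None:
            self.flags = np.zeros(self.values.shape, dtype=bool)


@dataclass
class LibraryFeatureStats:
    """Per-vertex, per-feature mean and population SD across the library."""

    mean: np.ndarray  # (V, 9)
    sd: np.ndarray  # (V, 9), >= 0

    @property
    def floored_sd(self) -> np.ndarray:
        return np.maximum(self.sd, SD_FLOOR)


@lru_cache(maxsize=64)
def _sphere_offsets_cached(
    spacing: tuple[float, float, float], radius: float, max_samples: int | None
) -> np.ndarray:
    """Integer voxel offsets whose centers can fall within `radius` mm.

    A one-voxel margin is included because offsets are taken about the
    rounded vertex voxel; exact distance filtering happens per vertex.
    With `max_samples`, a fixed pseudo-random subset is kept so repeated
    calls are deterministic.
    """
    sp = np.asarray(spacing)
    margin = float(np.linalg.norm(sp))
    nmax = np.ceil((radius + margin) / sp).astype(int)
    ax = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(grid * sp, axis=1)
    offs = grid[d <= radius + margin]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    offs = offs[order]
    if max_samples is not None and len(offs) > max_samples:
        rng = np.random.default_rng(12345)
        keep = np.sort(rng.permutation(len(offs))[:max_samples])
        offs = offs[keep]
    offs.setflags(write=False)
    return offs


def sphere_offsets(vol, radius: float, max_samples: int | None = None) -> np.ndarray:
    return _sphere_offsets_cached(tuple(np.round(vol.spacing, 9)), float(radius),
                                  max_samples)


def grad_magnitude(vol: Volume3D) -> np.ndarray:
    """Gradient magnitude sqrt(gx^2+gy^2+gz^2) by central differences."""
    gx, gy, gz = np.gradient(vol.data, *vol.spacing)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def _gather(vol, positions, radius, max_samples):
    """Sample lattice voxel centers within `radius` mm of each position.

    Returns (indices (V,O,3), centers (V,O,3), within (V,O), ingrid (V,O)).
    """
    positions = np.atleast_2d(positions)
    offs = sphere_offsets(vol, radius, max_samples)
    vox = vol.world_to_voxel(positions)
    # half-up rounding after snapping affine-inversion noise: unlike
    # round-half-to-even this anchors the sampling window identically under
    # integer-voxel translations (e.g. cropped grids)
    base = np.floor(np.round(vox, 6) + 0.5).astype(np.int64)
    idx = base[:, None, :] + offs[None, :, :]
    # voxel centers in world mm: one small matmul + broadcast add
    offs_world = offs @ vol.affine[:3, :3].T
    base_world = vol.voxel_to_world(base)
    centers = base_world[:, None, :] + offs_world[None, :, :]
    delta = centers - positions[:, None, :]
    within = np.einsum("vok,vok->vo", delta, delta) <= radius * radius
    shape = np.asarray(vol.data.shape)
    ingrid = np.all((idx >= 0) & (idx < shape), axis=2)
    return idx, centers, within, ingrid


def _values_at(data: np.ndarray, idx: np.ndarray, ingrid: np.ndarray,
               fill: float = 0.0) -> np.ndarray:
    safe = np.clip(idx, 0, np.asarray(data.shape) - 1)
    vals = data[safe[..., 0], safe[..., 1], safe[..., 2]]
    return np.where(ingrid, vals, fill)


def _region_stats(vals, member):
    """Masked mean and population SD along axis 1; count returned too."""
    n = member.sum(axis=1)
    safe_n = np.maximum(n, 1)
    mu = np.where(member, vals, 0.0).sum(axis=1) / safe_n
    var = np.where(member, (vals - mu[:, None]) ** 2, 0.0).sum(axis=1) / safe_n
    return mu, np.sqrt(var), n


def _features_core(vol, positions, inside_fn, max_samples, grad_mag=None):
    """Shared NI/RI/IG computation.

    `inside_fn(centers (N,3), rows (N,)) -> bool (N,)` classifies sample
    voxel centers against the structure boundary of the vertex owning each
    row.
    """
    positions = np.atleast_2d(positions)
    if grad_mag is None:
        grad_mag = grad_magnitude(vol)
    v_count = len(positions)
    values = np.zeros((v_count, 9))
    flags = np.zeros((v_count, 9), dtype=bool)
    for ri, radius in enumerate(RADII_MM):
        idx, centers, within, ingrid = _gather(vol, positions, radius, max_samples)
        vals = _values_at(vol.data, idx, ingrid)
        rows = np.repeat(np.arange(v_count), idx.shape[1]).reshape(idx.shape[:2])
        inside = inside_fn(centers.reshape(-1, 3), rows.ravel()).reshape(rows.shape)
        inside = inside & ingrid  # out-of-grid samples count as outside
        ir = within & inside
        orr = within & ~inside
        mu_ir, sd_ir, n_ir = _region_stats(vals, ir)
        mu_or, _, n_or = _region_stats(vals, orr)
        # NI (inner-region homogeneity)
        ni = mu_ir / np.maximum(sd_ir, SD_FLOOR)
        empty_ir = n_ir == 0
        values[:, ri] = np.where(empty_ir, 0.0, ni)
        flags[:, ri] = empty_ir
        # RI (boundary contrast)
        denom = mu_or + mu_ir
        bad = empty_ir | (n_or == 0) | (np.abs(denom) < 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            riv = 2.0 * (mu_or - mu_ir) / denom
        values[:, 3 + ri] = np.where(bad, 0.0, riv)
        flags[:, 3 + ri] = bad
        # IG (mean gradient magnitude over the whole sphere)
        gvals = _values_at(grad_mag, idx, ingrid)
        mu_g, _, n_g = _region_stats(gvals, within)
        values[:, 6 + ri] = np.where(n_g == 0, 0.0, mu_g)
        flags[:, 6 + ri] = n_g == 0
    return values, flags


def _label_inside_fn(boundary: LabelVolume, struct_of_row: np.ndarray):
    codes = np.array([STRUCTURE_CODES[s] for s in STRUCTURES])

    def fn(centers: np.ndarray, rows: np.ndarray) -> np.ndarray:
        vox = np.rint(boundary.world_to_voxel(centers)).astype(np.int64)
        shape = np.asarray(boundary.data.shape)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        safe = np.clip(vox, 0, shape - 1)
        lab = boundary.data[safe[:, 0], safe[:, 1], safe[:, 2]]
        return ok & (lab == codes[struct_of_row[rows]])

    return fn


def _radial_inside_fn(state: RadialSurfaceState, struct_of_row: np.ndarray,
                      fast: bool = False):
    def fn(centers: np.ndarray, rows: np.ndarray) -> np.ndarray:
        out = np.zeros(len(centers), dtype=bool)
        ks = struct_of_row[rows]
        for k in range(3):
            sel = ks == k
            if sel.any():
                out[sel] = state.inside(k, centers[sel], fast=fast)
        return out

    return fn


def _structure_of_vertex(surface: CorrespondedSurface) -> np.ndarray:
    n = surface.n_per_structure
    return np.repeat(np.arange(3), n)


def compute_vertex_features(
    vol: Volume3D,
    surface: CorrespondedSurface,
    boundary: LabelVolume | RadialSurfaceState | None = None,
    max_samples_per_radius: int | None = None,
    grad_mag: np.ndarray | None = None,
    fast_inside: bool = False,
) -> FeatureMatrix:
    """'True' features: computed on a template volume along its own surface.

    `boundary` defines the inside/outside split: a LabelVolume (manual
    label) or a radial state of the surface itself (default).
    """
    if np.isnan(vol.data).any():
        raise ValueError("volume contains NaN intensities")
    struct_of = _structure_of_vertex(surface)
    if boundary is None:
        boundary = RadialSurfaceState(surface)
    if isinstance(boundary, LabelVolume):
        inside_fn = _label_inside_fn(boundary, struct_of)
    else:
        inside_fn = _radial_inside_fn(boundary, struct_of, fast=fast_inside)
    values, flags = _features_core(
        vol, surface.vertices, inside_fn, max_samples_per_radius, grad_mag
    )
    return FeatureMatrix(values=values, provenance="true", flags=flags)


def estimate_features_on_test(
    test: Volume3D,
    mapped_surface: CorrespondedSurface,
    max_samples_per_radius: int | None = None,
    grad_mag: np.ndarray | None = None,
    fast_inside: bool = False,
) -> FeatureMatrix:
    """'Estimated' features: test-image intensities along a mapped surface.

    The boundary is the mapped surface itself, queried through the radial
    inside test (the voxel-center classification its voxelization induces).
    """
    if np.isnan(test.data).any():
        raise ValueError("volume contains NaN intensities")
    struct_of = _structure_of_vertex(mapped_surface)
    state = RadialSurfaceState(mapped_surface)
    values, flags = _features_core(
        test, mapped_surface.vertices,
        _radial_inside_fn(state, struct_of, fast=fast_inside),
        max_samples_per_radius, grad_mag
    )
    return FeatureMatrix(values=values, provenance="estimated", flags=flags)


def features_at_positions(
    test: Volume3D,
    state: RadialSurfaceState,
    positions: np.ndarray,
    struct_idx: np.ndarray,
    max_samples_per_radius: int | None = None,
    grad_mag: np.ndarray | None = None,
    fast_inside: bool = False,
) -> np.ndarray:
    """Estimated features for a subset of vertices at explicit positions.

    Used by the fusion optimizers, where only a handful of vertices move per
    objective evaluation. `state` must reflect the current surface geometry.
    """
    struct_idx = np.asarray(struct_idx)
    values, _ = _features_core(
        test, positions, _radial_inside_fn(state, struct_idx, fast=fast_inside),
        max_samples_per_radius, grad_mag
    )
    return values


def relative_intensity(
    vol: Volume3D,
    state: RadialSurfaceState,
    positions: np.ndarray,
    struct_idx: np.ndarray,
    radius: float = 5.0,
    max_samples: int | None = None,
    fast_inside: bool = True,
) -> np.ndarray:
    """RI at a single radius for given vertex positions (registration term)."""
    positions = np.atleast_2d(positions)
    struct_idx = np.asarray(struct_idx)
    idx, centers, within, ingrid = _gather(vol, positions, radius, max_samples)
    vals = _values_at(vol.data, idx, ingrid)
    rows = np.repeat(np.arange(len(positions)), idx.shape[1]).reshape(idx.shape[:2])
    inside = _radial_inside_fn(state, struct_idx, fast=fast_inside)(
        centers.reshape(-1, 3), rows.ravel()
    ).reshape(rows.shape)
    inside = inside & ingrid
    mu_ir, _, n_ir = _region_stats(vals, within & inside)
    mu_or, _, n_or = _region_stats(vals, within & ~inside)
    denom = mu_or + mu_ir
    bad = (n_ir == 0) | (n_or == 0) | (np.abs(denom) < 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = 2.0 * (mu_or - mu_ir) / denom
    return np.where(bad, 0.0, ri)


@lru_cache(maxsize=8)
def _ball_points(n_points: int) -> np.ndarray:
    """Fixed quasi-uniform sample points in the unit ball, (n, 3).

    Deterministic; used by the interpolated RI variant so the sample
    pattern moves rigidly with the vertex.
    """
    rng = np.random.default_rng(987654321)
    dirs = rng.normal(size=(n_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = rng.uniform(0.0, 1.0, size=n_points) ** (1.0 / 3.0)
    pts = dirs * radii[:, None]
    pts.setflags(write=False)
    return pts


def relative_intensity_interp(
    vol: Volume3D,
    state: RadialSurfaceState,
    positions: np.ndarray,
    struct_idx: np.ndarray,
    radius: float = 5.0,
    n_points: int = 64,
    fast_inside: bool = True,
) -> np.ndarray:
    """RI from a rigidly attached ball of trilinearly interpolated samples.

    Unlike the voxel-center variant, the sample pattern moves with the
    vertex, so the feature is continuous in the vertex position — the
    property the registration optimizer needs to avoid chasing sampling
    jitter.
    """
    from scipy import ndimage as _ndimage

    positions = np.atleast_2d(positions)
    struct_idx = np.asarray(struct_idx)
    offs = _ball_points(n_points) * radius
    pts = positions[:, None, :] + offs[None, :, :]  # (V, n, 3)
    flat = pts.reshape(-1, 3)
    inv = np.linalg.inv(vol.affine)
    vox = flat @ inv[:3, :3].T + inv[:3, 3]
    vals = _ndimage.map_coordinates(vol.data, vox.T, order=1,
                                    mode="constant", cval=0.0)
    vals = vals.reshape(len(positions), n_points)
    inside = np.zeros(len(flat), dtype=bool)
    ks = np.repeat(struct_idx, n_points)
    for k in range(3):
        sel = ks == k
        if sel.any():
            inside[sel] = state.inside(k, flat[sel], fast=fast_inside)
    inside = inside.reshape(len(positions), n_points)
    n_ir = inside.sum(axis=1)
    n_or = n_points - n_ir
    mu_ir = np.where(inside, vals, 0.0).sum(axis=1) / np.maximum(n_ir, 1)
    mu_or = np.where(~inside, vals, 0.0).sum(axis=1) / np.maximum(n_or, 1)
    denom = mu_or + mu_ir
    bad = (n_ir == 0) | (n_or == 0) | (np.abs(denom) < 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = 2.0 * (mu_or - mu_ir) / denom
    return np.where(bad, 0.0, ri)


def library_feature_stats(features: list[FeatureMatrix]) -> LibraryFeatureStats:
    """Per-vertex/per-feature mean and population SD over N templates."""
    if len(features) < 2:
        raise ValueError("need at least 2 templates for library statistics")
    stack = np.stack([f.values for f in features])
    return LibraryFeatureStats(mean=stack.mean(axis=0), sd=stack.std(axis=0))
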