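"""Subset restriction and global-to-local weighted shape averaging.

After non-linear registration, the n_a warped templates are restricted to
the n_b most similar (re-scoring the hybrid similarity on warped data).
Their surfaces are then fused in two stages:

1. Global weighting — one simplex weight vector w over the subset drives
   both the vertex-coordinate average S̄ = Σ_j w_j S_j and the weighted
   feature mean/SD; w maximizes the subset similarity
   O_subset = −mean_v ||F̄_v − F̂_v(S̄)|| / σ_v via Nelder-Mead, with the
   simplex constraint enforced by the squared-softmax reparameterization
   w_j = u_j² / Σ u_k².
2. Multi-level local weighting — weights are refined per icosphere sampling
   vertex from the coarsest level l0 (42 vertices) up to l_max, each level
   interpolating the optimized sampling weights to all surface vertices
   (spherical barycentric interpolation, renormalized per vertex) and
   rebuilding the surface as a per-vertex convex combination. The level
   loop stops when the subset similarity stops improving.

The feature mean and SD are held at their global-stage weighted values
during local refinement, so local weights drive only the surface geometry.
Accepted similarity is monotone across stages by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .features import (
    SD_FLOOR,
    compute_vertex_features,
    estimate_features_on_test,
    features_at_positions,
    grad_magnitude,
)
from .imaging import LabelVolume, Volume3D, dilate_label
from .library import Template
from .mesh import (
    CorrespondedSurface,
    RadialSurfaceState,
    get_interpolator,
    icosphere,
    level_vertex_count,
    surface_to_label,
)
from .registration import DeformationField, apply_to_surface, apply_to_volume
from .selection import SelectionConfig, SelectionResult, o_surface, o_total, o_volume


@dataclass
class FusionConfig:
    l0: int = 2
    l_max: int = 5
    level_tol: float = 1e-4  # required gain in O_subset to advance a level
    nm_maxiter_global: int = 200
    nm_maxiter_local: int = 60
    max_samples_per_radius: int | None = None
    fast_inside: bool = False
    # skip the per-vertex optimization where the subset surfaces already
    # agree within this distance (mm): the blend is insensitive to the
    # weights there; 0 disables the shortcut
    local_skip_agreement_mm: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.l0 <= self.l_max):
            raise ValueError("need 1 <= l0 <= l_max")


@dataclass
class FusionWeights:
    subset_ids: list[str]
    global_weights: np.ndarray  # (n_b,) simplex
    local_levels: dict = dc_field(default_factory=dict)  # l -> (n_b, 3, m(l))
    vertex_weights: np.ndarray | None = None  # (n_b, V_total) simplex per column
    level_reached: int | None = None


@dataclass
class WarpedTemplate:
    """A template carried into test space by its deformation field."""

    id: str
    volume: Volume3D
    label: LabelVolume
    surface: CorrespondedSurface
    features: np.ndarray  # (V_total, 9) true features recomputed post-warp
    field: DeformationField


def warp_template(
    template: Template,
    field: DeformationField,
    max_samples_per_radius: int | None = None,
    fast_inside: bool = False,
) -> WarpedTemplate:
    vol_w = apply_to_volume(field, template.volume, order=1)
    lab_w = apply_to_volume(field, template.label, order=0)
    surf_w = apply_to_surface(field, template.surface)
    feats = compute_vertex_features(
        vol_w, surf_w, boundary=None,
        max_samples_per_radius=max_samples_per_radius, fast_inside=fast_inside,
    )
    return WarpedTemplate(id=template.id, volume=vol_w, label=lab_w,
                          surface=surf_w, features=feats.values, field=field)


def restrict_subset(
    warped: list[WarpedTemplate],
    test: Volume3D,
    stats,
    cfg: SelectionConfig,
    n_b: int,
) -> list[SelectionResult]:
    """Re-rank warped templates by hybrid similarity; keep the top n_b."""
    if n_b > len(warped):
        raise ValueError(f"n_b={n_b} exceeds the registered subset ({len(warped)})")
    from .features import FeatureMatrix

    gm = grad_magnitude(test)
    results = []
    for wt in warped:
        mask = dilate_label(wt.label, iterations=3)
        ov = o_volume(wt.volume, test, mask, method=cfg.volume_similarity,
                      bins=cfg.nmi_bins)
        est = estimate_features_on_test(
            test, wt.surface, max_samples_per_radius=cfg.max_samples_per_radius,
            grad_mag=gm, fast_inside=cfg.fast_inside,
        )
        osf = o_surface(FeatureMatrix(values=wt.features, provenance="true"),
                        est, stats)
        results.append(SelectionResult(id=wt.id, o_volume=ov, o_surface=osf,
                                       o_total=o_total(ov, osf, cfg.w_surface)))
    results.sort(key=lambda r: (-r.o_total, r.id))
    for rank, r in enumerate(results):
        r.rank = rank
    return results[:n_b]


def average_surfaces(
    surfaces: list[CorrespondedSurface], weights: np.ndarray
) -> CorrespondedSurface:
    """Vertex-wise convex combination of topologically identical surfaces."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"weights must sum to 1 (got {w.sum()})")
    if np.any(w < -1e-12):
        raise ValueError("weights must be non-negative")
    if len(surfaces) != len(w):
        raise ValueError("one weight per surface required")
    verts = sum(wj * s.vertices for wj, s in zip(w, surfaces))
    return surfaces[0].with_vertices(verts)


def fuse_unweighted(surfaces: list[CorrespondedSurface]) -> CorrespondedSurface:
    """Uniform-weight shape average (the non-weighted fusion baseline)."""
    n = len(surfaces)
    return average_surfaces(surfaces, np.full(n, 1.0 / n))


def blend_surfaces(
    surfaces: list[CorrespondedSurface], vertex_weights: np.ndarray
) -> CorrespondedSurface:
    """Per-vertex convex combination: vertex_weights is (n_b, V_total)."""
    vw = np.asarray(vertex_weights, dtype=float)
    verts = sum(vw[j][:, None] * s.vertices for j, s in enumerate(surfaces))
    return surfaces[0].with_vertices(verts)


def _simplex_from_u(u: np.ndarray) -> np.ndarray:
    q = u * u
    s = q.sum()
    if s < 1e-300:
        return np.full(len(u), 1.0 / len(u))
    return q / s


def weighted_feature_stats(features: np.ndarray, w: np.ndarray):
    """Weighted mean and SD of subset true features; (V, 9) each."""
    mean = np.einsum("j,jvf->vf", w, features)
    var = np.einsum("j,jvf->vf", w, (features - mean[None]) ** 2)
    return mean, np.sqrt(var)


def subset_objective(
    f_mean: np.ndarray, f_sd: np.ndarray, f_est: np.ndarray
) -> float:
    """O_subset = -mean |F̄ - F̂| / σ (higher is better, 0 is perfect)."""
    dev = np.abs(f_mean - f_est) / np.maximum(f_sd, SD_FLOOR)
    return float(-dev.mean())


def _estimate_on_surface(
    test: Volume3D, surface: CorrespondedSurface, cfg: FusionConfig,
    grad_mag: np.ndarray,
) -> np.ndarray:
    state = RadialSurfaceState(surface)
    struct_idx = np.repeat(np.arange(3), surface.n_per_structure)
    return features_at_positions(
        test, state, surface.vertices, struct_idx,
        max_samples_per_radius=cfg.max_samples_per_radius,
        grad_mag=grad_mag, fast_inside=cfg.fast_inside,
    )


def optimize_global_weights(
    subset: list[WarpedTemplate],
    test: Volume3D,
    cfg: FusionConfig,
) -> tuple[FusionWeights, float, CorrespondedSurface]:
    """Nelder-Mead over the subset simplex; deterministic (uniform init)."""
    n_b = len(subset)
    if n_b < 2:
        raise ValueError("global weighting needs n_b >= 2")
    feats = np.stack([wt.features for wt in subset])  # (n_b, V, 9)
    surfaces = [wt.surface for wt in subset]
    gm = grad_magnitude(test)

    # degenerate subset: identical templates make the objective flat in w
    # (up to SD-floor-amplified rounding); keep the uniform initialization
    spread = feats.max(axis=0) - feats.min(axis=0)
    verts_spread = max(
        np.abs(s.vertices - surfaces[0].vertices).max() for s in surfaces
    )
    if spread.max() < 1e-9 and verts_spread < 1e-9:
        w = np.full(n_b, 1.0 / n_b)
        f_mean, f_sd = weighted_feature_stats(feats, w)
        sbar = average_surfaces(surfaces, w)
        o_flat = subset_objective(
            f_mean, f_sd, _estimate_on_surface(test, sbar, cfg, gm))
        return (FusionWeights(subset_ids=[t.id for t in subset],
                              global_weights=w), o_flat, sbar)

    def objective_of(w: np.ndarray) -> float:
        sbar = average_surfaces(surfaces, w)
        f_est = _estimate_on_surface(test, sbar, cfg, gm)
        f_mean, f_sd = weighted_feature_stats(feats, w)
        return subset_objective(f_mean, f_sd, f_est)

    def neg(u: np.ndarray) -> float:
        val = objective_of(_simplex_from_u(u))
        if not np.isfinite(val):
            raise ValueError("non-finite fusion objective")
        return -val

    u0 = np.ones(n_b)
    o_init = -neg(u0)
    res = minimize(neg, u0, method="Nelder-Mead",
                   options={"maxiter": cfg.nm_maxiter_global,
                            "xatol": 1e-3, "fatol": 1e-6})
    w = _simplex_from_u(res.x)
    o_opt = -res.fun
    if o_opt <= o_init + 1e-12 + 1e-9 * abs(o_init):
        # no strict improvement: keep the uniform initialization
        w = np.full(n_b, 1.0 / n_b)
        o_opt = o_init
    weights = FusionWeights(subset_ids=[t.id for t in subset], global_weights=w)
    return weights, o_opt, average_surfaces(surfaces, w)


@lru_cache(maxsize=32)
def _nearest_sampling_vertex(level_full: int, level_coarse: int) -> np.ndarray:
    """For each full-level vertex, the index of its nearest coarse vertex.

    Coarse vertices are the prefix of the full-level ordering, so this is a
    per-structure partition of vertex indices.
    """
    dirs = icosphere(level_full).vertices
    m = level_vertex_count(level_coarse)
    coarse = dirs[:m]
    return np.argmax(dirs @ coarse.T, axis=1)


def optimize_local_weights(
    subset: list[WarpedTemplate],
    test: Volume3D,
    global_weights: FusionWeights,
    cfg: FusionConfig,
) -> tuple[CorrespondedSurface, FusionWeights, float]:
    """Coarse-to-fine per-vertex weight refinement on icosphere samplings.

    Returns the final surface, the weights (with per-level sampling weights
    and the interpolated per-vertex field), and the final O_subset value.
    """
    n_b = len(subset)
    surfaces = [wt.surface for wt in subset]
    level_full = surfaces[0].level
    n_per = surfaces[0].n_per_structure
    feats = np.stack([wt.features for wt in subset])  # (n_b, V, 9)
    gm = grad_magnitude(test)
    struct_idx = np.repeat(np.arange(3), n_per)
    verts_stack = np.stack([s.vertices for s in surfaces])  # (n_b, V, 3)

    w_g = global_weights.global_weights
    # frozen feature statistics from the global stage
    f_mean, f_sd = weighted_feature_stats(feats, w_g)
    f_sd = np.maximum(f_sd, SD_FLOOR)

    # per-vertex weight field, initialized at the global weights
    vw = np.tile(w_g[:, None], (1, 3 * n_per))  # (n_b, V_total)

    def global_objective(vw_arr: np.ndarray) -> float:
        surf = blend_surfaces(surfaces, vw_arr)
        f_est = _estimate_on_surface(test, surf, cfg, gm)
        return subset_objective(f_mean, f_sd, f_est)

    best_o = global_objective(vw)
    weights = FusionWeights(subset_ids=[t.id for t in subset],
                            global_weights=w_g)
    level_reached = None
    for level in range(cfg.l0, min(cfg.l_max, level_full) + 1):
        m = level_vertex_count(level)
        part = _nearest_sampling_vertex(level_full, level)  # (n_per,)
        interp = get_interpolator(level)
        full_dirs = icosphere(level_full).vertices
        # sampling weights start from the current per-vertex field at the
        # sampling vertices (prefix indices within each structure)
        wl = np.empty((n_b, 3, m))
        vw_trial = vw.copy()
        surf_work = blend_surfaces(surfaces, vw_trial)
        state = RadialSurfaceState(surf_work)
        work_verts = surf_work.vertices.copy()
        for k in range(3):
            wl[:, k, :] = vw_trial[:, k * n_per : k * n_per + m]
        # one deterministic sweep over structures and sampling vertices
        for k in range(3):
            for s in range(m):
                pidx = np.nonzero(part == s)[0]  # within-structure indices
                if len(pidx) == 0:
                    continue
                gidx = pidx + k * n_per
                fm = f_mean[gidx]
                fs = f_sd[gidx]
                pos_stack = verts_stack[:, gidx, :]  # (n_b, |P|, 3)
                if cfg.local_skip_agreement_mm > 0:
                    spread = np.linalg.norm(
                        pos_stack.max(axis=0) - pos_stack.min(axis=0), axis=1
                    ).max()
                    if spread < cfg.local_skip_agreement_mm:
                        continue

                def local_obj(u: np.ndarray) -> float:
                    w = _simplex_from_u(u)
                    pos = np.einsum("j,jpk->pk", w, pos_stack)
                    # update the working radial state for the moved vertices
                    state.radii[k][pidx] = np.linalg.norm(
                        pos - state.centers[k], axis=1
                    )
                    f_est = features_at_positions(
                        test, state, pos, struct_idx[gidx],
                        max_samples_per_radius=cfg.max_samples_per_radius,
                        grad_mag=gm, fast_inside=cfg.fast_inside,
                    )
                    dev = np.abs(fm - f_est) / fs
                    return float(dev.mean())

                u0 = np.sqrt(np.maximum(wl[:, k, s], 1e-12))
                f0 = local_obj(u0)
                res = minimize(local_obj, u0, method="Nelder-Mead",
                               options={"maxiter": cfg.nm_maxiter_local,
                                        "xatol": 1e-3, "fatol": 1e-6})
                if res.fun < f0 - 1e-12:
                    wl[:, k, s] = _simplex_from_u(res.x)
                # restore working state to the accepted weights
                w_acc = wl[:, k, s]
                pos = np.einsum("j,jpk->pk", w_acc, pos_stack)
                state.radii[k][pidx] = np.linalg.norm(
                    pos - state.centers[k], axis=1
                )
                work_verts[gidx] = pos
        # interpolate sampling weights to every vertex, renormalize per vertex
        vw_new = np.empty_like(vw)
        for k in range(3):
            vals = interp.interpolate(wl[:, k, :].T, full_dirs)  # (n_per, n_b)
            if vals.min() < -1e-9:
                raise ValueError("negative interpolated weight beyond tolerance")
            vals = np.clip(vals, 0.0, None)
            vals /= vals.sum(axis=1, keepdims=True)
            vw_new[:, k * n_per : (k + 1) * n_per] = vals.T
        o_new = global_objective(vw_new)
        if o_new >= best_o - 1e-12:
            vw = vw_new
            weights.local_levels[level] = wl
            level_reached = level
            gain = o_new - best_o
            best_o = max(best_o, o_new)
            if gain < cfg.level_tol:
                break
        else:  # the level did not help: keep the previous field and stop
            break
    weights.vertex_weights = vw
    weights.level_reached = level_reached
    return blend_surfaces(surfaces, vw), weights, best_o


def finalize_segmentation(
    surface: CorrespondedSurface, geometry: Volume3D
) -> LabelVolume:
    """Rasterize the fused surface; every structure must be non-empty."""
    label = surface_to_label(surface, geometry)
    from .imaging import STRUCTURE_CODES

    for name, code in STRUCTURE_CODES.items():
        if not np.any(label.data == code):
            raise ValueError(f"empty structure {name} after averaging")
    return label
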