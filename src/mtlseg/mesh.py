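"""Corresponded triangle meshes on icosphere sampling.

The package replaces spherical-harmonic parameterization with a radial
ray-cast parameterization: every structure is assumed star-shaped about its
centroid, so sampling the boundary radius along a fixed set of icosphere
directions yields shape-inherent vertex-wise correspondence across subjects
by construction.

Icosphere levels follow the standard subdivision sequence
m(l) = 10 * 4**(l-1) + 2, i.e. 12, 42, 162, 642, 2562 for l = 1..5, and the
vertex ordering is deterministic with level-l vertices forming a prefix of
the level-(l+1) ordering, which makes coarse-to-fine weight refinement
index-stable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import (
    LabelVolume,
    STRUCTURE_CODES,
    STRUCTURES,
    Volume3D,
    sample_voxel_coords,
)


def level_vertex_count(level: int) -> int:
    """Number of icosphere vertices at subdivision level l (10*4**(l-1)+2)."""
    if level < 1:
        raise ValueError("level must be >= 1")
    return 10 * 4 ** (level - 1) + 2


_COUNT_TO_LEVEL = {level_vertex_count(l): l for l in range(1, 9)}


def level_for_count(count: int) -> int:
    try:
        return _COUNT_TO_LEVEL[count]
    except KeyError:
        raise ValueError(f"{count} is not an icosphere vertex count") from None


@dataclass
class TriangleMesh:
    """Closed, outward-oriented genus-0 triangle mesh in world mm."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    structure_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.sort(e, axis=1)

    def euler_characteristic(self) -> int:
        n_e = len(np.unique(self.edges(), axis=0))
        return self.n_vertices - n_e + len(self.faces)

    def is_closed_manifold(self) -> bool:
        """Every undirected edge used by exactly two faces, once per direction."""
        if np.any(self.faces[:, 0] == self.faces[:, 1]) or np.any(
            self.faces[:, 1] == self.faces[:, 2]
        ) or np.any(self.faces[:, 2] == self.faces[:, 0]):
            return False
        e = self.edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        if not np.all(counts == 2):
            return False
        # consistent orientation: each directed edge appears exactly once
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        _, dcounts = np.unique(directed, axis=0, return_counts=True)
        return bool(np.all(dcounts == 1))

    def signed_volume(self) -> float:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def validate(self) -> None:
        if not self.is_closed_manifold():
            raise ValueError(f"mesh ({self.structure_id}) is not a closed manifold")
        if self.euler_characteristic() != 2:
            raise ValueError(
                f"mesh ({self.structure_id}) is not genus 0 "
                f"(Euler characteristic {self.euler_characteristic()})"
            )
        if self.signed_volume() <= 0:
            raise ValueError(f"mesh ({self.structure_id}) is not outward oriented")


@dataclass
class SphericalParam:
    """Unit-sphere direction per vertex plus the radial center, world mm."""

    directions: np.ndarray  # (V, 3) unit vectors
    center: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must have unit norm")


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One midpoint split, re-projected to the unit sphere.

    New vertices are appended in deterministic face/edge order so existing
    vertices keep their indices (prefix property).
    """
    verts = list(verts)
    midpoint: dict[tuple[int, int], int] = {}

    def mid(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        if key not in midpoint:
            p = verts[i] + verts[j]
            p = p / np.linalg.norm(p)
            midpoint[key] = len(verts)
            verts.append(p)
        return midpoint[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces, dtype=np.int64)


@lru_cache(maxsize=16)
def _icosphere_arrays(level: int) -> tuple[np.ndarray, np.ndarray]:
    if level < 1:
        raise ValueError("level must be >= 1")
    verts, faces = _base_icosahedron()
    for _ in range(level - 1):
        verts, faces = _subdivide(verts, faces)
    verts.setflags(write=False)
    faces.setflags(write=False)
    return verts, faces


def icosphere(level: int) -> TriangleMesh:
    """Unit icosphere with m(level) vertices and deterministic ordering."""
    verts, faces = _icosphere_arrays(level)
    return TriangleMesh(vertices=verts.copy(), faces=faces.copy())


class SphereInterpolator:
    """Spherical barycentric interpolation over a level-l icosphere.

    A target direction is located in its containing spherical triangle; the
    value is the barycentric combination of the three corner values, with
    weights obtained by central (gnomonic) projection onto the triangle
    plane — equivalently, by solving p = x_a*a + x_b*b + x_c*c and
    normalizing x to sum 1. The weights form a partition of unity and the
    interpolant reproduces corner values exactly.
    """

    def __init__(self, level: int):
        self.level = level
        verts, faces = _icosphere_arrays(level)
        self.dirs = verts
        self.faces = faces
        self._tree = cKDTree(verts)
        # vertex -> incident faces, padded with -1
        n_inc = np.zeros(len(verts), dtype=int)
        for f in faces.ravel():
            n_inc[f] += 1
        self._vert_faces = -np.ones((len(verts), n_inc.max()), dtype=np.int64)
        fill = np.zeros(len(verts), dtype=int)
        for fi, f in enumerate(faces):
            for v in f:
                self._vert_faces[v, fill[v]] = fi
                fill[v] += 1
        # per-face inverse of the corner matrix [a b c] (columns)
        mats = np.stack([verts[faces[:, k]] for k in range(3)], axis=2)  # (F,3,3)
        self._inv = np.linalg.inv(mats)

    def locate(self, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (face index, barycentric weights) per target direction."""
        t = np.atleast_2d(np.asarray(targets, dtype=float))
        norms = np.linalg.norm(t, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("target directions must lie on the unit sphere")
        t = t / norms[:, None]
        _, nearest = self._tree.query(t)
        cand = self._vert_faces[nearest]  # (N, K)
        valid = cand >= 0
        safe = np.where(valid, cand, 0)
        # weights for all candidate faces at once: (N, K, 3)
        w = np.einsum("nkij,nj->nki", self._inv[safe], t)
        s = w.sum(axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(s > 1e-12, w / s, -np.inf)
        w = np.where(valid[:, :, None], w, -np.inf)
        minw = w.min(axis=2)  # (N, K)
        best = minw.argmax(axis=1)
        rows = np.arange(len(t))
        face_idx = safe[rows, best]
        weights = w[rows, best]
        bad = minw[rows, best] < -1e-9
        if np.any(bad):  # rare: fall back to an exhaustive face search
            tb = t[bad]
            wb = np.einsum("fij,nj->nfi", self._inv, tb)
            sb = wb.sum(axis=2, keepdims=True)
            # s must be positive: a negative sum means the antipodal face
            with np.errstate(divide="ignore", invalid="ignore"):
                wb = np.where(sb > 1e-12, wb / sb, -np.inf)
            idx = wb.min(axis=2).argmax(axis=1)
            face_idx[bad] = idx
            weights[bad] = wb[np.arange(len(tb)), idx]
        weights = np.clip(weights, 0.0, None)
        weights /= weights.sum(axis=1, keepdims=True)
        return face_idx, weights

    def interpolate(self, coarse_values: np.ndarray, targets: np.ndarray) -> np.ndarray:
        vals = np.asarray(coarse_values, dtype=float)
        if len(vals) != len(self.dirs):
            raise ValueError(
                f"expected {len(self.dirs)} coarse values, got {len(vals)}"
            )
        face_idx, w = self.locate(targets)
        corners = self.faces[face_idx]  # (N, 3)
        if vals.ndim == 1:
            return (vals[corners] * w).sum(axis=1)
        return np.einsum("nk,nk...->n...", w, vals[corners])


@lru_cache(maxsize=16)
def get_interpolator(level: int) -> SphereInterpolator:
    return SphereInterpolator(level)


def interpolate_spherical(coarse_values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Interpolate per-vertex values given at a full icosphere level to targets.

    The level is inferred from the number of coarse values.
    """
    level = level_for_count(len(np.asarray(coarse_values)))
    return get_interpolator(level).interpolate(coarse_values, targets)


@dataclass
class CorrespondedSurface:
    """Concatenated [HP, AM, EC] meshes with shared icosphere topology."""

    meshes: list[TriangleMesh]
    params: list[SphericalParam]
    level: int

    def __post_init__(self) -> None:
        if len(self.meshes) != len(STRUCTURES):
            raise ValueError("expected one mesh per structure (HP, AM, EC)")
        n = level_vertex_count(self.level)
        for mesh, name in zip(self.meshes, STRUCTURES):
            if mesh.n_vertices != n:
                raise ValueError(
                    f"{name}: vertex count {mesh.n_vertices} != level "
                    f"{self.level} count {n}"
                )
            if mesh.structure_id is None:
                mesh.structure_id = name

    @property
    def n_per_structure(self) -> int:
        return level_vertex_count(self.level)

    @property
    def n_total(self) -> int:
        return 3 * self.n_per_structure

    @property
    def vertices(self) -> np.ndarray:
        """Concatenated (V_total, 3) vertex array; index = offset + within-structure."""
        return np.concatenate([m.vertices for m in self.meshes])

    def with_vertices(self, verts: np.ndarray) -> "CorrespondedSurface":
        """New surface with replaced concatenated vertices (topology kept).

        Radial centers are recomputed as per-structure vertex centroids.
        """
        verts = np.asarray(verts, dtype=float)
        n = self.n_per_structure
        meshes, params = [], []
        for k, mesh in enumerate(self.meshes):
            v = verts[k * n : (k + 1) * n]
            meshes.append(
                TriangleMesh(vertices=v, faces=mesh.faces.copy(),
                             structure_id=mesh.structure_id)
            )
            params.append(
                SphericalParam(directions=self.params[k].directions.copy(),
                               center=v.mean(axis=0))
            )
        return CorrespondedSurface(meshes=meshes, params=params, level=self.level)

    def structure_slice(self, structure: str) -> slice:
        k = STRUCTURES.index(structure)
        n = self.n_per_structure
        return slice(k * n, (k + 1) * n)

    def radii(self, k: int) -> np.ndarray:
        """Per-vertex radius of structure k about its parameterization center."""
        return np.linalg.norm(
            self.meshes[k].vertices - self.params[k].center, axis=1
        )


def concat_surface(meshes: list[TriangleMesh],
                   params: list[SphericalParam]) -> CorrespondedSurface:
    counts = {m.n_vertices for m in meshes}
    if len(counts) != 1:
        raise ValueError(f"per-structure vertex counts differ: {sorted(counts)}")
    level = level_for_count(counts.pop())
    return CorrespondedSurface(meshes=list(meshes), params=list(params), level=level)


def split_surface(surface: CorrespondedSurface) -> list[TriangleMesh]:
    return list(surface.meshes)


def label_to_surface(
    label: LabelVolume,
    structure: str,
    level: int,
    ray_step: float = 0.25,
    require_single_crossing: bool = False,
) -> tuple[TriangleMesh, SphericalParam]:
    """Radial ray-cast parameterization of a star-shaped structure.

    For every icosphere direction the boundary radius is the last
    inside->outside crossing of the binarized label along the ray from the
    structure centroid, with sub-voxel position by linear interpolation of
    the label indicator at 0.5.
    """
    mask = label.structure_mask(structure)
    if not mask.any():
        raise ValueError(f"empty structure {structure}")
    n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))[1]
    if n_comp != 1:
        raise ValueError(
            f"structure {structure} has {n_comp} 6-connected components, expected 1"
        )
    centroid_vox = np.array(ndimage.center_of_mass(mask))
    center = label.voxel_to_world(centroid_vox)[0]

    sphere = icosphere(level)
    dirs = sphere.vertices
    spacing = float(label.spacing.min())
    step = ray_step * spacing
    extent = np.linalg.norm(np.asarray(mask.shape) * label.spacing)
    t = np.arange(0.0, extent / 2 + step, step)
    pts = center[None, None, :] + t[None, :, None] * dirs[:, None, :]  # (V,T,3)
    vox = label.world_to_voxel(pts.reshape(-1, 3))
    ind = sample_voxel_coords(mask.astype(float), vox).reshape(len(dirs), len(t))

    inside = ind >= 0.5
    crossing = inside[:, :-1] & ~inside[:, 1:]
    if require_single_crossing and np.any(crossing.sum(axis=1) != 1):
        raise ValueError(f"structure {structure} is not star-shaped about its centroid")
    has = crossing.any(axis=1)
    if not np.all(has):
        raise ValueError(
            f"ray with no inside->outside crossing for structure {structure} "
            "(non-star-shaped input or centroid outside)"
        )
    # last crossing per direction
    idx = crossing.shape[1] - 1 - crossing[:, ::-1].argmax(axis=1)
    v0 = ind[np.arange(len(dirs)), idx]
    v1 = ind[np.arange(len(dirs)), idx + 1]
    frac = np.where(v0 > v1, (v0 - 0.5) / np.maximum(v0 - v1, 1e-12), 0.5)
    radii = t[idx] + frac * step

    verts = center + radii[:, None] * dirs
    mesh = TriangleMesh(vertices=verts, faces=sphere.faces, structure_id=structure)
    return mesh, SphericalParam(directions=dirs, center=center)


class RadialSurfaceState:
    """Fast inside/outside queries against a radially parameterized surface.

    A point x belongs to structure k iff ||x - c_k|| <= r_k(dir(x - c_k)),
    where r_k is the surface radius field interpolated over the icosphere.
    This is the voxel-level inside test implied by the radial
    parameterization and is shared by feature estimation, registration, and
    label synthesis.
    """

    def __init__(self, surface: CorrespondedSurface):
        self.surface = surface
        self.level = surface.level
        self.interp = get_interpolator(surface.level)
        self.centers = [np.asarray(p.center, dtype=float) for p in surface.params]
        self.radii = [surface.radii(k) for k in range(3)]

    def surface_radius(
        self, k: int, points: np.ndarray, fast: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(distance from center, interpolated surface radius) at world points.

        With ``fast=True`` the radius field is looked up at the nearest
        icosphere direction (piecewise constant) instead of the exact
        spherical barycentric interpolation — a sub-voxel approximation used
        inside optimization hot loops.
        """
        d = np.atleast_2d(points) - self.centers[k]
        dist = np.linalg.norm(d, axis=1)
        if fast:
            # nearest icosphere direction by maximal dot product (no
            # normalization needed: |d| is constant per row)
            nearest = np.argmax(d @ self.interp.dirs.T, axis=1)
            r = self.radii[k][nearest]
        else:
            safe = np.where(dist[:, None] > 1e-9,
                            d / np.maximum(dist, 1e-9)[:, None],
                            np.array([1.0, 0.0, 0.0]))
            r = self.interp.interpolate(self.radii[k], safe)
        return dist, r

    def inside(self, k: int, points: np.ndarray, fast: bool = False) -> np.ndarray:
        dist, r = self.surface_radius(k, points, fast=fast)
        return dist <= r

    def signed_radial(self, k: int, points: np.ndarray) -> np.ndarray:
        """Radial signed distance proxy: ||x-c|| - r_surf (negative inside)."""
        dist, r = self.surface_radius(k, points)
        return dist - r


def surface_to_label(
    surface: CorrespondedSurface, geometry: Volume3D | LabelVolume
) -> LabelVolume:
    """Rasterize the corresponded surface onto the geometry's voxel grid.

    A voxel center strictly inside exactly one structure gets that code;
    centers inside two or more get the structure whose boundary is nearest
    (radial unsigned distance, ties to the lowest code).
    """
    for mesh in surface.meshes:
        mesh.validate()
    state = RadialSurfaceState(surface)
    shape = geometry.data.shape
    out = np.zeros(shape, dtype=np.int16)
    # nearest-boundary distance of the currently assigned structure, per voxel
    best = np.full(shape, np.inf)
    margin = 1.5 * float(np.max(geometry.spacing))
    for k in range(3):
        mesh = surface.meshes[k]
        lo = geometry.world_to_voxel(mesh.vertices.min(axis=0) - margin)[0]
        hi = geometry.world_to_voxel(mesh.vertices.max(axis=0) + margin)[0]
        lo = np.clip(np.floor(lo).astype(int), 0, np.asarray(shape) - 1)
        hi = np.clip(np.ceil(hi).astype(int) + 1, 0, np.asarray(shape))
        grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                            indexing="ij")
        ijk = np.stack([g.ravel() for g in grids], axis=1)
        if len(ijk) == 0:
            continue
        pts = geometry.voxel_to_world(ijk)
        dist, r = state.surface_radius(k, pts)
        inside = dist < r
        if not inside.any():
            continue
        sel = ijk[inside]
        d_bound = np.abs(dist - r)[inside]
        flat = (sel[:, 0], sel[:, 1], sel[:, 2])
        take = d_bound < best[flat]
        code = STRUCTURE_CODES[STRUCTURES[k]]
        cur = out[flat]
        # assign if unclaimed, or strictly nearer boundary (ties keep lower code)
        assign = (cur == 0) | take
        upd = tuple(a[assign] for a in flat)
        out[upd] = code
        best[upd] = d_bound[assign]
    return LabelVolume(data=out, affine=geometry.affine)


def save_surface(surface: CorrespondedSurface, out_dir: str | Path,
                 prefix: str = "surface") -> None:
    """Write a 3-OBJ bundle plus a JSON sidecar with parameterization info."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar = {"level": surface.level, "structures": [], "prefix": prefix}
    for k, name in enumerate(STRUCTURES):
        mesh = surface.meshes[k]
        path = out_dir / f"{prefix}_{name}.obj"
        trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces, process=False
        ).export(str(path))
        sidecar["structures"].append(
            {
                "structure": name,
                "obj": path.name,
                "center": list(surface.params[k].center),
                "n_vertices": mesh.n_vertices,
            }
        )
    (out_dir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_surface(out_dir: str | Path, prefix: str = "surface") -> CorrespondedSurface:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{prefix}.json").read_text())
    level = sidecar["level"]
    dirs = icosphere(level).vertices
    meshes, params = [], []
    for entry in sidecar["structures"]:
        tm = trimesh.load(str(out_dir / entry["obj"]), process=False)
        meshes.append(
            TriangleMesh(vertices=np.asarray(tm.vertices),
                         faces=np.asarray(tm.faces),
                         structure_id=entry["structure"])
        )
        params.append(SphericalParam(directions=dirs,
                                     center=np.asarray(entry["center"])))
    return CorrespondedSurface(meshes=meshes, params=params, level=level)
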