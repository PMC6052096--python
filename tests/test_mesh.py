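"""Icosphere sampling, radial parameterization, and spherical interpolation."""
import numpy as np
import pytest

from mtlseg.imaging import LabelVolume
from mtlseg.library import surface_from_label
from mtlseg.mesh import (
    SphereInterpolator,
    concat_surface,
    icosphere,
    interpolate_spherical,
    label_to_surface,
    level_vertex_count,
    split_surface,
    surface_to_label,
)
from conftest import ball_label


class TestIcosphere:
    @pytest.mark.parametrize("level,count",
                             [(1, 12), (2, 42), (3, 162), (4, 642), (5, 2562)])
    def test_subdivision_vertex_counts(self, level, count):
        mesh = icosphere(level)
        assert mesh.n_vertices == level_vertex_count(level) == count
        assert mesh.euler_characteristic() == 2
        mesh.validate()

    def test_unit_radius_and_prefix_nesting(self):
        for level in (1, 2, 3):
            coarse = icosphere(level).vertices
            fine = icosphere(level + 1).vertices
            np.testing.assert_allclose(np.linalg.norm(fine, axis=1), 1.0,
                                       atol=1e-12)
            np.testing.assert_allclose(fine[: len(coarse)], coarse)

    def test_level_below_one_rejected(self):
        with pytest.raises(ValueError):
            icosphere(0)


class TestLabelToSurface:
    def test_ball_radii_within_half_voxel(self):
        mesh, param = label_to_surface(ball_label(radius_mm=6.0), "HP", level=3)
        radii = np.linalg.norm(mesh.vertices - param.center, axis=1)
        assert np.all(np.abs(radii - 6.0) < 0.5)
        mesh.validate()

    def test_ellipsoid_axis_radius(self):
        shape = (40, 32, 32)
        center = np.array([19.5, 15.5, 15.5])
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                            indexing="ij")
        q = (((grids[0] - center[0]) / 8.0) ** 2
             + ((grids[1] - center[1]) / 5.0) ** 2
             + ((grids[2] - center[2]) / 4.0) ** 2)
        lab = LabelVolume(data=np.where(q <= 1.0, 1, 0).astype(np.int16))
        mesh, param = label_to_surface(lab, "HP", level=3)
        # vertex closest to the +x axis
        dirs = (mesh.vertices - param.center)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        i = np.argmax(dirs[:, 0])
        r = np.linalg.norm(mesh.vertices[i] - param.center)
        assert abs(r - 8.0) < 0.5

    def test_disconnected_structure_rejected(self):
        data = np.zeros((32, 32, 32), dtype=np.int16)
        data[4:8, 4:8, 4:8] = 1
        data[20:24, 20:24, 20:24] = 1
        with pytest.raises(ValueError, match="components"):
            label_to_surface(LabelVolume(data=data), "HP", level=2)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            label_to_surface(ball_label(code=2), "HP", level=2)


class TestSurfaceToLabel:
    def test_sphere_volume_close_to_analytic(self, phantom):
        _, label, _ = (None, None, None)  # unused; analytic ball below
        lab = ball_label(radius_mm=5.0)
        mesh, param = label_to_surface(lab, "HP", level=4)
        # build a full corresponded surface with the two other structures as
        # small far-away balls so the rasterizer has all three structures
        full = _three_ball_label()
        surf = surface_from_label(full, level=4)
        recon = surface_to_label(surf, full)
        vol_hp = int((recon.data == 1).sum())
        assert abs(vol_hp - (4 / 3) * np.pi * 5**3) / ((4 / 3) * np.pi * 5**3) < 0.05

    def test_round_trip_dice(self):
        full = _three_ball_label()
        surf = surface_from_label(full, level=4)
        recon = surface_to_label(surf, full)
        for code in (1, 2, 3):
            m = full.data == code
            a = recon.data == code
            d = 2 * np.sum(m & a) / (m.sum() + a.sum())
            assert d >= 0.95

    def test_all_outside_gives_background(self):
        full = _three_ball_label()
        surf = surface_from_label(full, level=3)
        # shift every mesh far outside the grid
        shifted = surf.with_vertices(surf.vertices + 500.0)
        recon = surface_to_label(shifted, full)
        assert recon.data.max() == 0


def _three_ball_label() -> LabelVolume:
    shape = (48, 48, 48)
    data = np.zeros(shape, dtype=np.int16)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    for code, center, r in ((1, (14, 14, 24), 5.0), (2, (32, 14, 24), 4.0),
                            (3, (23, 34, 24), 4.5)):
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        data[d2 <= r * r] = code
    return LabelVolume(data=data)


class TestSphericalInterpolation:
    def test_partition_of_unity_and_identity(self, rng):
        interp = SphereInterpolator(2)
        targets = rng.normal(size=(300, 3))
        targets /= np.linalg.norm(targets, axis=1, keepdims=True)
        _, w = interp.locate(targets)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)
        const = interp.interpolate(np.ones(42), targets)
        np.testing.assert_allclose(const, 1.0, atol=1e-12)
        vals = rng.normal(size=42)
        at_coarse = interp.interpolate(vals, interp.dirs)
        np.testing.assert_allclose(at_coarse, vals, atol=1e-12)

    def test_matches_gnomonic_projection_oracle(self, rng):
        interp = SphereInterpolator(2)
        vals = rng.normal(size=42)
        targets = rng.normal(size=(200, 3))
        targets /= np.linalg.norm(targets, axis=1, keepdims=True)
        got = interp.interpolate(vals, targets)
        # oracle: locate the containing face by exhaustive search, project
        # the target gnomonically onto the face plane, planar barycentric
        verts, faces = interp.dirs, interp.faces
        for t, g in zip(targets, got):
            best, best_w = None, None
            for f in faces:
                a, b, c = verts[f]
                m = np.column_stack([a, b, c])
                try:
                    x = np.linalg.solve(m, t)
                except np.linalg.LinAlgError:
                    continue
                s = x.sum()
                if s < 1e-12:  # non-positive: antipodal face, not containing
                    continue
                w = x / s
                if w.min() >= -1e-9 and (best_w is None
                                         or w.min() > best_w.min()):
                    # gnomonic projection point: t / (plane scale) lies in
                    # the triangle plane with these exact barycentrics
                    best = (vals[f] * np.clip(w, 0, None)
                            / np.clip(w, 0, None).sum()).sum()
                    best_w = w
            assert best is not None
            assert abs(best - g) < 1e-8

    def test_off_sphere_direction_rejected(self):
        interp = SphereInterpolator(2)
        with pytest.raises(ValueError, match="unit sphere"):
            interp.locate(np.array([[2.0, 0.0, 0.0]]))

    def test_level_inferred_from_count(self, rng):
        vals = rng.normal(size=162)
        t = rng.normal(size=(5, 3))
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        out = interpolate_spherical(vals, t)
        assert out.shape == (5,)
        with pytest.raises(ValueError, match="icosphere vertex count"):
            interpolate_spherical(np.zeros(100), t)


class TestConcatSplit:
    def test_concat_counts_and_inverse(self):
        full = _three_ball_label()
        surf = surface_from_label(full, level=4)
        assert surf.n_total == 3 * 642
        meshes = split_surface(surf)
        again = concat_surface(meshes, surf.params)
        np.testing.assert_array_equal(again.vertices, surf.vertices)

    def test_mismatched_levels_rejected(self):
        full = _three_ball_label()
        s3 = surface_from_label(full, level=3)
        s4 = surface_from_label(full, level=4)
        with pytest.raises(ValueError, match="vertex count"):
            concat_surface([s3.meshes[0], s4.meshes[1], s4.meshes[2]],
                           [s3.params[0], s4.params[1], s4.params[2]])
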