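"""Weighted shape averaging: subset restriction, global and local weights."""
import numpy as np
import pytest

from mtlseg.fusion import (
    FusionConfig,
    FusionWeights,
    average_surfaces,
    blend_surfaces,
    finalize_segmentation,
    fuse_unweighted,
    optimize_global_weights,
    optimize_local_weights,
    restrict_subset,
    warp_template,
    weighted_feature_stats,
)
from mtlseg.imaging import Volume3D
from mtlseg.library import surface_from_label
from mtlseg.registration import zero_field
from mtlseg.selection import SelectionConfig


@pytest.fixture(scope="module")
def warped_pool(small_library):
    """Four templates 'warped' by the zero field onto a common test image."""
    test = small_library.templates[5].volume
    out = []
    for t in small_library.templates[:4]:
        fld = zero_field(test, small_library.registration_mask, 10.0)
        out.append(warp_template(t, fld, max_samples_per_radius=150,
                                 fast_inside=True))
    return test, out


class TestAverageSurfaces:
    def test_identical_surfaces_are_a_fixed_point(self, phantom, rng):
        _, _, surf = phantom
        w = rng.dirichlet(np.ones(3))
        out = average_surfaces([surf, surf, surf], w)
        np.testing.assert_allclose(out.vertices, surf.vertices, atol=1e-12)

    def test_two_spheres_average_to_intermediate_radius(self):
        from conftest import ball_label

        lab4 = ball_label(radius_mm=4.0, shape=(48, 48, 48), center=(14, 14, 24))
        lab8 = ball_label(radius_mm=8.0, shape=(48, 48, 48), center=(14, 14, 24))
        data = lab4.data.copy()
        # add AM/EC far away so a full surface can be built
        data[34:40, 10:16, 20:28] = 2
        data[10:16, 34:40, 20:28] = 3
        d8 = lab8.data.copy()
        d8[34:40, 10:16, 20:28] = 2
        d8[10:16, 34:40, 20:28] = 3
        from mtlseg.imaging import LabelVolume

        s4 = surface_from_label(LabelVolume(data=data), level=3)
        s8 = surface_from_label(LabelVolume(data=d8), level=3)
        avg = average_surfaces([s4, s8], np.array([0.5, 0.5]))
        radii = avg.radii(0)
        assert np.all(np.abs(radii - 6.0) < 0.6)  # half-voxel ray tolerance

    def test_matches_per_vertex_loop(self, small_library, rng):
        surfaces = [t.surface for t in small_library.templates[:5]]
        w = rng.dirichlet(np.ones(5))
        out = average_surfaces(surfaces, w)
        expect = np.zeros_like(out.vertices)
        for wj, s in zip(w, surfaces):
            expect += wj * s.vertices
        np.testing.assert_allclose(out.vertices, expect, atol=1e-12)

    def test_convex_hull_containment(self, small_library, rng):
        surfaces = [t.surface for t in small_library.templates[:4]]
        w = rng.dirichlet(np.ones(4))
        out = average_surfaces(surfaces, w)
        stack = np.stack([s.vertices for s in surfaces])
        assert np.all(out.vertices <= stack.max(axis=0) + 1e-9)
        assert np.all(out.vertices >= stack.min(axis=0) - 1e-9)

    def test_bad_weights_rejected(self, small_library):
        surfaces = [t.surface for t in small_library.templates[:2]]
        with pytest.raises(ValueError, match="sum to 1"):
            average_surfaces(surfaces, np.array([0.7, 0.7]))

    def test_unweighted_fusion_equals_uniform_average(self, small_library):
        surfaces = [t.surface for t in small_library.templates[:3]]
        a = fuse_unweighted(surfaces)
        b = average_surfaces(surfaces, np.full(3, 1 / 3))
        np.testing.assert_array_equal(a.vertices, b.vertices)


class TestRestrictSubset:
    def test_identity_restriction(self, small_library, warped_pool):
        test, warped = warped_pool
        cfg = SelectionConfig(n_a=4, n_b=4, max_samples_per_radius=150,
                              fast_inside=True)
        res = restrict_subset(warped, test, small_library.stats, cfg, 4)
        assert {r.id for r in res} == {w.id for w in warped}

    def test_matches_independent_recomputation(self, small_library,
                                               warped_pool):
        from mtlseg.features import FeatureMatrix, estimate_features_on_test
        from mtlseg.imaging import dilate_label
        from mtlseg.selection import o_surface, o_total, o_volume

        test, warped = warped_pool
        cfg = SelectionConfig(n_a=4, n_b=2, max_samples_per_radius=150,
                              fast_inside=True)
        res = restrict_subset(warped, test, small_library.stats, cfg, 2)
        scored = []
        for w in warped:
            ov = o_volume(w.volume, test, dilate_label(w.label, 3))
            est = estimate_features_on_test(test, w.surface,
                                            max_samples_per_radius=150,
                                            fast_inside=True)
            osf = o_surface(FeatureMatrix(values=w.features,
                                          provenance="true"),
                            est, small_library.stats)
            scored.append((w.id, o_total(ov, osf, cfg.w_surface)))
        scored.sort(key=lambda t: (-t[1], t[0]))
        assert [r.id for r in res] == [s[0] for s in scored[:2]]

    def test_oversized_request_rejected(self, small_library, warped_pool):
        test, warped = warped_pool
        cfg = SelectionConfig(n_a=4, n_b=4)
        with pytest.raises(ValueError, match="exceeds"):
            restrict_subset(warped, test, small_library.stats, cfg, 9)


class TestGlobalWeights:
    def test_identical_templates_keep_uniform_weights(self, small_library,
                                                      warped_pool):
        test, warped = warped_pool
        clones = [warped[0]] * 3
        cfg = FusionConfig(nm_maxiter_global=40, max_samples_per_radius=150,
                           fast_inside=True)
        weights, o_val, _ = optimize_global_weights(clones, test, cfg)
        np.testing.assert_allclose(weights.global_weights, 1 / 3, atol=1e-6)

    def test_matching_template_dominates(self, small_library):
        # test equals template 0's own image: weights should favour it
        test = small_library.templates[0].volume
        warped = []
        for t in small_library.templates[:3]:
            fld = zero_field(test, small_library.registration_mask, 10.0)
            warped.append(warp_template(t, fld, max_samples_per_radius=150,
                                        fast_inside=True))
        cfg = FusionConfig(nm_maxiter_global=120, max_samples_per_radius=150,
                           fast_inside=True)
        weights, _, _ = optimize_global_weights(warped, test, cfg)
        assert weights.global_weights[0] > 0.6

    def test_never_worse_than_uniform_init(self, warped_pool):
        test, warped = warped_pool
        cfg = FusionConfig(nm_maxiter_global=40, max_samples_per_radius=150,
                           fast_inside=True)
        weights, o_opt, surface = optimize_global_weights(warped, test, cfg)
        from mtlseg.features import grad_magnitude
        from mtlseg.fusion import (_estimate_on_surface, subset_objective)

        feats = np.stack([w.features for w in warped])
        u = np.full(len(warped), 1 / len(warped))
        f_mean, f_sd = weighted_feature_stats(feats, u)
        f_est = _estimate_on_surface(test, fuse_unweighted(
            [w.surface for w in warped]), cfg, grad_magnitude(test))
        o_uniform = subset_objective(f_mean, f_sd, f_est)
        assert o_opt >= o_uniform - 1e-12
        assert abs(weights.global_weights.sum() - 1.0) < 1e-9
        assert np.all(weights.global_weights >= 0)


class TestLocalWeights:
    def test_constant_weights_reproduce_global_average(self, warped_pool):
        test, warped = warped_pool
        w = np.array([0.4, 0.3, 0.2, 0.1])
        surfaces = [x.surface for x in warped]
        global_avg = average_surfaces(surfaces, w)
        vw = np.tile(w[:, None], (1, surfaces[0].n_total))
        blended = blend_surfaces(surfaces, vw)
        np.testing.assert_allclose(blended.vertices, global_avg.vertices,
                                   atol=1e-12)

    def test_local_refinement_is_monotone_and_on_simplex(self, warped_pool):
        test, warped = warped_pool
        cfg = FusionConfig(l0=2, l_max=2, nm_maxiter_global=30,
                           nm_maxiter_local=12, max_samples_per_radius=100,
                           fast_inside=True)
        gweights, o_global, _ = optimize_global_weights(warped, test, cfg)
        surface, weights, o_local = optimize_local_weights(
            warped, test, gweights, cfg)
        assert o_local >= o_global - 1e-9
        vw = weights.vertex_weights
        assert np.all(vw >= -1e-12)
        np.testing.assert_allclose(vw.sum(axis=0), 1.0, atol=1e-9)
        # averaged surface within the convex hull of inputs, per vertex
        stack = np.stack([w.surface.vertices for w in warped])
        assert np.all(surface.vertices <= stack.max(axis=0) + 1e-9)
        assert np.all(surface.vertices >= stack.min(axis=0) - 1e-9)

    def test_chimera_test_image_splits_weights_spatially(self, small_library):
        """A test image stitched from two templates pulls local weights
        towards the matching template on each side."""
        ta, tb = small_library.templates[0], small_library.templates[1]
        cut = 30  # x-voxel where the two template images are joined
        data = ta.volume.data.copy()
        data[cut:] = tb.volume.data[cut:]
        test = Volume3D(data=data, affine=ta.volume.affine)
        warped = []
        for t in (ta, tb):
            fld = zero_field(test, small_library.registration_mask, 10.0)
            warped.append(warp_template(t, fld, max_samples_per_radius=150,
                                        fast_inside=True))
        cfg = FusionConfig(l0=2, l_max=2, nm_maxiter_global=40,
                           nm_maxiter_local=40, max_samples_per_radius=150,
                           fast_inside=True)
        gw = FusionWeights(subset_ids=[ta.id, tb.id],
                           global_weights=np.array([0.5, 0.5]))
        surface, weights, _ = optimize_local_weights(warped, test, gw, cfg)
        vw = weights.vertex_weights  # (2, V)
        verts = warped[0].surface.vertices
        a_side = verts[:, 0] < cut - 2
        b_side = verts[:, 0] > cut + 2
        assert vw[0][a_side].mean() > 0.5
        assert vw[0][b_side].mean() < 0.5


class TestFinalize:
    def test_truth_surface_rasterizes_accurately(self, phantom):
        vol, label, surf = phantom
        out = finalize_segmentation(surf, vol)
        from mtlseg.evaluation import dice_report

        rep = dice_report(label, out)
        assert rep["mean"] >= 0.95

    def test_empty_structure_rejected(self, phantom):
        vol, _, surf = phantom
        shrunk = surf.with_vertices(surf.vertices * 1e-6)
        with pytest.raises((ValueError, RuntimeError)):
            finalize_segmentation(shrunk, vol)


class TestWeightedFeatureStats:
    def test_degenerate_weight_recovers_single_template(self, rng):
        feats = rng.normal(size=(3, 7, 9))
        w = np.array([0.0, 1.0, 0.0])
        mean, sd = weighted_feature_stats(feats, w)
        np.testing.assert_allclose(mean, feats[1], atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-9)

    def test_matches_loop(self, rng):
        feats = rng.normal(size=(4, 5, 9))
        w = rng.dirichlet(np.ones(4))
        mean, sd = weighted_feature_stats(feats, w)
        for v in range(5):
            for f in range(9):
                cell = feats[:, v, f]
                m = (w * cell).sum()
                s = np.sqrt((w * (cell - m) ** 2).sum())
                assert abs(mean[v, f] - m) < 1e-12
                assert abs(sd[v, f] - s) < 1e-12
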