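"""Boundary-weighted non-linear registration: costs, fields, recovery."""
import numpy as np
import pytest

from mtlseg.imaging import BinaryMask, LabelVolume, Volume3D, dilate_label
from mtlseg.library import build_template
from mtlseg.registration import (
    DeformationField,
    RegistrationConfig,
    apply_to_surface,
    apply_to_volume,
    forward_map,
    o_surf_reg,
    o_vol_reg,
    register_hybrid,
    smoothness_penalty,
    zero_field,
)
from mtlseg.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="module")
def template():
    vol, lab, surf = make_phantom(PhantomSpec(level=3), seed=7)
    return build_template("t0", vol, lab, level=3, surface=surf,
                          max_samples_per_radius=150, fast_inside=True,
                          check_voxelization=False)


@pytest.fixture(scope="module")
def reg_mask(template):
    return dilate_label(template.label, 5)


def _translated(template, dx=2):
    """Test image/label: the template translated +dx voxels along x."""
    v, l = template.volume, template.label
    data = np.zeros_like(v.data)
    data[dx:, :, :] = v.data[:-dx, :, :]
    lab = np.zeros_like(l.data)
    lab[dx:, :, :] = l.data[:-dx, :, :]
    return (Volume3D(data=data, affine=v.affine),
            LabelVolume(data=lab, affine=l.affine))


class TestCosts:
    def test_vol_reg_identity_and_offset_invariance(self, template, reg_mask):
        v = template.volume
        assert abs(o_vol_reg(v, v, reg_mask) - 1.0) < 1e-12
        shifted = Volume3D(data=v.data + 42.0, affine=v.affine)
        assert abs(o_vol_reg(shifted, v, reg_mask) - 1.0) < 1e-12

    def test_vol_reg_matches_covariance_oracle(self, reg_mask, rng):
        shape = reg_mask.data.shape
        a = Volume3D(data=rng.normal(size=shape))
        b = Volume3D(data=rng.normal(size=shape))
        got = o_vol_reg(a, b, reg_mask)
        x, y = a.data[reg_mask.data], b.data[reg_mask.data]
        assert abs(got - np.corrcoef(x, y)[0, 1]) < 1e-10

    def test_surf_reg_correlation_limits(self, rng):
        f = rng.normal(size=200)
        assert abs(o_surf_reg(f, f) - 1.0) < 1e-12
        assert abs(o_surf_reg(f, -f) + 1.0) < 1e-12
        g = rng.normal(size=200)
        assert abs(o_surf_reg(f, g) - np.corrcoef(f, g)[0, 1]) < 1e-12
        with pytest.raises(ValueError, match="variance"):
            o_surf_reg(f, np.zeros(200))

    def test_smoothness_zero_for_constant_fields(self, template, reg_mask):
        fld = zero_field(template.volume, reg_mask, 8.0)
        assert smoothness_penalty(fld) == 0.0
        fld.disp[...] = 1.7  # constant displacement: zero Laplacian
        assert smoothness_penalty(fld) < 1e-24

    def test_smoothness_matches_per_node_loop(self, template, reg_mask, rng):
        fld = zero_field(template.volume, reg_mask, 8.0)
        fld.disp = rng.normal(0, 1, size=fld.disp.shape)
        got = smoothness_penalty(fld)
        d = fld.disp
        acc = 0.0
        for i in range(d.shape[0]):
            for j in range(d.shape[1]):
                for k in range(d.shape[2]):
                    lap = np.zeros(3)
                    for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        ni, nj, nk = i + off[0], j + off[1], k + off[2]
                        if (0 <= ni < d.shape[0] and 0 <= nj < d.shape[1]
                                and 0 <= nk < d.shape[2]):
                            lap += d[ni, nj, nk] - d[i, j, k]
                    acc += (lap**2).sum()
        assert abs(got - acc / np.prod(d.shape[:3])) < 1e-10


class TestFieldApplication:
    def test_zero_field_is_identity(self, template, reg_mask):
        fld = zero_field(template.volume, reg_mask, 8.0)
        out = apply_to_volume(fld, template.volume)
        np.testing.assert_array_equal(out.data, template.volume.data)
        surf = apply_to_surface(fld, template.surface)
        np.testing.assert_array_equal(surf.vertices,
                                      template.surface.vertices)

    def test_constant_field_moves_surface_oppositely(self, template, reg_mask):
        fld = zero_field(template.volume, reg_mask, 8.0)
        fld.disp[..., 0] = 2.0  # backward map: sample template at x + 2
        surf = apply_to_surface(fld, template.surface)
        shift = surf.vertices - template.surface.vertices
        np.testing.assert_allclose(shift[:, 0], -2.0, atol=1e-6)
        np.testing.assert_allclose(shift[:, 1:], 0.0, atol=1e-6)

    def test_forward_backward_composition_residual(self, template, reg_mask,
                                                   rng):
        fld = zero_field(template.volume, reg_mask, 8.0)
        cap = fld.cap
        fld.disp = rng.uniform(-cap, cap, size=fld.disp.shape)
        pts = template.surface.vertices
        fwd, n_fail = forward_map(fld, pts)
        assert n_fail == 0
        back = fwd + fld.displacement_at(fwd)
        assert np.max(np.linalg.norm(back - pts, axis=1)) < 0.05

    def test_capped_field_has_positive_jacobian(self, template, reg_mask, rng):
        fld = zero_field(template.volume, reg_mask, 8.0)
        cap = fld.cap
        fld.disp = rng.uniform(-cap, cap, size=fld.disp.shape)
        # sample the Jacobian of x -> x + d(x) on a grid by finite differences
        pts = template.volume.voxel_to_world(
            np.argwhere(reg_mask.data)[::53])
        h = 0.25
        eye = np.eye(3)
        for p in pts:
            J = np.zeros((3, 3))
            for ax in range(3):
                dp = fld.displacement_at(p + h * eye[ax])[0]
                dm = fld.displacement_at(p - h * eye[ax])[0]
                J[:, ax] = (dp - dm) / (2 * h)
            assert np.linalg.det(np.eye(3) + J) > 0


class TestRegisterHybrid:
    def test_identity_configuration_stays_put(self, template, reg_mask):
        cfg = RegistrationConfig(lattice_spacings=(8.0,), sweeps_per_level=1,
                                 nm_maxiter=16, max_ri_samples=60)
        fld, info = register_hybrid(template, template.volume, reg_mask, cfg)
        assert fld.max_displacement() < 0.2
        assert info["final_cost"] >= info["initial_cost"] - 1e-9

    def test_translation_recovery_within_half_mm(self, template):
        test, lab = _translated(template, dx=2)
        mask = dilate_label(lab, 5)
        cfg = RegistrationConfig(lattice_spacings=(8.0,), sweeps_per_level=3,
                                 nm_maxiter=24)
        fld, info = register_hybrid(template, test, mask, cfg)
        d = fld.displacement_at(test.voxel_to_world(np.argwhere(mask.data)))
        err = np.linalg.norm(d.mean(axis=0) - np.array([-2.0, 0.0, 0.0]))
        assert err < 0.5
        # accepted cost is monotone across sweeps
        costs = info["levels"][0]["costs"]
        assert all(b >= a - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_volume_only_reduction(self, template):
        # w_surf_reg = 0 must run the pure intensity-driven registration
        test, lab = _translated(template, dx=2)
        mask = dilate_label(lab, 5)
        cfg = RegistrationConfig(w_surf_reg=0.0, lattice_spacings=(8.0,),
                                 sweeps_per_level=2, nm_maxiter=24)
        fld, info = register_hybrid(template, test, mask, cfg)
        d = fld.displacement_at(test.voxel_to_world(np.argwhere(mask.data)))
        assert d.mean(axis=0)[0] < -1.0  # moves towards the translation
        assert info["final_cost"] >= info["initial_cost"]

    def test_empty_mask_rejected(self, template):
        empty = BinaryMask(data=np.zeros(template.volume.shape, dtype=bool))
        with pytest.raises(ValueError):
            register_hybrid(template, template.volume, empty,
                            RegistrationConfig())


class TestWarpedLabelGain:
    def test_registration_improves_template_label_overlap(self, template):
        """Warping another subject's template towards a test raises Dice."""
        from mtlseg.evaluation import dice_report

        cfg = RegistrationConfig(lattice_spacings=(10.0,), sweeps_per_level=2,
                                 nm_maxiter=12, max_ri_samples=32,
                                 mask_subsample=2)
        gains = []
        for seed in (21, 22, 23):
            vol, lab, surf = make_phantom(PhantomSpec(level=3), seed=seed)
            other = build_template(f"s{seed}", vol, lab, level=3, surface=surf,
                                   max_samples_per_radius=150,
                                   fast_inside=True, check_voxelization=False)
            union = LabelVolume(
                data=np.maximum(lab.data, template.label.data),
                affine=lab.affine)
            mask = dilate_label(union, 5)
            fld, _ = register_hybrid(other, template.volume, mask, cfg)
            warped = apply_to_volume(fld, other.label, order=0)
            pre = dice_report(template.label, other.label)["mean"]
            post = dice_report(template.label, warped)["mean"]
            gains.append(post - pre)
        assert np.mean(gains) > 0
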