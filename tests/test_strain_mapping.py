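"""Alignment, registration QC, and deformation-gradient decomposition."""

import numpy as np
import pytest

from tibmech.strain_mapping import (
    SQRT3,
    deformation_gradient,
    dice,
    dice_qc,
    initial_align,
    midplane_maps,
    register,
)
from tibmech.synthetic_data import (
    SyntheticSpec,
    apply_deformation,
    compaction_band,
    generate_section,
    rotation_about_z,
)


@pytest.fixture(scope="module")
def dvc_section():
    spec = SyntheticSpec(
        grid_shape=(48, 48, 48), spacing=0.0725, target_bvtv=0.25,
        cortical_thickness=0.4, noise_sd=15.0, seed=2,
    )
    return generate_section(spec)


class TestDice:
    def test_identical_masks(self):
        a = np.zeros((5, 5, 5), bool)
        a[1:3] = True
        assert dice(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[:2], b[1:3] = True, True  # equal size, overlap half
        assert dice(a, b) == 0.5

    def test_symmetry(self, rng):
        a = rng.random((6, 6, 6)) > 0.5
        b = rng.random((6, 6, 6)) > 0.5
        assert dice(a, b) == dice(b, a)
        assert dice_qc(a, b) == dice(a, b)

    def test_both_empty_undefined(self):
        z = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError, match="empty"):
            dice(z, z)


class TestInitialAlign:
    def test_identity_zero_angle_dice_one(self, dvc_section):
        vol, _ = dvc_section
        _, angle, trace = initial_align(vol, vol, angle_range=(-20, 20))
        assert angle == 0.0
        assert trace["best_dice"] > 0.99

    def test_constructed_rotation_recovered_within_one_degree(self, dvc_section):
        vol, _ = dvc_section
        n = vol.shape[1]
        c = (n * vol.spacing / 2, n * vol.spacing / 2, 0.0)
        post = apply_deformation(vol, rotation_about_z(15.0, center=c))
        _, angle, trace = initial_align(vol, post, angle_range=(-180, 180), angle_step=1.0)
        assert abs(abs(angle) - 15.0) <= 1.0
        assert trace["best_dice"] > 0.8

    def test_disjoint_content_low_confidence_flag(self):
        from tibmech.volumes import DensityVolume

        # ring vs central rod: same centre of gravity, no overlap at any
        # rotation about the vertical axis
        yy, xx = np.mgrid[0:24, 0:24]
        r = np.hypot(yy - 11.5, xx - 11.5)
        a = np.where((r > 8) & (r < 11), 700.0, 0.0) * np.ones((24, 1, 1))
        b = np.where(r < 3, 700.0, 0.0) * np.ones((24, 1, 1))
        _, _, trace = initial_align(
            DensityVolume(a, 0.1), DensityVolume(b, 0.1), angle_range=(-20, 20)
        )
        assert trace["low_confidence"]

    def test_all_background_rejected(self):
        from tibmech.volumes import DensityVolume

        z = DensityVolume(np.zeros((16, 16, 16)), 0.1)
        with pytest.raises(ValueError, match="background"):
            initial_align(z, z)


class TestDeformationGradient:
    def test_zero_displacement(self):
        u = np.zeros((5, 5, 5, 3))
        fld = deformation_gradient(u, 0.5)
        assert np.abs(fld.F - np.eye(3)).max() == 0.0
        np.testing.assert_allclose(fld.J, 1.0)
        np.testing.assert_allclose(fld.F_iso_norm, SQRT3)

    def test_uniform_dilation(self):
        alpha = 0.03
        n = 7
        ax = np.arange(n) * 0.5
        gz, gy, gx = np.meshgrid(ax, ax, ax, indexing="ij")
        u = alpha * np.stack([gx, gy, gz], axis=-1)
        fld = deformation_gradient(u, 0.5)
        assert np.abs(fld.F - (1 + alpha) * np.eye(3)).max() < 1e-12
        np.testing.assert_allclose(fld.J, (1 + alpha) ** 3, rtol=1e-12)
        np.testing.assert_allclose(fld.F_iso_norm, SQRT3, rtol=1e-12)

    def test_simple_shear(self):
        gamma = 0.2
        n = 7
        ax = np.arange(n) * 0.5
        gz, gy, gx = np.meshgrid(ax, ax, ax, indexing="ij")
        u = np.zeros((n, n, n, 3))
        u[..., 0] = gamma * gy  # u_x = gamma * y
        fld = deformation_gradient(u, 0.5)
        np.testing.assert_allclose(fld.J, 1.0, atol=1e-12)
        np.testing.assert_allclose(fld.F_iso_norm, np.sqrt(3 + gamma**2), rtol=1e-12)

    def test_unimodularity_random_fields(self, rng):
        # smooth random admissible displacement: det(J^(-1/3) F) = 1 to 1e-9
        from scipy.ndimage import gaussian_filter

        n = 22  # > 10^4 cells
        u = np.stack(
            [gaussian_filter(rng.normal(0, 0.3, (n, n, n)), 3.0) for _ in range(3)], axis=-1
        )
        fld = deformation_gradient(u, 1.0)
        assert fld.valid.sum() >= 10_000
        Ft = fld.F * np.where(fld.valid, fld.J, 1.0)[..., None, None] ** (-1 / 3)
        det_iso = np.linalg.det(Ft[fld.valid])
        np.testing.assert_allclose(det_iso, 1.0, atol=1e-9)

    def test_norm_bounded_below_by_sqrt3(self, rng):
        from scipy.ndimage import gaussian_filter

        u = np.stack(
            [gaussian_filter(rng.normal(0, 0.2, (12, 12, 12)), 2.0) for _ in range(3)], axis=-1
        )
        fld = deformation_gradient(u, 1.0)
        assert np.nanmin(fld.F_iso_norm) >= SQRT3 - 1e-12

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            deformation_gradient(np.zeros((2, 5, 5, 3)), 1.0)


class TestMidplaneMaps:
    def test_uniform_field_constant_maps(self):
        u = np.zeros((6, 6, 6, 3))
        fld = deformation_gradient(u, 1.0)
        J, N = midplane_maps(fld)
        np.testing.assert_allclose(J, 1.0)
        np.testing.assert_allclose(N, SQRT3)

    def test_band_visible_at_true_height(self):
        # analytic band displacement evaluated on the cell grid
        n, h = 12, 12.0
        band = compaction_band(center_mm=h / 2, width_mm=3.0, shortening_mm=0.3)
        ax = (np.arange(n) + 0.5) * 1.0
        gz, gy, gx = np.meshgrid(ax, ax, ax, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1)
        u = band.displacement(centers)
        fld = deformation_gradient(u, 1.0, centers)
        k_band = n // 2
        J_mid, _ = midplane_maps(fld, plane_index=k_band)
        J_out, _ = midplane_maps(fld, plane_index=1)
        assert J_mid.mean() < 0.95 < J_out.mean()

    def test_plane_outside_volume_rejected(self):
        fld = deformation_gradient(np.zeros((6, 6, 6, 3)), 1.0)
        with pytest.raises(ValueError, match="outside"):
            midplane_maps(fld, plane_index=10)

    def test_hfe_and_dvc_maps_share_grid_shape(self, iso_material):
        from tibmech.hfe import build_hex_mesh, solve_compression

        mesh = build_hex_mesh(np.ones((12, 12, 12), bool), spacing=0.5,
                              sample_height=6.0, max_elem=1.0)
        sol = solve_compression(mesh, [iso_material] * mesh.n_elements,
                                prescribed_disp=0.01, n_increments=2)
        Jh, Nh = midplane_maps(sol)
        assert Jh.shape == mesh.grid_shape[1:]
        assert np.isfinite(Nh).all()


class TestRegister:
    def test_identity_near_zero_field(self, dvc_section):
        vol, _ = dvc_section
        res = register(vol, vol, grid_spacing=0.87, bspline_iterations=15)
        assert np.abs(res.displacement).max() < vol.spacing / 10
        assert res.dice_bspline > 0.99
        # grid spacing recorded and respected
        assert res.grid_spacing == 0.87

    def test_pure_translation_recovered(self, dvc_section):
        from tibmech.synthetic_data import GroundTruthDeformation

        vol, _ = dvc_section
        shift = np.array([0.15, -0.1, 0.2])
        tr = GroundTruthDeformation(
            displacement=lambda p: np.broadcast_to(shift, p.shape).copy(),
            inverse_map=lambda p: p - shift,
            gradient=lambda p: np.broadcast_to(np.eye(3), p.shape[:-1] + (3, 3)).copy(),
            description="translation",
        )
        post = apply_deformation(vol, tr)
        res = register(vol, post, grid_spacing=0.87, bspline_iterations=25)
        err = np.abs(res.displacement - shift)
        # rigid stage absorbs the shift; residual B-spline error under a voxel
        assert np.median(err) < vol.spacing


class TestAffineFieldProperty:
    """Central differences are exact on affine displacement fields."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _grid(n=6, h=0.8):
        ax = np.arange(n) * h
        gz, gy, gx = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1), h

    @given(
        A=st.lists(st.floats(-0.05, 0.05), min_size=9, max_size=9).map(
            lambda v: np.array(v).reshape(3, 3)
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_displacement_recovers_gradient(self, A):
        pts, h = self._grid()
        u = pts @ A.T  # u_i = A_ij x_j
        fld = deformation_gradient(u, h)
        F_expect = np.eye(3) + A
        assert np.abs(fld.F - F_expect).max() < 1e-10
        if np.linalg.det(F_expect) > 0:
            assert fld.valid.all()
            Ft = fld.F * fld.J[..., None, None] ** (-1.0 / 3.0)
            assert np.abs(np.linalg.det(Ft) - 1.0).max() < 1e-9
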