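"""Meshing, material mapping, and the elastoplastic compression solver."""

import numpy as np
import pytest

from tibmech._fabric import FabricTensor, mil_fabric
from tibmech._material import MaterialParams, make_material, mandel_rotation, stiffness_matrix
from tibmech.hfe import (
    build_hex_mesh,
    export_vtk,
    hfe_structural,
    map_element_properties,
    solve_compression,
)
from tibmech.image_analysis import segment_three_phase


def cube_mesh(n_vox=8, height=1.0):
    return build_hex_mesh(np.ones((n_vox,) * 3, bool), spacing=height / n_vox,
                          sample_height=height)


class TestBuildHexMesh:
    def test_section_height_ceiling_rule(self):
        # 30.6 mm at a 1.27 mm cap: 25 layers of 1.224 mm (in 1.20-1.25 mm)
        mesh = build_hex_mesh(np.ones((30, 10, 10), bool), spacing=1.02, sample_height=30.6)
        assert mesh.n_layers == 25
        assert mesh.edge == pytest.approx(1.224)
        assert 1.20 <= mesh.edge <= 1.25
        assert mesh.height == pytest.approx(30.6)

    def test_single_layer(self):
        mesh = build_hex_mesh(np.ones((8, 8, 8), bool), spacing=0.125, sample_height=1.0)
        assert mesh.n_layers == 1
        assert mesh.edge == pytest.approx(1.0)

    def test_full_cuboid_element_count(self):
        # 10 x 10 x 25 elements from a full mask
        mesh = build_hex_mesh(
            np.ones((50, 20, 20), bool), spacing=0.5, sample_height=25.0, max_elem=1.0
        )
        assert mesh.grid_shape == (25, 10, 10)
        assert mesh.n_elements == 2500

    def test_occupancy_threshold_drops_empty_elements(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[:, :8, :8] = True  # half the cross-section
        mesh = build_hex_mesh(mask, spacing=0.25, sample_height=4.0, max_elem=1.0)
        assert mesh.n_elements == 4 * 2 * 2

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError):
            build_hex_mesh(np.ones((8, 8, 8), bool), spacing=0.1, sample_height=0.0)

    def test_vtk_export_text(self, tmp_path):
        mesh = cube_mesh()
        p = tmp_path / "mesh.vtk"
        export_vtk(p, mesh, {"rho": np.ones(mesh.n_elements)})
        txt = p.read_text()
        assert "UNSTRUCTURED_GRID" in txt and "SCALARS rho" in txt


class TestFabricTensor:
    def test_horizontal_plates_smallest_eigenvalue_vertical(self):
        mask = np.zeros((60, 60, 60), bool)
        for z0 in range(0, 60, 10):
            mask[z0 : z0 + 2] = True
        fab = mil_fabric(mask, spacing=0.1)
        assert abs(fab.eigenvectors[2, 0]) > 0.99  # m1 axis is z

    def test_rotation_equivariance_90deg(self):
        from scipy import ndimage

        rng = np.random.default_rng(1)
        f = ndimage.gaussian_filter(rng.standard_normal((72, 72, 72)), (5.0, 2.5, 2.5))
        an = f > np.quantile(f, 0.75)
        fa = mil_fabric(an, spacing=0.1, radius_vox=30)
        fb = mil_fabric(np.rot90(an, axes=(0, 2)), spacing=0.1, radius_vox=30)
        np.testing.assert_allclose(fa.eigenvalues, fb.eigenvalues, rtol=0.05)
        # principal axis maps z -> x under the 90 degree rotation
        assert abs(fa.eigenvectors[2, 2]) > 0.95
        assert abs(fb.eigenvectors[0, 2]) > 0.95

    def test_solid_content_isotropic_fallback(self):
        fab = mil_fabric(np.ones((20, 20, 20), bool), spacing=0.1)
        assert fab.isotropic_fallback
        np.testing.assert_allclose(fab.M, np.eye(3))

    def test_eigenvalues_normalized_to_mean_one(self, small_section):
        vol, truth = small_section
        fab = mil_fabric(truth.bone_mask, vol.spacing, domain_mask=truth.interior_mask)
        assert fab.eigenvalues.sum() == pytest.approx(3.0)
        assert fab.degree_of_anisotropy >= 1.0


class TestMaterialModel:
    def test_rho_one_isotropic_stiffness_scaling(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        C = stiffness_matrix(1.0, fab, params)
        S = np.linalg.inv(C)
        assert 1.0 / S[0, 0] == pytest.approx(params.stiffness_scale * params.E0)

    def test_density_power_law(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        C1 = stiffness_matrix(0.25, fab, params)
        C2 = stiffness_matrix(0.5, fab, params)
        np.testing.assert_allclose(C2, C1 * 2**params.k, rtol=1e-12)

    def test_rho_floor_flagged(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        m = make_material(0.001, fab, params)
        assert "rho_floored" in m.flags
        assert m.rho == params.rho_min

    def test_stiffness_spd_and_orthotropic_in_fabric_frame(self, params, rng):
        M = np.diag([0.7, 1.0, 1.3])
        fab = FabricTensor.from_matrix(M)
        C = stiffness_matrix(0.4, fab, params)
        w = np.linalg.eigvalsh(C)
        assert w.min() > 0
        # in the fabric eigenframe: no normal-shear coupling
        R6 = mandel_rotation(fab.eigenvectors)
        C_eig = R6.T @ C @ R6
        assert np.abs(C_eig[:3, 3:]).max() < 1e-8 * np.abs(C_eig).max()

    def test_mandel_rotation_orthogonal(self, rng):
        from scipy.spatial.transform import Rotation

        R6 = mandel_rotation(Rotation.random(random_state=3).as_matrix())
        np.testing.assert_allclose(R6 @ R6.T, np.eye(6), atol=1e-12)


class TestMapElementProperties:
    def test_solid_bone_element(self, params):
        from tibmech.volumes import LabelVolume

        shape = (24, 24, 24)
        labels = LabelVolume(
            2 * np.ones(shape, np.uint8), np.ones(shape, bool),
            np.ones(shape, bool), np.zeros(shape, bool), 0.25,
        )
        mesh = build_hex_mesh(np.ones(shape, bool), spacing=0.25, sample_height=6.0, max_elem=6.0)
        mats = map_element_properties(labels, mesh, params)
        assert all(m.rho == pytest.approx(1.0) for m in mats)
        ref = stiffness_matrix(1.0, FabricTensor.isotropic(fallback=False), params)
        np.testing.assert_allclose(mats[0].C, ref, rtol=1e-9)

    def test_empty_region_floored_and_flagged(self, params):
        from tibmech.volumes import LabelVolume

        shape = (24, 24, 24)
        labels = LabelVolume(
            np.zeros(shape, np.uint8), np.ones(shape, bool),
            np.zeros(shape, bool), np.ones(shape, bool), 0.25,
        )
        mesh = build_hex_mesh(np.ones(shape, bool), spacing=0.25, sample_height=6.0, max_elem=6.0)
        mats = map_element_properties(labels, mesh, params)
        assert all(m.rho == params.rho_min for m in mats)
        assert all("rho_floored" in m.flags for m in mats)


class TestSolveCompression:
    def test_single_element_elastic_stiffness_exact(self, iso_material):
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.002,
                                n_increments=4, bc_mode="frictionless")
        E = 1.0 / np.linalg.inv(iso_material.C)[0, 0]
        k_fe = sol.curve.force[-1] / sol.curve.displacement[-1] * 1000.0  # N/mm
        assert k_fe == pytest.approx(E * mesh.edge, rel=5e-3)

    def test_single_element_plastic_plateau_exact(self, iso_material, params):
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.05,
                                n_increments=25, bc_mode="frictionless")
        sigma_y = params.strength_scale * params.sigma0
        assert sol.curve.force[-1] * 1000.0 == pytest.approx(sigma_y * mesh.edge**2, rel=1e-6)

    def test_zero_displacement_zero_reaction(self, iso_material):
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.0, n_increments=3)
        np.testing.assert_allclose(sol.curve.force, 0.0, atol=1e-12)

    def test_bonded_at_least_as_stiff_as_frictionless(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        mesh = build_hex_mesh(np.ones((16, 16, 16), bool), spacing=0.25,
                              sample_height=4.0, max_elem=1.0)
        mats = [make_material(0.3, fab, params) for _ in range(mesh.n_elements)]
        kb = solve_compression(mesh, mats, 0.004, 2, "bonded").curve.force[-1]
        kf = solve_compression(mesh, mats, 0.004, 2, "frictionless").curve.force[-1]
        assert kb >= kf

    def test_equilibrium_top_equals_bottom_reaction(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        mesh = build_hex_mesh(np.ones((16, 16, 16), bool), spacing=0.25,
                              sample_height=4.0, max_elem=1.0)
        mats = [make_material(0.3, fab, params) for _ in range(mesh.n_elements)]
        sol = solve_compression(mesh, mats, 0.04, 8, "bonded")
        np.testing.assert_allclose(
            np.abs(sol.curve.force[1:]), np.abs(sol.reaction_bottom[1:]), rtol=1e-5
        )

    def test_monotonic_force_under_perfect_plasticity(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        mesh = build_hex_mesh(np.ones((16, 16, 16), bool), spacing=0.25,
                              sample_height=4.0, max_elem=1.0)
        mats = [make_material(0.3, fab, params) for _ in range(mesh.n_elements)]
        sol = solve_compression(mesh, mats, 0.06, 15, "bonded")
        assert np.all(np.diff(sol.curve.force) >= -1e-9)

    def test_external_work_bounds_elastic_energy(self, iso_material, params):
        # after yielding, dissipated work makes external work exceed the
        # recoverable elastic energy 0.5 F^2 / K
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.05,
                                n_increments=25, bc_mode="frictionless")
        d, f = sol.curve.displacement, sol.curve.force
        work = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(d))])
        k0 = f[1] / d[1]
        elastic = 0.5 * f**2 / k0
        assert np.all(work >= elastic - 1e-12)

    def test_deformation_gradient_field_uniaxial(self, iso_material):
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.002,
                                n_increments=2, bc_mode="frictionless")
        F = sol.F[0]
        assert F[2, 2] == pytest.approx(1.0 - 0.002 / mesh.height, rel=1e-6)
        # lateral Poisson expansion, no shear
        assert F[0, 0] > 1.0 and F[1, 1] > 1.0
        assert abs(F[0, 1]) < 1e-10

    def test_material_count_mismatch_rejected(self, iso_material):
        mesh = build_hex_mesh(np.ones((16, 16, 16), bool), spacing=0.25,
                              sample_height=4.0, max_elem=1.0)
        with pytest.raises(ValueError, match="one material per element"):
            solve_compression(mesh, [iso_material], 0.01, 2)


class TestHfeStructural:
    def test_linear_elastic_run_stiffness_exact(self, iso_material):
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.001,
                                n_increments=10, bc_mode="frictionless")
        res = hfe_structural(sol, area=mesh.edge**2)
        k_true = sol.curve.force[1] / sol.curve.displacement[1]
        assert res.stiffness == pytest.approx(k_true, rel=1e-9)

    def test_yield_not_above_plateau(self, iso_material):
        mesh = cube_mesh()
        sol = solve_compression(mesh, [iso_material], prescribed_disp=0.05,
                                n_increments=25, bc_mode="frictionless")
        res = hfe_structural(sol, area=mesh.edge**2)
        assert res.yield_force is not None
        assert res.yield_force <= sol.curve.force.max() + 1e-12

    def test_increment_refinement_consistency(self, params):
        fab = FabricTensor.isotropic(fallback=False)
        mesh = build_hex_mesh(np.ones((16, 16, 16), bool), spacing=0.25,
                              sample_height=4.0, max_elem=1.0)
        mats = [make_material(0.3, fab, params) for _ in range(mesh.n_elements)]
        r20 = hfe_structural(solve_compression(mesh, mats, 0.06, 20), area=16.0)
        r40 = hfe_structural(solve_compression(mesh, mats, 0.06, 40), area=16.0)
        assert r20.stiffness == pytest.approx(r40.stiffness, rel=0.01)


class TestPipelineOnSyntheticSection:
    def test_section_mesh_materials_solve(self, small_section, params):
        vol, truth = small_section
        labels = segment_three_phase(
            vol, truth.periosteal_mask, truth.cortex_mask, truth.interior_mask
        )
        mesh = build_hex_mesh(labels.periosteal_mask, vol.spacing)
        assert mesh.edge <= 1.27
        mats = map_element_properties(labels, mesh, params, n_directions=15)
        sol = solve_compression(mesh, mats, prescribed_disp=0.01 * mesh.height,
                                n_increments=8)
        res = hfe_structural(sol)
        assert res.stiffness > 0
        assert np.all(np.diff(sol.curve.force) >= -1e-9)
        assert np.all(np.linalg.det(sol.F) > 0)


class TestMandelRotationProperty:
    from hypothesis import given, settings, strategies as st

    @given(
        angles=st.tuples(
            st.floats(-np.pi, np.pi), st.floats(0, np.pi), st.floats(-np.pi, np.pi)
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_orthogonality_and_stiffness_equivariance(self, angles):
        from scipy.spatial.transform import Rotation

        from tibmech._material import MaterialParams, stiffness_matrix

        R = Rotation.from_euler("zyz", angles).as_matrix()
        R6 = mandel_rotation(R)
        assert np.abs(R6 @ R6.T - np.eye(6)).max() < 1e-10
        # equivariance: rotating the fabric rotates the stiffness tensor
        par = MaterialParams()
        fab = FabricTensor.from_matrix(np.diag([0.7, 1.0, 1.3]))
        C1 = stiffness_matrix(0.5, fab, par)
        fab_rot = FabricTensor.from_matrix(R @ fab.M @ R.T)
        C2 = stiffness_matrix(0.5, fab_rot, par)
        assert np.abs(C2 - R6 @ C1 @ R6.T).max() < 1e-6 * np.abs(C1).max()
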