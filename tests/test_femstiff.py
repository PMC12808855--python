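"""Finite-element stage: surface/volume meshing, the density-modulus law,
material mapping, and the compression solver against closed-form oracles."""

import numpy as np
import pytest

from qctstiff import (DensityImage, FEConfig, build_voi_mesh,
                      density_to_modulus, extract_surface, map_materials,
                      run_fem, solve_compression, tetrahedralize)
from qctstiff.errors import BCError, MappingError, MeshingError
from qctstiff.femstiff import SurfaceMesh, _boundary_faces, _lattice_tets
from qctstiff.voi import VOIMask

from conftest import uniform_density


def make_voi(mask, spacing=1.0, depth=None):
    mask = np.asarray(mask, bool)
    if depth is None:
        depth = mask.shape[2] * spacing
    return VOIMask(mask, (spacing,) * 3, (spacing / 2,) * 3, depth=depth)


class TestDensityModulus:
    def test_printed_coefficient_at_unit_density(self):
        assert density_to_modulus(1.0) == pytest.approx(12486.0)

    def test_power_law_point(self):
        # 12486 * 0.5**1.16, evaluated at high precision
        assert density_to_modulus(0.5) == pytest.approx(5587.6415178, rel=1e-9)

    def test_floor_clamps_nonpositive_density(self):
        floor_E = 12486.0 * 0.001 ** 1.16
        assert density_to_modulus(0.0) == pytest.approx(floor_E)
        assert density_to_modulus(-2.0) == pytest.approx(floor_E)
        assert floor_E == pytest.approx(4.13, abs=0.01)

    def test_monotone_above_floor(self):
        rho = np.linspace(0.01, 2.0, 50)
        assert np.all(np.diff(density_to_modulus(rho)) > 0)


class TestSurface:
    def test_cube_area_and_watertight(self, cube_voi):
        mesh = extract_surface(cube_voi, max_edge=1.5)
        assert mesh.is_watertight()
        assert mesh.area() == pytest.approx(600.0, rel=0.05)
        assert mesh.enclosed_volume() == pytest.approx(1000.0, rel=1e-9)
        assert mesh.max_edge <= 1.5 * 1.1

    def test_single_voxel_mask(self):
        voi = make_voi(np.ones((1, 1, 1)), depth=1.0)
        mesh = extract_surface(voi, max_edge=2.0)
        assert mesh.is_watertight()
        assert len(mesh.vertices) == 8
        assert mesh.enclosed_volume() == pytest.approx(1.0)

    def test_disconnected_mask_rejected(self):
        mask = np.zeros((8, 4, 4), bool)
        mask[0:2, :2, :2] = True
        mask[6:8, :2, :2] = True
        with pytest.raises(MeshingError):
            extract_surface(make_voi(mask), max_edge=2.0)

    def test_subdivision_respects_max_edge(self, cube_voi):
        mesh = extract_surface(cube_voi, max_edge=0.8)
        assert mesh.max_edge <= 0.8 * 1.1


class TestTetrahedralize:
    def test_volume_conservation_exact_on_lattice(self, cube_voi):
        tet = tetrahedralize(extract_surface(cube_voi, max_edge=1.5))
        assert tet.total_volume() == pytest.approx(1000.0, abs=1e-6)
        assert np.all(tet.volumes() > 0)

    def test_cube_tet_count_order_of_magnitude(self, cube_voi):
        tet = tetrahedralize(extract_surface(cube_voi, max_edge=1.5))
        assert len(tet.tets) >= 1000       # 5 tets per voxel, 1000 voxels

    def test_open_surface_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        tris = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3]])  # missing one face
        with pytest.raises(MeshingError):
            tetrahedralize(SurfaceMesh(verts, tris, 1.5, 0.0))

    def test_generic_watertight_surface_delaunay_path(self):
        # unit tetrahedron given only as a surface -> exact Delaunay fill
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        tris = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        tet = tetrahedralize(SurfaceMesh(verts, tris, 2.0, 0.0))
        assert tet.total_volume() == pytest.approx(1 / 6, rel=1e-9)

    def test_boundary_faces_close_the_mesh(self, cube_voi):
        nodes, tets = _lattice_tets(cube_voi.mask, cube_voi.spacing,
                                    cube_voi.origin)
        tris = _boundary_faces(nodes, tets)
        # outward orientation: divergence-theorem volume is positive & exact
        vol = np.einsum("ij,ij->i", nodes[tris[:, 0]],
                        np.cross(nodes[tris[:, 1]], nodes[tris[:, 2]])).sum() / 6
        assert vol == pytest.approx(1000.0, rel=1e-9)


class TestMapMaterials:
    def test_uniform_field_maps_identically(self, cube_voi):
        tet = build_voi_mesh(cube_voi, None, FEConfig())
        tet = map_materials(tet, uniform_density(cube_voi, 500.0))
        np.testing.assert_allclose(tet.element_density, 500.0)
        np.testing.assert_allclose(tet.element_modulus,
                                   density_to_modulus(0.5), rtol=1e-12)

    def test_ramp_cannot_overshoot(self, cube_voi):
        ramp = np.tile(np.linspace(100, 700, 10)[None, None, :], (10, 10, 1))
        d = DensityImage(ramp, cube_voi.spacing, cube_voi.origin)
        tet = build_voi_mesh(cube_voi, None, FEConfig())
        tet = map_materials(tet, d)
        assert tet.element_density.min() >= 100.0 - 1e-9
        assert tet.element_density.max() <= 700.0 + 1e-9

    def test_zero_image_floors_all_elements(self, cube_voi):
        tet = build_voi_mesh(cube_voi, None, FEConfig())
        tet = map_materials(tet, uniform_density(cube_voi, 0.0))
        np.testing.assert_allclose(tet.element_modulus,
                                   density_to_modulus(0.0))

    def test_mesh_outside_image_rejected(self, cube_voi):
        small = DensityImage(np.zeros((4, 4, 4)), cube_voi.spacing,
                             cube_voi.origin)
        tet = build_voi_mesh(cube_voi, None, FEConfig())
        with pytest.raises(MappingError):
            map_materials(tet, small)


class TestSolveCompression:
    def _solved_cube(self, modulus=5000.0, nu=0.0, strain=0.01, edge=6):
        voi = make_voi(np.ones((edge, edge, edge)), depth=float(edge))
        rho = (modulus / 12486.0) ** (1 / 1.16) * 1000.0
        cfg = FEConfig(max_edge=1.5, poisson_ratio=nu, strain=strain)
        tet = build_voi_mesh(voi, None, cfg)
        return run_fem(uniform_density(voi, rho), voi, cfg, tet=tet)

    def test_homogeneous_cube_oracle(self):
        """nu = 0 uniform compression is exactly representable: apparent
        stiffness equals the prescribed modulus."""
        r = self._solved_cube()
        assert r.apparent_stiffness == pytest.approx(5000.0, rel=1e-3)
        assert r.apparent_stress == pytest.approx(r.reaction_force / r.apparent_area)

    def test_equilibrium_and_energy(self):
        r = self._solved_cube(nu=0.3)
        assert r.equilibrium_residual < 1e-6
        assert r.energy_balance < 1e-6

    def test_linearity_under_modulus_doubling(self, cube_voi):
        cfg = FEConfig(poisson_ratio=0.3)
        tet = build_voi_mesh(cube_voi, None, cfg)
        tet = map_materials(tet, uniform_density(cube_voi, 400.0))
        r1 = solve_compression(tet, 0.1, 0.01, axis=tet.load_axis)
        tet.element_modulus = 2.0 * tet.element_modulus
        r2 = solve_compression(tet, 0.1, 0.01, axis=tet.load_axis)
        assert r2.reaction_force == pytest.approx(2.0 * r1.reaction_force,
                                                  rel=1e-9)

    def test_density_scaling_composes_with_power_law(self):
        """Scaling density by 2**(1/1.16) doubles every modulus, hence the
        apparent stiffness."""
        voi = make_voi(np.ones((6, 6, 6)), depth=6.0)
        cfg = FEConfig(poisson_ratio=0.3)
        tet = build_voi_mesh(voi, None, cfg)
        r1 = run_fem(uniform_density(voi, 300.0), voi, cfg, tet=tet)
        r2 = run_fem(uniform_density(voi, 300.0 * 2 ** (1 / 1.16)), voi, cfg,
                     tet=tet)
        assert r2.apparent_stiffness == pytest.approx(
            2.0 * r1.apparent_stiffness, rel=1e-9)

    def test_positive_stiffness_and_monotonicity(self):
        voi = make_voi(np.ones((5, 5, 5)), depth=5.0)
        cfg = FEConfig(poisson_ratio=0.3)
        tet = build_voi_mesh(voi, None, cfg)
        rng = np.random.default_rng(0)
        base = rng.uniform(100, 500, voi.shape)
        r_lo = run_fem(DensityImage(base, voi.spacing, voi.origin), voi, cfg,
                       tet=tet)
        r_hi = run_fem(DensityImage(base + 50.0, voi.spacing, voi.origin),
                       voi, cfg, tet=tet)
        assert r_lo.apparent_stiffness > 0
        assert r_hi.apparent_stiffness >= r_lo.apparent_stiffness

    def test_mesh_refinement_changes_little(self):
        # the uniform nu=0 state is mesh-independent, so halving max_edge
        # must leave the apparent stiffness essentially unchanged
        r1 = self._solved_cube(nu=0.0, edge=6)
        voi = make_voi(np.ones((6, 6, 6)), depth=6.0)
        rho = (5000.0 / 12486.0) ** (1 / 1.16) * 1000.0
        cfg = FEConfig(max_edge=0.75, poisson_ratio=0.0, strain=0.01)
        tet = build_voi_mesh(voi, None, cfg)
        r2 = run_fem(uniform_density(voi, rho), voi, cfg, tet=tet)
        assert abs(r2.apparent_stiffness - r1.apparent_stiffness) \
            / r1.apparent_stiffness < 0.01

    def test_missing_materials_rejected(self, cube_voi):
        tet = build_voi_mesh(cube_voi, None, FEConfig())
        with pytest.raises(BCError):
            solve_compression(tet, 0.1, 0.01)

    def test_identical_density_images_identical_results(self, cube_voi):
        cfg = FEConfig(poisson_ratio=0.3)
        tet = build_voi_mesh(cube_voi, None, cfg)
        d = uniform_density(cube_voi, 350.0)
        r1 = run_fem(d, cube_voi, cfg, tet=tet)
        r2 = run_fem(DensityImage(d.voxels.copy(), d.spacing, d.origin,
                                  calibration="other"), cube_voi, cfg, tet=tet)
        assert r1.apparent_stiffness == r2.apparent_stiffness


def test_strain_displacement_identity():
    """1% apparent strain over the 10 mm slab is a 0.1 mm displacement."""
    cfg = FEConfig(strain=0.01)
    assert cfg.strain * 10.0 == pytest.approx(0.1)


def test_vtk_and_stl_outputs(tmp_path, cube_voi):
    mesh = extract_surface(cube_voi, max_edge=1.5)
    mesh.to_stl(tmp_path / "surf.stl")
    tet = build_voi_mesh(cube_voi, None, FEConfig())
    tet = map_materials(tet, uniform_density(cube_voi, 200.0))
    tet.to_vtk(tmp_path / "model.vtk")
    text = (tmp_path / "model.vtk").read_text()
    assert "UNSTRUCTURED_GRID" in text and "density_mg_cm3" in text
    assert (tmp_path / "surf.stl").stat().st_size > 0
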