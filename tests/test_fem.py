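import numpy as np
import pytest

from conftest import (TUBE_A_MM, TUBE_L_MM, TUBE_T_MM,
                      mid_inner_radial_displacement)
from vesselmech.fem import (ConstrainedSystem, SolveOptions, TransientOptions,
                            apply_loads_and_bcs, assemble_system,
                            pressure_forces, recover_stress, solve_case,
                            solve_static, solve_transient)
from vesselmech.lame import lame_inner_displacement
from vesselmech.materials import (MaterialCase, pressure_levels,
                                  uniform_aorta_cases)
from vesselmech.meshing import Ties, WallMesh, mesh_tree, single_tube_tree

CASE1 = uniform_aorta_cases()[0]
E_TUBE = CASE1.modulus("ascending_aorta")
NU = CASE1.poisson_ratio
P = 5594.0


def block_mesh(distort: float = 0.08) -> WallMesh:
    """2x2x2-element block, deterministically distorted (patch fixture)."""
    g = np.linspace(0.0, 1.0, 3)
    pts = np.array([[x, y, z] for z in g for y in g for x in g])
    rng = np.random.default_rng(7)
    interior = np.all((pts > 0) & (pts < 1), axis=1)
    pts = pts + distort * rng.uniform(-0.2, 0.2, pts.shape) * interior[:, None]

    def nid(i, j, k):
        return i + 3 * j + 9 * k

    cells = []
    for k in range(2):
        for j in range(2):
            for i in range(2):
                cells.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    return WallMesh(pts, np.array(cells), np.zeros(8, dtype=np.int64),
                    ["ascending_aorta"],
                    {"inner_surface": np.zeros((0, 4), dtype=np.int64)},
                    {}, [], Ties.empty())


class TestElement:
    def test_patch_linear_field_reproduced_exactly(self):
        """Constant-strain patch: linear displacement on the boundary of a
        distorted block solves to the same linear field inside, with
        uniform stress matching Hooke's law."""
        mesh = block_mesh()
        case = MaterialCase(1, {"ascending_aorta": 1e6}, 0.45)
        A = np.array([[2e-4, 1e-4, 0.0], [0.0, -1e-4, 5e-5], [1e-4, 0.0, 3e-4]])
        u_exact = mesh.points @ A.T
        system = assemble_system(mesh, case)
        boundary = np.where(np.any((mesh.points <= 0) | (mesh.points >= 1),
                                   axis=1))[0]
        prescribed = {}
        fixed = []
        for n in boundary:
            for c in range(3):
                prescribed[3 * n + c] = u_exact[n, c]
                fixed.append(3 * n + c)
        cs = ConstrainedSystem(system, np.zeros(3 * mesh.n_nodes),
                               np.zeros(0, dtype=np.int64), 0.0)
        res = solve_static(cs, prescribed=prescribed)
        assert np.allclose(res.displacement, u_exact, atol=1e-12)
        sig = res.stress
        assert np.allclose(sig, sig[0], rtol=1e-9)
        eps = 0.5 * (A + A.T)
        lam, mu = 1e6 * 0.45 / (1.45 * 0.1), 1e6 / 2.9
        sig_exact = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
        assert np.allclose(sig[0], sig_exact, rtol=1e-9)

    def test_stiffness_symmetric(self):
        K = assemble_system(block_mesh(), CASE1).K
        assert abs(K - K.T).max() <= 1e-12 * abs(K).max()

    def test_rigid_translation_and_rotation_zero_stress(self):
        mesh = block_mesh()
        u_t = np.tile([1e-3, -2e-3, 5e-4], (mesh.n_nodes, 1))
        assert np.abs(recover_stress(mesh, CASE1, u_t)).max() < 1e-6
        W = np.array([[0, 1e-4, -2e-4], [-1e-4, 0, 5e-5], [2e-4, -5e-5, 0]])
        u_r = mesh.points @ W.T      # linearized rigid rotation
        assert np.abs(recover_stress(mesh, CASE1, u_r)).max() < 1e-6

    def test_uniaxial_stretch_matches_hooke(self):
        # prescribed eps11 with free lateral contraction: sigma11 = E eps11
        mesh = block_mesh(distort=0.0)
        E, nu = 1e6, 0.3
        case = MaterialCase(1, {"ascending_aorta": E}, nu)
        eps11 = 1e-3
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = eps11 * mesh.points[:, 0]
        u[:, 1] = -nu * eps11 * mesh.points[:, 1]
        u[:, 2] = -nu * eps11 * mesh.points[:, 2]
        sig = recover_stress(mesh, case, u)
        assert np.allclose(sig[:, 0, 0], E * eps11, rtol=1e-9)
        assert np.allclose(sig[:, 1, 1], 0.0, atol=1e-9 * E * eps11)
        assert np.allclose(sig[:, 2, 2], 0.0, atol=1e-9 * E * eps11)


class TestPressureLoads:
    def test_zero_pressure_zero_forces(self, small_tube_mesh):
        f = pressure_forces(small_tube_mesh.points,
                            small_tube_mesh.facet_sets["inner_surface"], 0.0)
        assert np.all(f == 0)

    def test_closed_surface_zero_net_force(self):
        # unit cube with all six faces oriented outward
        mesh = block_mesh(distort=0.0)

        def nid(i, j, k):
            return i + 3 * j + 9 * k

        faces = []
        for a in range(2):
            for b in range(2):
                faces += [[nid(a, b, 0), nid(a, b + 1, 0),
                           nid(a + 1, b + 1, 0), nid(a + 1, b, 0)],
                          [nid(a, b, 2), nid(a + 1, b, 2),
                           nid(a + 1, b + 1, 2), nid(a, b + 1, 2)],
                          [nid(a, 0, b), nid(a + 1, 0, b),
                           nid(a + 1, 0, b + 1), nid(a, 0, b + 1)],
                          [nid(a, 2, b), nid(a, 2, b + 1),
                           nid(a + 1, 2, b + 1), nid(a + 1, 2, b)],
                          [nid(0, a, b), nid(0, a, b + 1),
                           nid(0, a + 1, b + 1), nid(0, a + 1, b)],
                          [nid(2, a, b), nid(2, a + 1, b),
                           nid(2, a + 1, b + 1), nid(2, a, b + 1)]]
        f = pressure_forces(mesh.points, np.array(faces), 1000.0)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_nodal_forces_match_facet_area_vectors(self, small_tube_mesh):
        """Brute-force oracle: for a uniform pressure the total force
        equals p times the sum of exact bilinear-quad area vectors
        0.5 (d1 x d2)."""
        quads = small_tube_mesh.facet_sets["inner_surface"]
        P_ = small_tube_mesh.points
        f = pressure_forces(P_, quads, 1000.0)
        areas = 0.5 * np.cross(P_[quads[:, 2]] - P_[quads[:, 0]],
                               P_[quads[:, 3]] - P_[quads[:, 1]])
        assert np.allclose(f.sum(axis=0), 1000.0 * areas.sum(axis=0),
                           atol=1e-12)

    def test_empty_inner_surface_rejected(self):
        mesh = block_mesh()
        system = assemble_system(mesh, CASE1)
        with pytest.raises(ValueError, match="inner_surface"):
            apply_loads_and_bcs(system, mesh, P)

    def test_region_without_modulus_named(self, small_tube_mesh):
        case = MaterialCase(1, {"left_subclavian": 1e6})
        with pytest.raises(KeyError, match="ascending_aorta"):
            assemble_system(small_tube_mesh, case)


class TestStaticSolve:
    def test_tube_matches_lame_within_3_percent(self, tube_mesh):
        res = solve_case(tube_mesh, CASE1, P)
        u_mid = mid_inner_radial_displacement(tube_mesh, res.displacement,
                                              TUBE_L_MM)
        u_ref = lame_inner_displacement(TUBE_A_MM * 1e-3,
                                        (TUBE_A_MM + TUBE_T_MM) * 1e-3,
                                        E_TUBE, NU, P)
        assert abs(u_mid - u_ref) / u_ref < 0.03

    def test_displacement_zero_on_openings(self, tube_mesh):
        res = solve_case(tube_mesh, CASE1, P)
        fixed = tube_mesh.opening_nodes()
        assert np.abs(res.displacement[fixed]).max() < 1e-15

    def test_exact_linearity_in_pressure(self, small_tube_mesh):
        r1 = solve_case(small_tube_mesh, CASE1, P)
        r2 = solve_case(small_tube_mesh, CASE1, 2 * P)
        assert np.allclose(r2.displacement, 2 * r1.displacement, rtol=1e-12,
                           atol=1e-18)

    def test_exact_material_scaling(self, small_tube_mesh):
        r1 = solve_case(small_tube_mesh, CASE1, P)
        r2 = solve_case(small_tube_mesh, CASE1.scaled(2.0), P)
        assert np.allclose(r2.displacement, r1.displacement / 2, rtol=1e-12,
                           atol=1e-18)

    def test_frame_objectivity_under_mesh_rotation(self, small_tube_mesh):
        th = np.deg2rad(30.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(th), -np.sin(th)],
                      [0, np.sin(th), np.cos(th)]])
        rotated = WallMesh(small_tube_mesh.points @ R.T, small_tube_mesh.cells,
                           small_tube_mesh.cell_region,
                           small_tube_mesh.region_names,
                           small_tube_mesh.facet_sets,
                           small_tube_mesh.inner_facets_by_region,
                           small_tube_mesh.caps, small_tube_mesh.ties)
        r0 = solve_case(small_tube_mesh, CASE1, P)
        r1 = solve_case(rotated, CASE1, P)
        assert np.allclose(r1.displacement, r0.displacement @ R.T,
                           rtol=1e-8, atol=1e-12)

    def test_mirror_symmetry(self, small_tube_mesh):
        res = solve_case(small_tube_mesh, CASE1, P)
        pts = small_tube_mesh.points
        key = {(round(-x, 9), round(y, 9), round(z, 9)): i
               for i, (x, y, z) in enumerate(pts)}
        mirrored = np.array([key[(round(x, 9), round(y, 9), round(z, 9))]
                             for x, y, z in pts])
        u, um = res.displacement, res.displacement[mirrored]
        assert np.allclose(u[:, 0], -um[:, 0], atol=1e-12)
        assert np.allclose(u[:, 1:], um[:, 1:], atol=1e-12)

    def test_selective_reduced_is_default_and_accurate(self):
        # coarse, nearly incompressible: B-bar stays within 5 % of Lamé
        assert SolveOptions().integration_scheme == "selective_reduced"
        mesh = mesh_tree(single_tube_tree(160.0, TUBE_A_MM, TUBE_T_MM),
                         (16, 0.25, 1))
        res = solve_case(mesh, CASE1, P)
        u_mid = mid_inner_radial_displacement(mesh, res.displacement, 160.0)
        u_ref = lame_inner_displacement(TUBE_A_MM * 1e-3,
                                        (TUBE_A_MM + TUBE_T_MM) * 1e-3,
                                        E_TUBE, NU, P)
        assert abs(u_mid - u_ref) / u_ref < 0.05

    def test_hoop_stress_within_5_percent_of_lame(self, tube_mesh):
        from vesselmech.lame import lame_stresses
        res = solve_case(tube_mesh, CASE1, P)
        # mid-length, mid-wall cells: compare hoop component
        cells = tube_mesh.cells
        cent = tube_mesh.points[cells].mean(axis=1)
        r = np.linalg.norm(cent[:, :2], axis=1)
        a, b = TUBE_A_MM * 1e-3, (TUBE_A_MM + TUBE_T_MM) * 1e-3
        sel = np.where((np.abs(cent[:, 2] - TUBE_L_MM / 2 * 1e-3) < 2e-3))[0]
        e_t = np.stack([-cent[sel, 1], cent[sel, 0],
                        np.zeros(len(sel))], axis=1)
        e_t /= np.linalg.norm(e_t, axis=1, keepdims=True)
        hoop = np.einsum("ki,kij,kj->k", e_t, res.stress[sel], e_t)
        _, hoop_ref, _ = lame_stresses(r[sel], a, b, P, NU)
        assert np.all(np.abs(hoop - hoop_ref) / np.abs(hoop_ref) < 0.05)

    def test_convergence_order_at_least_one(self):
        """Plane-strain ring refinement: observed order of the inner-wall
        displacement error is >= 1 (in practice ~2)."""
        a, t = TUBE_A_MM, TUBE_T_MM
        u_ref = lame_inner_displacement(a * 1e-3, (a + t) * 1e-3, E_TUBE, NU, P)
        errors, hs = [], []
        for nc, nr in ((16, 1), (32, 2), (64, 4)):
            mesh = mesh_tree(single_tube_tree(4.0, a, t), (nc, 0.5, nr))
            system = assemble_system(mesh, CASE1)
            f = pressure_forces(mesh.points,
                                mesh.facet_sets["inner_surface"], P).ravel()
            fixed = list(3 * np.arange(mesh.n_nodes) + 2)    # plane strain
            pts = mesh.points
            pin = int(np.argmin(np.abs(pts[:, 1]) + np.abs(pts[:, 2])
                                + np.abs(np.linalg.norm(pts[:, :2], axis=1)
                                         - a * 1e-3)))
            fixed.append(3 * pin + 1)
            cs = ConstrainedSystem(system, f, np.array(fixed), P)
            res = solve_static(cs)
            inner = np.unique(mesh.facet_sets["inner_surface"].ravel())
            ur = (np.einsum("ij,ij->i", res.displacement[inner, :2],
                            pts[inner, :2])
                  / np.linalg.norm(pts[inner, :2], axis=1)).mean()
            errors.append(abs(ur - u_ref))
            hs.append(1.0 / nc)
        order = np.polyfit(np.log(hs), np.log(errors), 1)[0]
        assert order >= 1.0


class TestTransient:
    def test_zero_load_zero_trajectory(self, small_tube_mesh):
        system = assemble_system(small_tube_mesh, CASE1)
        cs = apply_loads_and_bcs(system, small_tube_mesh, 0.0)
        opts = SolveOptions(transient=TransientOptions(
            time_step=5e-3, total_cycles=0.1, output_every=5))
        series = solve_transient(cs, lambda t: 1.0, opts)
        assert all(np.all(r.displacement == 0) for r in series)

    def test_constant_load_converges_to_static(self, small_tube_mesh):
        system = assemble_system(small_tube_mesh, CASE1)
        cs = apply_loads_and_bcs(system, small_tube_mesh, P)
        static = solve_static(cs)
        # gamma > 1/2 adds algorithmic damping so the ring-down decays
        opts = SolveOptions(transient=TransientOptions(
            time_step=2e-3, total_cycles=2.0, output_every=100,
            newmark_gamma=0.6, newmark_beta=0.3025))
        series = solve_transient(cs, lambda t: 1.0, opts)
        final = series[-1].displacement
        ref = np.abs(static.displacement).max()
        assert np.abs(final - static.displacement).max() < 0.02 * ref

    def test_quasi_static_peak_within_1_percent(self, small_tube_mesh):
        pp1, _ = pressure_levels()
        system = assemble_system(small_tube_mesh, CASE1)
        cs = apply_loads_and_bcs(system, small_tube_mesh, pp1.pulse_pressure)
        static = solve_static(cs)
        opts = SolveOptions(transient=TransientOptions(
            time_step=2e-3, total_cycles=1.0, cycle_period=1.0,
            output_every=10))
        series = solve_transient(cs, pp1.waveform, opts)
        peak = max(np.abs(r.displacement).max() for r in series)
        assert abs(peak - np.abs(static.displacement).max()) \
            < 0.01 * np.abs(static.displacement).max()

    def test_unstable_newmark_refused_with_warning(self, small_tube_mesh):
        system = assemble_system(small_tube_mesh, CASE1)
        cs = apply_loads_and_bcs(system, small_tube_mesh, P)
        opts = SolveOptions(transient=TransientOptions(
            time_step=5e-3, total_cycles=0.05, newmark_beta=0.1,
            newmark_gamma=0.6))
        with pytest.warns(UserWarning, match="stability"):
            with pytest.raises(ValueError, match="force=True"):
                solve_transient(cs, lambda t: 1.0, opts)
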