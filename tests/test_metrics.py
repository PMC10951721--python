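import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselmech.fem import SolveResult, solve_case
from vesselmech.materials import uniform_aorta_cases
from vesselmech.meshing import mesh_tree, single_tube_tree
from vesselmech.metrics import (compliance, deformation_magnitude,
                                enclosed_volume, local_compliance_map,
                                percent_change, region_volume_changes,
                                region_volumes, summarize_deformation,
                                von_mises)

CASE1 = uniform_aorta_cases()[0]
P = 5594.0


class TestDeformation:
    def test_pythagorean_triple(self):
        assert deformation_magnitude(np.array([[3.0, 4.0, 0.0]]))[0] == 5.0

    def test_zero_iff_zero(self):
        u = np.array([[0.0, 0.0, 0.0], [1e-9, 0, 0]])
        U = deformation_magnitude(u)
        assert U[0] == 0.0 and U[1] > 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            deformation_magnitude(np.array([[np.nan, 0, 0]]))

    def test_uniform_field_equal_regional_maxima(self, default_mesh):
        u = np.full((default_mesh.n_nodes, 3), 2.0e-4)
        summary = summarize_deformation(default_mesh, u)
        expected = float(np.linalg.norm([2e-4] * 3))
        assert all(np.isclose(v, expected)
                   for v in summary.max_by_region.values())
        # the arg node actually attains the max
        for region, i in summary.argmax_by_region.items():
            assert np.isclose(np.linalg.norm(u[i]),
                              summary.max_by_region[region])


class TestEnclosedVolume:
    def test_metre_cylinder_volume_within_chordal_bound(self):
        # a = 1 m, L = 1 m meshed at 32 circumferential divisions
        tree = single_tube_tree(1000.0, 1000.0, 50.0)
        mesh = mesh_tree(tree, (32, 0.004, 1))
        v = enclosed_volume(mesh)
        assert abs(v - np.pi) / np.pi < 0.01

    def test_zero_displacement_zero_delta_v(self, small_tube_mesh):
        dv = region_volume_changes(small_tube_mesh,
                                   np.zeros((small_tube_mesh.n_nodes, 3)))
        assert all(abs(d) < 1e-30 for d in dv.values())

    def test_uniform_inflation_matches_closed_form(self):
        a_mm, L_mm, u0 = 3.0, 20.0, 5e-5
        mesh = mesh_tree(single_tube_tree(L_mm, a_mm, 1.0), (32, 0.5, 1))
        P_ = mesh.points
        r = np.linalg.norm(P_[:, :2], axis=1)
        u = np.zeros_like(P_)
        u[:, :2] = u0 * P_[:, :2] / r[:, None]
        a, L = a_mm * 1e-3, L_mm * 1e-3
        dv = sum(region_volume_changes(mesh, u).values())
        assert dv == pytest.approx(2 * np.pi * a * u0 * L, rel=0.01)
        # the exact displaced-surface volume carries the quadratic term
        dv_exact = enclosed_volume(mesh, u) - enclosed_volume(mesh)
        assert dv_exact == pytest.approx(
            np.pi * ((a + u0) ** 2 - a ** 2) * L, rel=0.01)

    def test_regional_additivity(self, uniform_fem_bundle):
        comp = uniform_fem_bundle.compliance_table
        sel = comp[(comp.case_id == 1) & (comp.pressure == "PP1")]
        regions = sel[~sel.region.isin(
            ["aorta", "left_carotid", "right_carotid", "aorta_carotid",
             "whole_model"])]
        whole = float(sel[sel.region == "whole_model"].delta_v_m3.iloc[0])
        assert regions.delta_v_m3.sum() == pytest.approx(whole, rel=5e-3)

    def test_region_volumes_positive(self, default_mesh):
        assert all(v > 0 for v in region_volumes(default_mesh).values())


@pytest.fixture(scope="module")
def tube_solves(small_tube_mesh):
    return {p: solve_case(small_tube_mesh, CASE1, p)
            for p in (P, 2 * P, 7639.0)}


class TestCompliance:

    def test_same_solve_twice_zero_compliance(self, small_tube_mesh, tube_solves):
        rep = compliance(small_tube_mesh, tube_solves[P], tube_solves[P], P)
        assert np.allclose(rep.table.compliance_m3_per_pa, 0.0)

    def test_pressure_independent(self, small_tube_mesh, tube_solves):
        c1 = compliance(small_tube_mesh, tube_solves[P], None, P)
        c2 = compliance(small_tube_mesh, tube_solves[7639.0], None, 7639.0)
        assert np.allclose(c1.table.compliance_m3_per_pa,
                           c2.table.compliance_m3_per_pa, rtol=1e-9)

    def test_modulus_doubling_halves_compliance(self, small_tube_mesh, tube_solves):
        r2 = solve_case(small_tube_mesh, CASE1.scaled(2.0), P)
        c1 = compliance(small_tube_mesh, tube_solves[P], None, P)
        c2 = compliance(small_tube_mesh, r2, None, P)
        assert np.allclose(c2.table.compliance_m3_per_pa,
                           c1.table.compliance_m3_per_pa / 2, rtol=1e-9)

    def test_invalid_delta_p(self, small_tube_mesh, tube_solves):
        with pytest.raises(ValueError, match="delta_p"):
            compliance(small_tube_mesh, tube_solves[P], None, -1.0)


class TestVonMises:
    def test_uniaxial(self):
        s = np.zeros((1, 3, 3))
        s[0, 0, 0] = 2.0e4
        assert von_mises(s)[0] == pytest.approx(2.0e4)

    def test_hydrostatic_zero(self):
        assert von_mises(np.eye(3)[None] * 5e4)[0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_shear_sqrt3(self):
        s = np.zeros((1, 3, 3))
        s[0, 0, 1] = s[0, 1, 0] = 7.0e3
        assert von_mises(s)[0] == pytest.approx(np.sqrt(3) * 7.0e3)

    def test_asymmetric_rejected(self):
        s = np.zeros((1, 3, 3))
        s[0, 0, 1] = 1e4
        with pytest.raises(ValueError, match="asymmetric"):
            von_mises(s)

    def test_rotation_invariance_100_rotations(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(3)
        base = rng.normal(size=(3, 3))
        s = (base + base.T)[None] * 1e4
        ref = von_mises(s)[0]
        rots = Rotation.random(100, random_state=12345).as_matrix()
        for R in rots:
            sr = (R @ s[0] @ R.T)[None]
            assert abs(von_mises(sr)[0] - ref) / ref < 1e-10


class TestPercentChange:
    def test_arithmetic(self):
        assert percent_change(100.0, 47.0) == 53.0
        assert percent_change(3.7, 3.7) == 0.0

    def test_halving_is_exactly_50(self):
        c = 8.31e-10
        assert percent_change(c, c / 2) == 50.0

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_reference_rejected(self, bad):
        with pytest.raises(ValueError, match="reference"):
            percent_change(bad, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ref=st.floats(1e-12, 1e3), frac=st.floats(0.0, 2.0))
    def test_sign_convention(self, ref, frac):
        pc = percent_change(ref, ref * frac)
        assert (pc > 0) == (frac < 1.0) or frac == 1.0

    def test_uniform_model_E_doubling_gives_50(self, small_tube_mesh):
        r1 = solve_case(small_tube_mesh, CASE1, P)
        r2 = solve_case(small_tube_mesh, CASE1.scaled(2.0), P)
        c1 = compliance(small_tube_mesh, r1, None, P)
        c2 = compliance(small_tube_mesh, r2, None, P)
        region = small_tube_mesh.region_names[0]
        pc = percent_change(c1.compliance_of(region), c2.compliance_of(region))
        assert pc == pytest.approx(50.0, abs=1e-9)


class TestLocalComplianceMap:
    def test_zero_displacement_zero_map(self, small_tube_mesh):
        zero = SolveResult(np.zeros((small_tube_mesh.n_nodes, 3)), None, 0.0)
        _, vals = local_compliance_map(small_tube_mesh, zero, None, P)
        assert np.all(vals == 0)

    def test_only_inner_surface_nodes_included(self, small_tube_mesh):
        zero = SolveResult(np.zeros((small_tube_mesh.n_nodes, 3)), None, 0.0)
        ids, _ = local_compliance_map(small_tube_mesh, zero, None, P)
        inner = np.unique(small_tube_mesh.facet_sets["inner_surface"].ravel())
        assert np.array_equal(ids, inner)

    def test_nodewise_variation_between_E_and_2E_is_50(self, small_tube_mesh):
        r1 = solve_case(small_tube_mesh, CASE1, P)
        r2 = solve_case(small_tube_mesh, CASE1.scaled(2.0), P)
        _, v1 = local_compliance_map(small_tube_mesh, r1, None, P)
        _, v2 = local_compliance_map(small_tube_mesh, r2, None, P)
        # nodewise variation 100*(v1-v2)/v1 = 50 % wherever motion exists
        assert np.allclose(v2, v1 / 2, rtol=1e-9, atol=1e-16)
        live = np.abs(v1) > 1e-3 * np.abs(v1).max()
        assert np.allclose(100.0 * (v1[live] - v2[live]) / v1[live], 50.0,
                           atol=1e-6)
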