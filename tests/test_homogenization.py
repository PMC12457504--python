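"""Effective tensors, engineering constants, local field reconstruction."""

import numpy as np
import pytest

import ringhomog as rh
from ringhomog.homogenization import (extract_orthotropic_constants,
                                      homogenize, reconstruct_fields)
from ringhomog.materials import (AXIAL_CELL_WALL, MaterialField,
                                 build_cell_wall_material,
                                 orthotropic_compliance)
from ringhomog.phantom import analytic_levelset
from ringhomog.pipeline import solve_homogenization
from ringhomog.segmentation import LevelSetField
from ringhomog.solver import (assemble_system, build_periodic_dof_map,
                              build_preconditioner, solve_cell_problems)
from ringhomog.xfem import (ELEM_SOLID, StructuredHexMesh, element_B_stack,
                            gauss_rule, integrate_elements_batch)
from tests.conftest import iso_stiffness

NO_CUTS = np.zeros((0, 27))


def solve_solid_mesh(dims, C, beta, h=0.01, tol=1e-10):
    """Assemble and solve a fully solid mesh with per-element properties."""
    ne = int(np.prod(dims))
    mesh = StructuredHexMesh(dims=dims, spacing_mm=(h, h, h))
    cls = np.full(ne, ELEM_SOLID, np.uint8)
    dof_map = build_periodic_dof_map(dims, cls)
    rule = gauss_rule(2)
    B = element_B_stack(rule.points, mesh.spacing_mm)
    Ke, Fe, fe = integrate_elements_batch(C, beta, rule.weights, B,
                                          mesh.det_jacobian)
    K, F, f = assemble_system(Ke, Fe, fe, np.arange(ne), dof_map)
    S = build_preconditioner(Ke, np.arange(ne), dof_map)
    sol = solve_cell_problems(K, F, f, S, dof_map, tol=tol)
    mat = MaterialField(C=C, beta=beta, cell_type=cls, alpha=np.zeros(ne),
                        shape=dims)
    return mesh, cls, mat, sol


def laminate_material(dims, Ca, Cb, ba, bb):
    """Two-phase laminate normal to x, equal volume fractions."""
    ne = int(np.prod(dims))
    n = dims[0]
    in_a = np.repeat(np.arange(n) < n // 2, dims[1] * dims[2])
    C = np.where(in_a[:, None, None], Ca, Cb)
    beta = np.where(in_a[:, None], ba, bb)
    return C, beta


def backus_laminate_stiffness(E1, nu1, E2, nu2):
    """Closed-form effective stiffness of an equal-fraction isotropic
    laminate with layers normal to x (series/parallel mixture oracle)."""
    def lame(E, nu):
        return E * nu / ((1 + nu) * (1 - 2 * nu)), E / (2 * (1 + nu))

    l1, m1 = lame(E1, nu1)
    l2, m2 = lame(E2, nu2)
    avg = lambda a, b: 0.5 * (a + b)
    havg = lambda a, b: 1.0 / avg(1.0 / a, 1.0 / b)
    Cxx = havg(l1 + 2 * m1, l2 + 2 * m2)
    r = avg(l1 / (l1 + 2 * m1), l2 / (l2 + 2 * m2))
    Cxy = r * Cxx
    Cyy = avg(4 * m1 * (l1 + m1) / (l1 + 2 * m1),
              4 * m2 * (l2 + m2) / (l2 + 2 * m2)) + r**2 * Cxx
    Cyz = avg(2 * m1 * l1 / (l1 + 2 * m1),
              2 * m2 * l2 / (l2 + 2 * m2)) + r**2 * Cxx
    C = np.zeros((6, 6))
    C[0, 0] = Cxx
    C[0, 1] = C[1, 0] = C[0, 2] = C[2, 0] = Cxy
    C[1, 1] = C[2, 2] = Cyy
    C[1, 2] = C[2, 1] = Cyz
    C[3, 3] = avg(m1, m2)          # y-z shear: parallel
    C[4, 4] = C[5, 5] = havg(m1, m2)  # shears across the layering: series
    return C


class TestHomogenize:
    def test_homogeneous_cell_returns_constituent_tensors(self):
        C0 = iso_stiffness(1e4, 0.3)
        beta0 = np.r_[0.2, 0.3, 0.1, 0, 0, 0]
        mesh, cls, mat, sol = solve_solid_mesh(
            (3, 3, 3), np.tile(C0, (27, 1, 1)), np.tile(beta0, (27, 1)))
        eff = homogenize(sol, mat, mesh, cls, NO_CUTS)
        np.testing.assert_allclose(eff.C_bar, C0, rtol=1e-12, atol=1e-8)
        np.testing.assert_allclose(eff.beta_bar, beta0, atol=1e-12)

    def test_effective_stiffness_is_symmetric(self):
        rng = np.random.default_rng(4)
        dims = (4, 4, 4)
        C = np.stack([iso_stiffness(E, nu) for E, nu in
                      zip(rng.uniform(1e3, 2e4, 64), rng.uniform(0.1, 0.4, 64))])
        mesh, cls, mat, sol = solve_solid_mesh(dims, C, np.zeros((64, 6)))
        eff = homogenize(sol, mat, mesh, cls, NO_CUTS)
        np.testing.assert_allclose(eff.C_bar, eff.C_bar.T,
                                   atol=1e-9 * np.abs(eff.C_bar).max())

    def test_laminate_matches_series_parallel_closed_form(self):
        E1, nu1, E2, nu2 = 1e4, 0.3, 2e3, 0.2
        dims = (4, 4, 4)
        C, beta = laminate_material(dims, iso_stiffness(E1, nu1),
                                    iso_stiffness(E2, nu2),
                                    np.zeros(6), np.zeros(6))
        mesh, cls, mat, sol = solve_solid_mesh(dims, C, beta)
        eff = homogenize(sol, mat, mesh, cls, NO_CUTS)
        ref = backus_laminate_stiffness(E1, nu1, E2, nu2)
        np.testing.assert_allclose(eff.C_bar, ref, atol=1e-6 * np.abs(ref).max())

    def test_porous_cell_below_voigt_bound(self):
        # isotropic matrix with a centered cylindrical void: C_bar must stay
        # below the (1 - porosity) * C dilution bound in the Loewner sense
        n = 10
        ls = analytic_levelset("cylinder", {"center": (n / 2, n / 2),
                                            "radius": n / 4}, ((n, n, n), 1.0))
        E, nu = 10.0, 0.3
        iso = rh.CellWallParams(E1=E, E2=E, E3=E, nu12=nu, nu13=nu, nu23=nu,
                                G12=E / 2.6, G13=E / 2.6, G23=E / 2.6,
                                beta1=0.1, beta2=0.1, beta3=0.1)
        ct = np.where(ls.phi >= 0, rh.CELL_AXIAL, rh.CELL_VOID).astype(np.uint8)
        res = solve_homogenization(ls, ct, spacing_um=10.0, axial=iso)
        C_local, _ = build_cell_wall_material(iso)
        porosity = np.count_nonzero(ls.phi < 0) / ls.phi.size
        bound = (1 - porosity) * C_local
        lam = np.linalg.eigvalsh(bound - res.effective.C_bar)
        assert lam.min() > -1e-6 * np.abs(C_local).max()

    def test_hill_energy_consistency_on_laminate(self):
        # quadrature average of sigma : eps under a unit macroscopic strain
        # equals the corresponding diagonal entry of C_bar
        E1, nu1, E2, nu2 = 1e4, 0.3, 2e3, 0.2
        dims = (4, 4, 4)
        C, beta = laminate_material(dims, iso_stiffness(E1, nu1),
                                    iso_stiffness(E2, nu2),
                                    np.zeros(6), np.zeros(6))
        mesh, cls, mat, sol = solve_solid_mesh(dims, C, beta)
        eff = homogenize(sol, mat, mesh, cls, NO_CUTS)
        rule = gauss_rule(2)
        B = element_B_stack(rule.points, mesh.spacing_mm)
        vals = sol.element_values()            # (ne, 24, 7)
        for j in (0, 3):
            unit = np.zeros(6)
            unit[j] = 1.0
            epsq = unit[None, None, :] + np.einsum("ibk,nk->nib", B,
                                                   vals[:, :, j])
            sigq = np.einsum("nab,nib->nia", C, epsq)
            energy = np.einsum("i,nia,nia->", rule.weights, sigq, epsq)
            energy *= mesh.det_jacobian / mesh.volume
            assert energy == pytest.approx(eff.C_bar[j, j], rel=1e-2)


class TestEngineeringConstants:
    def test_round_trip_from_known_constants(self):
        D = orthotropic_compliance(AXIAL_CELL_WALL) / 1e3  # 1/MPa
        C = np.linalg.inv(D)
        constants, residual = extract_orthotropic_constants(C)
        assert constants["E_R"] == pytest.approx(5.8e3, rel=1e-10)
        assert constants["E_T"] == pytest.approx(3.7e3, rel=1e-10)
        assert constants["E_L"] == pytest.approx(18.3e3, rel=1e-10)
        assert constants["nu_RT"] == pytest.approx(0.24, rel=1e-10)
        assert constants["G_LT"] == pytest.approx(1.2e3, rel=1e-10)
        assert constants["G_RT"] == pytest.approx(1.0e3, rel=1e-10)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_relations_between_poisson_ratios(self):
        C = np.linalg.inv(orthotropic_compliance(AXIAL_CELL_WALL) / 1e3)
        constants, _ = extract_orthotropic_constants(C)
        assert constants["nu_TR"] / constants["E_T"] == pytest.approx(
            constants["nu_RT"] / constants["E_R"], rel=1e-10)

    def test_non_orthotropic_input_reports_residual(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        C = A @ A.T + 6 * np.eye(6)
        constants, residual = extract_orthotropic_constants(C)
        assert residual > 0
        assert np.isfinite(list(constants.values())).all()


class TestLocalFields:
    def _homogeneous(self):
        C0 = iso_stiffness(1e4, 0.3)
        beta0 = np.r_[0.2, 0.3, 0.1, 0, 0, 0]
        return solve_solid_mesh((3, 3, 3), np.tile(C0, (27, 1, 1)),
                                np.tile(beta0, (27, 1))), C0, beta0

    def test_free_expansion_is_stress_free_uniform_swelling(self):
        (mesh, cls, mat, sol), C0, beta0 = self._homogeneous()
        eff = homogenize(sol, mat, mesh, cls, NO_CUTS)
        lf = reconstruct_fields(sol, mat, mesh, cls, NO_CUTS, delta_m=2.0,
                                mode="free", beta_bar=eff.beta_bar)
        np.testing.assert_allclose(lf.strain - 2.0 * beta0, 0.0, atol=1e-10)
        np.testing.assert_allclose(lf.stress, 0.0, atol=1e-7)
        np.testing.assert_allclose(lf.avg_strain, 2.0 * eff.beta_bar,
                                   atol=1e-10)
        np.testing.assert_allclose(lf.avg_stress, 0.0, atol=1e-7)

    def test_constrained_expansion_uniform_compressive_stress(self):
        (mesh, cls, mat, sol), C0, beta0 = self._homogeneous()
        lf = reconstruct_fields(sol, mat, mesh, cls, NO_CUTS, delta_m=1.0,
                                mode="constrained")
        np.testing.assert_allclose(lf.strain, 0.0, atol=1e-12)
        # percent strains enter the law as absolute strain: sigma in MPa
        np.testing.assert_allclose(lf.stress - (-0.01 * (C0 @ beta0)), 0.0,
                                   atol=1e-10)
        np.testing.assert_allclose(lf.avg_strain, 0.0, atol=1e-12)

    def test_laminate_constrained_sigma_xx_continuous(self):
        E1, nu1, E2, nu2 = 1e4, 0.3, 2e3, 0.2
        dims = (8, 8, 8)
        ba = np.r_[0.1, 0.1, 0.1, 0, 0, 0]
        bb = np.r_[0.4, 0.4, 0.4, 0, 0, 0]
        C, beta = laminate_material(dims, iso_stiffness(E1, nu1),
                                    iso_stiffness(E2, nu2), ba, bb)
        mesh, cls, mat, sol = solve_solid_mesh(dims, C, beta)
        lf = reconstruct_fields(sol, mat, mesh, cls, NO_CUTS, delta_m=1.0,
                                mode="constrained")
        sxx = lf.stress[:, 0]
        # traction continuity across the layers: sigma_xx uniform
        assert np.ptp(sxx) < 1e-6 * np.abs(sxx).max()

    def test_porous_free_expansion_has_zero_average_stress(self):
        n = 8
        ls = analytic_levelset("cylinder", {"center": (n / 2, n / 2),
                                            "radius": n / 4}, ((n, n, n), 1.0))
        ct = np.where(ls.phi >= 0, rh.CELL_AXIAL, rh.CELL_VOID).astype(np.uint8)
        res = solve_homogenization(ls, ct, spacing_um=10.0, tol=1e-10)
        lf = res.local_fields(1.0, "free")
        scale = np.abs(lf.stress).max()
        np.testing.assert_allclose(lf.avg_stress, 0.0, atol=1e-6 * scale)

    def test_unknown_mode_rejected(self):
        (mesh, cls, mat, sol), *_ = self._homogeneous()
        with pytest.raises(ValueError, match="mode"):
            reconstruct_fields(sol, mat, mesh, cls, NO_CUTS, 1.0, "swelling")

    def test_free_mode_requires_beta_bar(self):
        (mesh, cls, mat, sol), *_ = self._homogeneous()
        with pytest.raises(ValueError, match="beta_bar"):
            reconstruct_fields(sol, mat, mesh, cls, NO_CUTS, 1.0, "free")


class TestSolutionInvariances:
    def test_constant_shift_leaves_homogenized_tensors_unchanged(self):
        rng = np.random.default_rng(2)
        dims = (3, 3, 3)
        C = np.stack([iso_stiffness(E, nu) for E, nu in
                      zip(rng.uniform(1e3, 2e4, 27), rng.uniform(0.1, 0.4, 27))])
        beta = np.zeros((27, 6))
        beta[:, :3] = rng.uniform(0.05, 0.5, (27, 3))
        mesh, cls, mat, sol = solve_solid_mesh(dims, C, beta)
        eff = homogenize(sol, mat, mesh, cls, NO_CUTS)
        shifted = sol
        shifted.N = sol.N + np.tile([1.0, -2.0, 0.5], sol.N.shape[0] // 3)[:, None]
        shifted.b = sol.b + 7.0
        eff2 = homogenize(shifted, mat, mesh, cls, NO_CUTS)
        np.testing.assert_allclose(eff2.C_bar, eff.C_bar, rtol=1e-10)
        np.testing.assert_allclose(eff2.beta_bar, eff.beta_bar, atol=1e-10)
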