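"""Finite-element kernels and the quasi-static solver."""

import numpy as np
import pytest

from pelvifem.constitutive import uniaxial_nominal_stress
from pelvifem.fem import (
    BoundaryConditions,
    SolverSettings,
    default_bulk_penalty,
    element_internal_force,
    solve_quasistatic,
    tet_jacobians,
    truss_internal_force,
)
from pelvifem.mesh import MeshError
from pelvifem.synthetic import fixture_cube

UNIT_TET = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)


@pytest.fixture(scope="module")
def fascia(structure_params):
    return structure_params["collagen_rich_fascia"]


@pytest.fixture(scope="module")
def cube_solution(structure_params):
    """Uniaxial stretch of a tetrahedralized cube to lambda = 1.1.

    The prescribed-displacement boundary conditions (axial faces moved,
    symmetry planes held) admit the homogeneous closed-form solution.
    """
    fascia = structure_params["collagen_rich_fascia"]
    cube = fixture_cube(2)
    side = 10.0
    n = cube.n_nodes
    fixed = np.zeros((n, 3), dtype=bool)
    prescribed = np.zeros((n, 3))
    fixed[cube.node_sets["xmin"], 0] = True
    fixed[cube.node_sets["xmax"], 0] = True
    prescribed[cube.node_sets["xmax"], 0] = 0.1 * side
    fixed[cube.node_sets["ymin"], 1] = True
    fixed[cube.node_sets["zmin"], 2] = True
    bc = BoundaryConditions(fixed_mask=fixed, prescribed=prescribed)
    settings = SolverSettings(penalty_bulk=1e3 * fascia.c01)
    solution = solve_quasistatic(cube, bc, {"bulk": fascia}, settings)
    return cube, bc, settings, solution


class TestTetElement:
    def test_zero_displacement_zero_force(self, fascia):
        f, _ = element_internal_force(UNIT_TET, fascia, np.zeros((4, 3)), kappa=100.0)
        assert np.abs(f).max() == 0.0

    def test_rigid_translation_zero_force(self, fascia):
        u = np.tile([0.3, -0.2, 0.5], (4, 1))
        f, _ = element_internal_force(UNIT_TET, fascia, u, kappa=100.0)
        assert np.abs(f).max() < 1e-12

    def test_tangent_matches_finite_difference(self, fascia):
        rng = np.random.default_rng(0)
        u0 = rng.normal(0.0, 0.02, (4, 3))
        _, k = element_internal_force(UNIT_TET, fascia, u0, kappa=100.0)
        h = 1e-7
        k_fd = np.zeros((12, 12))
        for dof in range(12):
            du = np.zeros(12)
            du[dof] = h
            fp, _ = element_internal_force(
                UNIT_TET, fascia, u0 + du.reshape(4, 3), kappa=100.0
            )
            fm, _ = element_internal_force(
                UNIT_TET, fascia, u0 - du.reshape(4, 3), kappa=100.0
            )
            k_fd[:, dof] = (fp - fm) / (2.0 * h)
        assert np.abs(k - k_fd).max() / np.abs(k_fd).max() < 1e-5

    def test_degenerate_tet_rejected(self, fascia):
        flat = UNIT_TET.copy()
        flat[3] = [1.0, 1.0, 0.0]  # coplanar
        with pytest.raises(MeshError):
            element_internal_force(flat, fascia, np.zeros((4, 3)), kappa=100.0)


class TestTrussElement:
    def test_unit_stretch_zero_force(self, structure_params):
        pul = structure_params["pubourethral_ligament"]
        nodes = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        f, _ = truss_internal_force(nodes, pul, np.zeros((2, 3)), area=10.0)
        assert np.abs(f).max() == 0.0

    def test_axial_stress_matches_closed_form(self, structure_params):
        # hand evaluation of the uniaxial nominal stress at lambda = 1.1
        pul = structure_params["pubourethral_ligament"]
        lam = 1.1
        base = lam - lam**-2
        expected_stress = 2.0 * 0.68 * base + 4.0 * 5.0 * base * (
            lam**2 + 2.0 / lam - 3.0
        )
        nodes = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        u = np.zeros((2, 3))
        u[1, 0] = 1.0  # stretch to 11 mm
        area = 10.0
        f, _ = truss_internal_force(nodes, pul, u, area=area)
        assert f[3] == pytest.approx(expected_stress * area, rel=1e-12)
        assert f[0] == pytest.approx(-expected_stress * area, rel=1e-12)

    def test_slack_in_compression_by_default(self, structure_params):
        pul = structure_params["pubourethral_ligament"]
        nodes = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        u = np.zeros((2, 3))
        u[1, 0] = -1.0  # lambda = 0.9, well below the engagement window
        f, k = truss_internal_force(nodes, pul, u, area=10.0)
        assert np.abs(f).max() == 0.0
        assert np.abs(k).max() == 0.0
        f_c, _ = truss_internal_force(nodes, pul, u, area=10.0, tension_only=False)
        assert f_c[3] < 0.0  # compression carried when slack mode is off

    def test_zero_length_rejected(self, structure_params):
        pul = structure_params["pubourethral_ligament"]
        nodes = np.zeros((2, 3))
        with pytest.raises(MeshError):
            truss_internal_force(nodes, pul, np.zeros((2, 3)), area=1.0)


class TestQuasistaticSolve:
    def test_zero_load_zero_displacement(self, fascia):
        cube = fixture_cube(1)
        fixed = np.zeros((cube.n_nodes, 3), dtype=bool)
        fixed[cube.node_sets["zmin"]] = True
        bc = BoundaryConditions(fixed_mask=fixed)
        solution = solve_quasistatic(
            cube, bc, {"bulk": fascia}, SolverSettings(n_load_steps=1)
        )
        assert np.abs(solution.final_displacement).max() == 0.0
        assert solution.converged

    def test_cube_uniaxial_matches_closed_form(self, cube_solution, structure_params):
        cube, _, _, solution = cube_solution
        side = 10.0
        reaction = solution.reaction_forces[cube.node_sets["xmax"], 0].sum()
        nominal = reaction / side**2
        expected = uniaxial_nominal_stress(
            structure_params["collagen_rich_fascia"], 1.1
        )
        assert expected == pytest.approx(0.3222, abs=5e-5)
        assert nominal == pytest.approx(expected, rel=0.01)

    def test_cube_volume_preserved(self, cube_solution):
        cube, _, _, solution = cube_solution
        j = tet_jacobians(cube, solution.final_displacement)
        assert np.abs(j - 1.0).max() <= 1e-3

    def test_penalty_insensitivity(self, cube_solution, structure_params):
        # doubling kappa changes the reaction by < 0.5% and tightens J
        cube, bc, settings, solution = cube_solution
        fascia = structure_params["collagen_rich_fascia"]
        doubled = SolverSettings(penalty_bulk=2e3 * fascia.c01)
        solution2 = solve_quasistatic(cube, bc, {"bulk": fascia}, doubled)
        r1 = solution.reaction_forces[cube.node_sets["xmax"], 0].sum()
        r2 = solution2.reaction_forces[cube.node_sets["xmax"], 0].sum()
        assert abs(r2 - r1) / abs(r1) < 0.005
        j1 = np.abs(tet_jacobians(cube, solution.final_displacement) - 1.0).max()
        j2 = np.abs(tet_jacobians(cube, solution2.final_displacement) - 1.0).max()
        assert j2 < j1
        assert j2 <= 1e-3

    def test_global_equilibrium(self, cube_solution):
        _, _, _, solution = cube_solution
        # no external loads: reactions alone must balance
        assert np.abs(solution.reaction_forces.sum(axis=0)).max() < 1e-8

    def test_deterministic_bitwise(self, cube_solution, structure_params):
        cube, bc, settings, solution = cube_solution
        fascia = structure_params["collagen_rich_fascia"]
        repeat = solve_quasistatic(cube, bc, {"bulk": fascia}, settings)
        assert np.array_equal(repeat.displacements, solution.displacements)

    def test_fixed_dofs_exact(self, cube_solution):
        cube, bc, _, solution = cube_solution
        u = solution.final_displacement
        assert np.all(u[bc.fixed_mask] == bc.prescribed[bc.fixed_mask])


class TestBoundaryConditionValidation:
    def test_force_on_fixed_dof_rejected(self):
        cube = fixture_cube(1)
        fixed = np.zeros((cube.n_nodes, 3), dtype=bool)
        fixed[0] = True
        forces = np.zeros((cube.n_nodes, 3))
        forces[0, 2] = 1.0
        with pytest.raises(MeshError):
            BoundaryConditions(fixed_mask=fixed, nodal_forces=forces)

    def test_default_penalty_scales_with_stiffest_term(self, structure_params):
        usl = structure_params["uterosacral_ligament"]
        assert default_bulk_penalty(usl, 1e3) == pytest.approx(8.0e3)
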