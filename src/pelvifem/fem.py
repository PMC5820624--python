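"""Quasi-static total-Lagrangian finite elements for soft tissue.

Bulk tissue is discretized with 4-node (constant-strain) tetrahedra and a
nearly incompressible hyperelastic law: the three-term polynomial energy is
evaluated on the isochoric invariants (I1_bar = J^{-2/3} I1,
I2_bar = J^{-4/3} I2) and the exact incompressibility multiplier is
replaced by a volumetric penalty U(J) = kappa/2 (J - 1)^2.  Ligaments are
2-node truss elements carrying the closed-form uniaxial nominal stress of
their material; by default they are tension-only (a slack ligament carries
no compression).

The nonlinear system is solved by incremental loading with Newton
iterations.  The material part of the tangent uses the first elasticity
tensor dP/dF obtained by vectorized central finite differences of the
analytic stress (step 1e-6 on the components of F); follower pressures
contribute their exact (unsymmetric) load stiffness.  Everything is plain
NumPy/SciPy and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    HyperelasticParams,
    InvalidDeformationError,
    Material,
    VoigtMixture,
    uniaxial_nominal_stress,
    uniaxial_nominal_stress_slope,
)
from .mesh import Mesh, MeshError, tet_volumes

__all__ = [
    "BoundaryConditions",
    "SolverError",
    "SolverSettings",
    "SolutionField",
    "default_bulk_penalty",
    "element_internal_force",
    "pk1_stress_penalty",
    "solve_quasistatic",
    "truss_internal_force",
]

_FD_STEP = 1e-6  # perturbation on F for the elasticity tensor
_SLACK_SMOOTHING = 0.01  # stretch half-window of the tension-only engagement


class SolverError(RuntimeError):
    """Raised when the nonlinear solve cannot be completed."""


# ---------------------------------------------------------------------------
# boundary conditions and settings
# ---------------------------------------------------------------------------


@dataclass
class BoundaryConditions:
    """Dirichlet data, nodal forces (N) and face pressures (MPa).

    ``pressure_faces`` are surface triangles ordered so that the right-hand
    normal points out of the loaded body; a positive pressure pushes
    against that normal (compression onto the surface).
    """

    fixed_mask: np.ndarray  # (N, 3) bool
    prescribed: np.ndarray | None = None  # (N, 3) values at full load, mm
    nodal_forces: np.ndarray | None = None  # (N, 3) at full load, N
    pressure_faces: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=int)
    )
    face_pressures: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self) -> None:
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        n = self.fixed_mask.shape[0]
        if self.prescribed is None:
            self.prescribed = np.zeros((n, 3))
        self.prescribed = np.asarray(self.prescribed, dtype=float)
        if self.nodal_forces is None:
            self.nodal_forces = np.zeros((n, 3))
        self.nodal_forces = np.asarray(self.nodal_forces, dtype=float)
        self.pressure_faces = np.asarray(self.pressure_faces, dtype=int).reshape(-1, 3)
        self.face_pressures = np.atleast_1d(
            np.asarray(self.face_pressures, dtype=float)
        )
        if self.fixed_mask.shape != (n, 3) or self.prescribed.shape != (n, 3):
            raise MeshError("boundary-condition arrays must have shape (n_nodes, 3)")
        if self.nodal_forces.shape != (n, 3):
            raise MeshError("nodal_forces must have shape (n_nodes, 3)")
        if self.face_pressures.shape[0] != self.pressure_faces.shape[0]:
            raise MeshError("one pressure magnitude required per pressure face")
        if np.any(self.nodal_forces[self.fixed_mask] != 0.0):
            raise MeshError("a dof cannot be both fixed and force-loaded")

    def validate_against(self, mesh: Mesh) -> None:
        if self.fixed_mask.shape[0] != mesh.n_nodes:
            raise MeshError("boundary conditions sized for a different mesh")
        if self.pressure_faces.size and self.pressure_faces.max() >= mesh.n_nodes:
            raise MeshError("pressure face references missing nodes")


@dataclass
class SolverSettings:
    """Numerical controls of the incremental Newton solve."""

    n_load_steps: int = 10
    newton_tol: float = 1e-9
    max_newton_iters: int = 25
    penalty_factor: float = 1e3  # kappa = factor x largest deviatoric coefficient
    penalty_bulk: float | None = None  # explicit kappa (MPa), overrides the factor
    follower_pressure: bool = True
    tension_only_trusses: bool = True
    max_bisections: int = 8

    def __post_init__(self) -> None:
        if self.n_load_steps < 1:
            raise ValueError("n_load_steps must be >= 1")
        if self.newton_tol <= 0.0:
            raise ValueError("newton_tol must be positive")
        if self.penalty_bulk is not None and self.penalty_bulk <= 0.0:
            raise ValueError("penalty_bulk must be positive")


@dataclass
class SolutionField:
    """Converged displacement history of a quasi-static solve."""

    displacements: np.ndarray  # (n_steps, N, 3) mm
    load_factors: np.ndarray  # (n_steps,)
    converged: bool
    reaction_forces: np.ndarray  # (N, 3) at final state, N
    diagnostics: dict

    @property
    def final_displacement(self) -> np.ndarray:
        return self.displacements[-1]


# ---------------------------------------------------------------------------
# constitutive evaluation (vectorized over elements)
# ---------------------------------------------------------------------------


def default_bulk_penalty(material: Material, factor: float = 1e3) -> float:
    """Penalty bulk modulus: *factor* times the largest effective coefficient.

    For a Voigt mixture the effective coefficients are the
    volume-fraction-weighted sums.
    """
    phases = (
        material.phases if isinstance(material, VoigtMixture) else ((1.0, material),)
    )
    c10 = sum(f * p.c10 for f, p in phases)
    c01 = sum(f * p.c01 for f, p in phases)
    c20 = sum(f * p.c20 for f, p in phases)
    largest = max(abs(c10), abs(c01), abs(c20))
    if largest == 0.0:
        raise ValueError("material has all-zero coefficients; no penalty scale")
    return factor * largest


def pk1_stress_penalty(material: Material, kappa: float, f: np.ndarray) -> np.ndarray:
    """First Piola-Kirchhoff stress of the penalty-regularized law.

    W = W_dev(I1_bar, I2_bar) + kappa/2 (J - 1)^2 evaluated for a batch of
    deformation gradients *f* of shape (..., 3, 3).
    """
    f = np.asarray(f, dtype=float)
    j = np.linalg.det(f)
    if np.any(j <= 0.0):
        raise InvalidDeformationError("inverted element: det F <= 0")
    c = np.einsum("...ji,...jk->...ik", f, f)
    i1 = np.trace(c, axis1=-2, axis2=-1)
    i2 = 0.5 * (i1**2 - np.trace(np.einsum("...ij,...jk->...ik", c, c), axis1=-2, axis2=-1))
    i3 = j**2
    i1b = i3 ** (-1.0 / 3.0) * i1
    i2b = i3 ** (-2.0 / 3.0) * i2
    w1, w2 = material.energy_derivatives(i1b, i2b)
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)

    c_inv = np.linalg.inv(c)
    eye = np.broadcast_to(np.eye(3), c.shape)
    a1 = i3[..., None, None] ** (-1.0 / 3.0) * (
        eye - (i1 / 3.0)[..., None, None] * c_inv
    )
    a2 = i3[..., None, None] ** (-2.0 / 3.0) * (
        i1[..., None, None] * eye - c - (2.0 * i2 / 3.0)[..., None, None] * c_inv
    )
    s = (
        2.0 * w1[..., None, None] * a1
        + 2.0 * w2[..., None, None] * a2
        + (kappa * (j - 1.0) * j)[..., None, None] * c_inv
    )
    return np.einsum("...ij,...jk->...ik", f, s)


_FD_DIRECTIONS = np.zeros((9, 3, 3))
for _c, (_k, _l) in enumerate(np.ndindex(3, 3)):
    _FD_DIRECTIONS[_c, _k, _l] = _FD_STEP


def _elasticity_tensor_fd(
    material: Material, kappa: float, f: np.ndarray
) -> np.ndarray:
    """dP/dF by central differences, shape (M, 3, 3, 3, 3).

    All 18 perturbed states are evaluated in one batched stress call.
    """
    f = np.asarray(f, dtype=float)
    m = f.shape[0]
    # (2, 9, M, 3, 3): +h and -h perturbations of every F component
    f_pert = np.empty((2, 9, m, 3, 3))
    f_pert[0] = f[None, :, :, :] + _FD_DIRECTIONS[:, None, :, :]
    f_pert[1] = f[None, :, :, :] - _FD_DIRECTIONS[:, None, :, :]
    p = pk1_stress_penalty(material, kappa, f_pert.reshape(-1, 3, 3))
    p = p.reshape(2, 9, m, 3, 3)
    # a[m, i, j, k, l] = dP_ij/dF_kl
    a = (p[0] - p[1]).transpose(1, 2, 3, 0) / (2.0 * _FD_STEP)
    return a.reshape(m, 3, 3, 3, 3)


# ---------------------------------------------------------------------------
# element kernels
# ---------------------------------------------------------------------------


def _tet_shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Constant shape-function gradients per tet, shape (M, 4, 3)."""
    x = nodes[tets]
    e = np.swapaxes(x[:, 1:, :] - x[:, :1, :], 1, 2)  # columns = edge vectors
    e_inv = np.linalg.inv(e)
    g = np.empty((tets.shape[0], 4, 3))
    g[:, 1:, :] = e_inv  # gradient of N_a (a=1..3) is row a-1 of E^{-1}
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g


def _deformation_gradients(
    u: np.ndarray, tets: np.ndarray, g: np.ndarray
) -> np.ndarray:
    """F = I + sum_a u_a (x) grad N_a for every tet, shape (M, 3, 3)."""
    u_el = u[tets]  # (M, 4, 3)
    grad_u = np.einsum("mai,maj->mij", u_el, g)
    return np.eye(3) + grad_u


def _tet_forces_batch(
    u: np.ndarray,
    tets: np.ndarray,
    g: np.ndarray,
    v0: np.ndarray,
    material: Material,
    kappa: float,
    with_tangent: bool,
):
    f_def = _deformation_gradients(u, tets, g)
    p = pk1_stress_penalty(material, kappa, f_def)
    forces = np.einsum("m,mij,maj->mai", v0, p, g)  # (M, 4, 3)
    if not with_tangent:
        return forces, None, f_def
    a = _elasticity_tensor_fd(material, kappa, f_def)
    k_el = np.einsum("m,mijkl,maj,mbl->maibk", v0, a, g, g)
    return forces, k_el.reshape(tets.shape[0], 12, 12), f_def


def tet_jacobians(mesh: Mesh, displacements: np.ndarray) -> np.ndarray:
    """det F of every tetrahedron at the given displacement field."""
    g = _tet_shape_gradients(mesh.nodes, mesh.tets)
    return np.linalg.det(_deformation_gradients(displacements, mesh.tets, g))


def element_internal_force(
    tet_nodes: np.ndarray,
    material: Material,
    nodal_displacements: np.ndarray,
    kappa: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Internal force (12,) and consistent tangent (12, 12) of one tet.

    *tet_nodes* are the four reference coordinates (4, 3);
    *nodal_displacements* the four displacement vectors (4, 3).
    """
    nodes = np.asarray(tet_nodes, dtype=float).reshape(4, 3)
    u = np.asarray(nodal_displacements, dtype=float).reshape(4, 3)
    tets = np.array([[0, 1, 2, 3]])
    v0 = tet_volumes(nodes, tets)
    if v0[0] <= 0.0:
        raise MeshError("degenerate or inverted reference tetrahedron")
    g = _tet_shape_gradients(nodes, tets)
    forces, k_el, _ = _tet_forces_batch(u, tets, g, v0, material, kappa, True)
    return forces.reshape(12), k_el[0]


def _truss_forces_batch(
    u: np.ndarray,
    nodes: np.ndarray,
    trusses: np.ndarray,
    areas: np.ndarray,
    l0: np.ndarray,
    material: Material,
    tension_only: bool,
):
    """Axial forces (K, 2, 3) and tangents (K, 6, 6) of a truss group."""
    x = nodes + u
    d = x[trusses[:, 1]] - x[trusses[:, 0]]
    length = np.linalg.norm(d, axis=1)
    if np.any(length <= 0.0):
        raise InvalidDeformationError("truss collapsed to zero length")
    n_hat = d / length[:, None]
    lam = length / l0
    axial = areas * uniaxial_nominal_stress(material, lam)  # N
    slope = areas * uniaxial_nominal_stress_slope(material, lam) / l0
    if tension_only:
        # smooth slack-to-taut engagement (C1 over a small stretch window)
        # instead of a hard cut at lambda = 1: avoids Newton chatter when a
        # ligament sits exactly at its reference length
        eps = _SLACK_SMOOTHING
        t = np.clip((lam - (1.0 - eps)) / (2.0 * eps), 0.0, 1.0)
        engage = t * t * (3.0 - 2.0 * t)
        dengage = np.where((t > 0.0) & (t < 1.0), 6.0 * t * (1.0 - t) / (2.0 * eps), 0.0)
        slope = engage * slope + dengage * (axial / l0)
        axial = engage * axial

    forces = np.empty((trusses.shape[0], 2, 3))
    forces[:, 0, :] = -axial[:, None] * n_hat
    forces[:, 1, :] = axial[:, None] * n_hat

    nn = np.einsum("ki,kj->kij", n_hat, n_hat)
    eye = np.broadcast_to(np.eye(3), nn.shape)
    k_loc = slope[:, None, None] * nn + (axial / length)[:, None, None] * (eye - nn)
    k_el = np.empty((trusses.shape[0], 6, 6))
    k_el[:, :3, :3] = k_loc
    k_el[:, 3:, 3:] = k_loc
    k_el[:, :3, 3:] = -k_loc
    k_el[:, 3:, :3] = -k_loc
    return forces, k_el, lam


def truss_internal_force(
    end_nodes: np.ndarray,
    material: Material,
    nodal_displacements: np.ndarray,
    area: float,
    tension_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Internal force (6,) and tangent (6, 6) of one ligament truss."""
    nodes = np.asarray(end_nodes, dtype=float).reshape(2, 3)
    u = np.asarray(nodal_displacements, dtype=float).reshape(2, 3)
    l0 = float(np.linalg.norm(nodes[1] - nodes[0]))
    if l0 <= 0.0:
        raise MeshError("degenerate truss: zero reference length")
    forces, k_el, _ = _truss_forces_batch(
        u,
        nodes,
        np.array([[0, 1]]),
        np.array([area], dtype=float),
        np.array([l0]),
        material,
        tension_only,
    )
    return forces.reshape(6), k_el[0]


# ---------------------------------------------------------------------------
# loads
# ---------------------------------------------------------------------------


def _skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrices [v]x for a batch of vectors (T, 3)."""
    t = v.shape[0]
    s = np.zeros((t, 3, 3))
    s[:, 0, 1], s[:, 0, 2] = -v[:, 2], v[:, 1]
    s[:, 1, 0], s[:, 1, 2] = v[:, 2], -v[:, 0]
    s[:, 2, 0], s[:, 2, 1] = -v[:, 1], v[:, 0]
    return s


def _pressure_load_stiffness(
    coords: np.ndarray, faces: np.ndarray, pressures: np.ndarray, n_dof: int
) -> sp.csr_matrix:
    """d f_ext / d u of follower face pressures (unsymmetric).

    The nodal force of a pressurized triangle is -(p/6) (x10 x x20) on each
    of its three nodes; its exact linearization w.r.t. the node positions
    is assembled so that Newton retains its quadratic rate when the load
    stiffness is comparable to the material stiffness (heavily impaired
    tissue).
    """
    if faces.shape[0] == 0:
        return sp.csr_matrix((n_dof, n_dof))
    x = coords[faces]
    x10 = x[:, 1] - x[:, 0]
    x20 = x[:, 2] - x[:, 0]
    d = np.empty((faces.shape[0], 3, 3, 3))  # (T, b, i, j)
    d[:, 1] = -_skew(x20)
    d[:, 2] = _skew(x10)
    d[:, 0] = _skew(x20 - x10)
    blocks = -(pressures[:, None, None, None] / 6.0) * d  # dF/dx_b, any row a
    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            ra = (3 * faces[:, a, None] + np.arange(3))[:, :, None]
            cb = (3 * faces[:, b, None] + np.arange(3))[:, None, :]
            rows.append(np.broadcast_to(ra, blocks[:, b].shape).ravel())
            cols.append(np.broadcast_to(cb, blocks[:, b].shape).ravel())
            vals.append(blocks[:, b].ravel())
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    ).tocsr()


def _pressure_forces(
    coords: np.ndarray, faces: np.ndarray, pressures: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Consistent nodal forces of face pressures on (possibly deformed) coords."""
    out = np.zeros((n_nodes, 3))
    if faces.shape[0] == 0:
        return out
    x = coords[faces]
    normal_area2 = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])  # 2 A n
    f_face = -(pressures[:, None] / 6.0) * normal_area2  # per node
    for a in range(3):
        np.add.at(out, faces[:, a], f_face)
    return out


# ---------------------------------------------------------------------------
# assembly and Newton solve
# ---------------------------------------------------------------------------


class _Assembler:
    """Groups elements by region and assembles forces and tangents."""

    def __init__(
        self,
        mesh: Mesh,
        materials: dict[str, Material],
        settings: SolverSettings,
    ) -> None:
        self.mesh = mesh
        self.settings = settings
        self.tet_groups = []
        for region in dict.fromkeys(mesh.tet_regions):
            if region not in materials:
                raise SolverError(f"no material assigned to tet region {region!r}")
            idx = mesh.region_tets(region)
            tets = mesh.tets[idx]
            material = materials[region]
            kappa = (
                settings.penalty_bulk
                if settings.penalty_bulk is not None
                else default_bulk_penalty(material, settings.penalty_factor)
            )
            self.tet_groups.append(
                {
                    "tets": tets,
                    "g": _tet_shape_gradients(mesh.nodes, tets),
                    "v0": tet_volumes(mesh.nodes, tets),
                    "material": material,
                    "kappa": kappa,
                    "dofs": (3 * tets[:, :, None] + np.arange(3)).reshape(-1, 12),
                }
            )
        self.truss_groups = []
        for region in dict.fromkeys(mesh.truss_regions):
            if region not in materials:
                raise SolverError(f"no material assigned to truss region {region!r}")
            idx = mesh.region_trusses(region)
            trusses = mesh.trusses[idx]
            d = mesh.nodes[trusses[:, 1]] - mesh.nodes[trusses[:, 0]]
            self.truss_groups.append(
                {
                    "trusses": trusses,
                    "areas": mesh.truss_areas[idx],
                    "l0": np.linalg.norm(d, axis=1),
                    "material": materials[region],
                    "dofs": (3 * trusses[:, :, None] + np.arange(3)).reshape(-1, 6),
                }
            )

    def internal(self, u: np.ndarray, with_tangent: bool):
        n_dof = 3 * self.mesh.n_nodes
        f_int = np.zeros((self.mesh.n_nodes, 3))
        rows, cols, vals = [], [], []
        j_extremes = [np.inf, -np.inf]
        for grp in self.tet_groups:
            forces, k_el, f_def = _tet_forces_batch(
                u,
                grp["tets"],
                grp["g"],
                grp["v0"],
                grp["material"],
                grp["kappa"],
                with_tangent,
            )
            dets = np.linalg.det(f_def)
            j_extremes[0] = min(j_extremes[0], float(dets.min()))
            j_extremes[1] = max(j_extremes[1], float(dets.max()))
            np.add.at(f_int.reshape(-1), grp["dofs"].ravel(), forces.ravel())
            if with_tangent:
                dofs = grp["dofs"]
                rows.append(np.repeat(dofs, 12, axis=1).ravel())
                cols.append(np.tile(dofs, (1, 12)).ravel())
                vals.append(k_el.ravel())
        for grp in self.truss_groups:
            forces, k_el, _ = _truss_forces_batch(
                u,
                self.mesh.nodes,
                grp["trusses"],
                grp["areas"],
                grp["l0"],
                grp["material"],
                self.settings.tension_only_trusses,
            )
            np.add.at(f_int.reshape(-1), grp["dofs"].ravel(), forces.ravel())
            if with_tangent:
                dofs = grp["dofs"]
                rows.append(np.repeat(dofs, 6, axis=1).ravel())
                cols.append(np.tile(dofs, (1, 6)).ravel())
                vals.append(k_el.ravel())
        k = None
        if with_tangent:
            k = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n_dof, n_dof),
            ).tocsr()
        return f_int, k, j_extremes

    def external(self, u: np.ndarray, bc: BoundaryConditions, factor: float):
        f_ext = factor * bc.nodal_forces
        coords = (
            self.mesh.nodes + u
            if self.settings.follower_pressure
            else self.mesh.nodes
        )
        f_ext = f_ext + _pressure_forces(
            coords, bc.pressure_faces, factor * bc.face_pressures, self.mesh.n_nodes
        )
        return f_ext

    def external_stiffness(
        self, u: np.ndarray, bc: BoundaryConditions, factor: float
    ) -> sp.csr_matrix | None:
        """d f_ext / d u (follower pressures only; None for dead loads)."""
        if not self.settings.follower_pressure or bc.pressure_faces.shape[0] == 0:
            return None
        return _pressure_load_stiffness(
            self.mesh.nodes + u,
            bc.pressure_faces,
            factor * bc.face_pressures,
            3 * self.mesh.n_nodes,
        )


def solve_quasistatic(
    mesh: Mesh,
    bc: BoundaryConditions,
    materials: dict[str, Material],
    settings: SolverSettings | None = None,
    initial_displacements: np.ndarray | None = None,
) -> SolutionField:
    """Incremental Newton solve of the quasi-static equilibrium problem.

    Loads and prescribed displacements are ramped proportionally; on
    divergence or element inversion the increment is bisected (up to
    ``max_bisections`` times).  Raises :class:`SolverError` if the full
    load cannot be reached.

    *initial_displacements* warm-starts the solve (e.g. from a converged
    state of a slightly different material set): the full load is then
    attempted in a single step before falling back to ramping.
    """
    settings = settings or SolverSettings()
    bc.validate_against(mesh)
    asm = _Assembler(mesh, materials, settings)

    free = ~bc.fixed_mask.reshape(-1)
    u = np.zeros((mesh.n_nodes, 3))
    history, factors = [], []
    worst_residual = 0.0
    j_range = [np.inf, -np.inf]

    reached = 0.0
    d_gamma = 1.0 / settings.n_load_steps
    if initial_displacements is not None:
        u = np.asarray(initial_displacements, dtype=float).copy()
        if u.shape != (mesh.n_nodes, 3):
            raise ValueError("initial_displacements must have shape (n_nodes, 3)")
        d_gamma = 1.0
    bisections = 0
    successes = 0
    while reached < 1.0 - 1e-12:
        target = reached + d_gamma
        if target >= 1.0 - 1e-12:
            target = 1.0
        u_trial = u.copy()
        u_trial[bc.fixed_mask] = target * bc.prescribed[bc.fixed_mask]
        ok = False
        try:
            for _ in range(settings.max_newton_iters):
                f_int, k, j_ext = asm.internal(u_trial, with_tangent=True)
                j_range[0] = min(j_range[0], j_ext[0])
                j_range[1] = max(j_range[1], j_ext[1])
                f_ext = asm.external(u_trial, bc, target)
                residual = (f_int - f_ext).reshape(-1)
                ref = max(
                    float(np.linalg.norm(f_ext)),
                    float(np.linalg.norm(f_int)),
                    1e-10,
                )
                res_norm = float(np.linalg.norm(residual[free]))
                if res_norm <= settings.newton_tol * ref:
                    ok = True
                    break
                k_ext = asm.external_stiffness(u_trial, bc, target)
                if k_ext is not None:
                    k = k - k_ext
                k_ff = k[free][:, free]
                delta = spla.spsolve(k_ff.tocsc(), -residual[free])
                if not np.all(np.isfinite(delta)):
                    break
                # full Newton steps; halve only if a step would invert an
                # element (the residual itself is allowed to grow
                # transiently, e.g. at slack-ligament state changes)
                alpha = 1.0
                accepted = None
                for _ls in range(6):
                    u_try = u_trial.copy()
                    u_try.reshape(-1)[free] += alpha * delta
                    try:
                        asm.internal(u_try, with_tangent=False)
                    except InvalidDeformationError:
                        alpha *= 0.5
                        continue
                    accepted = u_try
                    break
                if accepted is None:
                    raise InvalidDeformationError("no admissible Newton step")
                u_trial = accepted
        except InvalidDeformationError:
            ok = False
        if ok:
            u = u_trial
            reached = target
            history.append(u.copy())
            factors.append(reached)
            worst_residual = max(worst_residual, res_norm / ref)
            # recover the step size after two consecutive successes
            successes += 1
            if successes >= 2 and d_gamma < 1.0 / settings.n_load_steps:
                d_gamma = min(2.0 * d_gamma, 1.0 / settings.n_load_steps)
                successes = 0
        else:
            bisections += 1
            successes = 0
            d_gamma *= 0.5
            if bisections > settings.max_bisections:
                raise SolverError(
                    "load step failed after "
                    f"{settings.max_bisections} bisections at load factor "
                    f"{reached:.3f} (det F range {j_range})"
                )

    f_int, _, _ = asm.internal(u, with_tangent=False)
    f_ext = asm.external(u, bc, 1.0)
    reactions = np.where(bc.fixed_mask, f_int - f_ext, 0.0)
    return SolutionField(
        displacements=np.array(history),
        load_factors=np.array(factors),
        converged=True,
        reaction_forces=reactions,
        diagnostics={
            "worst_relative_residual": worst_residual,
            "det_f_range": tuple(j_range),
            "n_increments": len(factors),
            "n_bisections": bisections,
        },
    )
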