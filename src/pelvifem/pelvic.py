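"""Idealized pelvic-floor model, clinical measurements, impairment sweeps.

The geometry is a deliberately simple, parametrized stand-in for a
cadaver-derived pelvic mesh: an endopelvic-fascia hammock (a tet plate
fixed at its lateral and posterior margins, the pelvic-sidewall and sacrum
analogues) carrying a soft organ block (bladder analogue), suspended by
ligament trusses (pubourethral, uterosacral, cardinal) anchored at fixed
bone points.  The hammock has a collagen-rich distal (anterior) strip and
an elastin-rich proximal region, each modelled as a Voigt mixture of
fibre compound, adipose tissue and smooth muscle.  Intra-abdominal
pressure acts on the upward-facing surfaces; small constant muscle forces
pull the bladder neck posteriorly (levator plate) and the anorectal region
inferiorly (longitudinal anal muscle).

Coordinates: x lateral, y anterior (y = 0 is the posterior, sacral
margin), z vertical (cranial positive); mm throughout.  The model supports
the clinical measurements used for stress urinary incontinence:
urethrovesical-junction (UVJ) mobility, urethral axis angle Ur from the
vertical, angle alpha between the midpubic line and the bladder neck, and
the levator plate angle LPA from the horizontal.  Absolute displacements
on this geometry are not comparable to patient data; impairment sweeps are
interpreted through orderings and trends only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constitutive import (
    DEFAULT_FASCIA_COMPOSITION,
    Material,
    MixtureComposition,
    VoigtMixture,
)
from .fem import (
    BoundaryConditions,
    SolutionField,
    SolverError,
    SolverSettings,
    solve_quasistatic,
)
from .materials import load_fascia_constituents, load_pelvic_structures
from .mesh import Mesh, boundary_triangles
from .synthetic import box_grid, kuhn_tets
from .units import cmh2o_to_mpa

__all__ = [
    "FASCIA_REGIONS",
    "LIGAMENT_REGIONS",
    "Landmarks",
    "PelvicConfig",
    "PelvicModel",
    "build_idealized_pelvis",
    "impairment_sweep",
    "measure_alpha",
    "measure_lpa",
    "measure_urethral_angle",
    "measure_uvj",
    "solve_healthy",
    "ur_crossing_level",
    "uvj_resultant",
]

FASCIA_REGIONS = ("collagen_rich_fascia", "elastin_rich_fascia")
LIGAMENT_REGIONS = (
    "pubourethral_ligament",
    "uterosacral_ligament",
    "cardinal_ligament",
)

SWEEP_COLUMNS = [
    "impairment",
    "target",
    "vuvj_mm",
    "huvj_mm",
    "uvj_mm",
    "ur_deg",
    "alpha_deg",
    "lpa_deg",
    "converged",
]


class ConfigurationError(ValueError):
    """Raised for geometrically infeasible pelvic configurations."""


@dataclass(frozen=True)
class PelvicConfig:
    """Parametrization of the idealized pelvic floor (lengths mm).

    The defaults describe a hammock of roughly pelvic dimensions with a
    2.5 cm collagen-rich distal strip, a resting urethral inclination of
    22 degrees from the vertical, a resting midpubic-line angle alpha of
    110 degrees, and a supine-Valsalva intra-abdominal pressure of
    40 cm H2O.  Muscle forces are small constants in the directions of the
    Integral Theory (levator plate posterior, longitudinal anal muscle
    inferior), sized so that the healthy urethral angle stays within
    10 degrees of rest.
    """

    # fascia hammock
    hammock_span: float = 80.0
    hammock_depth: float = 100.0
    hammock_thickness: float = 3.0
    collagen_strip_length: float = 25.0  # distal (anterior) strip
    n_span: int = 8
    n_depth: int = 10
    n_thickness: int = 1
    # organ block (bladder analogue) resting on the hammock
    organ_span: float = 40.0
    organ_depth: float = 40.0
    organ_height: float = 30.0
    organ_anterior_y: float = 80.0
    organ_divisions: tuple[int, int, int] = (4, 4, 2)
    # urethra and landmark geometry
    urethra_length: float = 30.0
    urethral_rest_angle_deg: float = 22.0
    urethra_area: float = 5.0
    midpubic_point: tuple[float, float, float] = (0.0, 105.0, 0.0)
    midpubic_tilt_deg: float = 20.0
    levator_line_length: float = 30.0
    # ligaments: fixed bone anchors and reference cross-sections
    pul_anchor: tuple[float, float, float] = (0.0, 110.0, 5.0)
    pul_area: float = 10.0
    usl_anchor: tuple[float, float, float] = (0.0, -20.0, 35.0)
    usl_area: float = 15.0
    cl_anchor_halfspan: float = 55.0
    cl_anchor: tuple[float, float] = (50.0, 35.0)  # (y, z) of the +/-x anchors
    cl_area: float = 10.0
    # loads
    iap_cmh2o: float = 40.0
    lp_force_n: float = 0.5
    lma_force_n: float = 0.5
    neck_pressure_cmh2o: float = 0.0
    # composition of the fascia mixture
    fascia_composition: MixtureComposition = DEFAULT_FASCIA_COMPOSITION

    def __post_init__(self) -> None:
        for name in (
            "hammock_span",
            "hammock_depth",
            "hammock_thickness",
            "organ_span",
            "organ_depth",
            "organ_height",
            "urethra_length",
            "levator_line_length",
        ):
            if getattr(self, name) <= 0.0:
                raise ConfigurationError(f"{name} must be positive")
        if self.collagen_strip_length < 0.0:
            raise ConfigurationError("collagen_strip_length must be >= 0")
        if self.collagen_strip_length > self.hammock_depth:
            raise ConfigurationError("collagen strip cannot exceed hammock depth")
        if self.iap_cmh2o < 0.0:
            raise ConfigurationError("IAP must be non-negative")
        if self.n_span % 2 or self.organ_divisions[0] % 2:
            raise ConfigurationError(
                "n_span and the organ x-division must be even "
                "(mid-sagittal landmarks must fall on grid nodes)"
            )


@dataclass(frozen=True)
class Landmarks:
    """Node indices of the measurement landmarks."""

    uvj: int
    urethra_proximal: int
    urethra_distal: int
    midpubic_line: tuple[int, int]
    levator_line: tuple[int, int]  # (coccyx end, anorectal-junction end)


@dataclass
class PelvicModel:
    """A ready-to-solve idealized pelvic floor."""

    config: PelvicConfig
    mesh: Mesh
    bc: BoundaryConditions
    landmarks: Landmarks
    materials: dict[str, Material]


def _grid_index(value: float, origin: float, spacing: float, label: str) -> int:
    raw = (value - origin) / spacing
    idx = int(round(raw))
    if abs(raw - idx) > 1e-9:
        raise ConfigurationError(
            f"{label} = {value} does not fall on a hammock grid line "
            f"(spacing {spacing})"
        )
    return idx


def default_materials(config: PelvicConfig) -> dict[str, Material]:
    """Region-to-material map of the healthy model.

    The two hammock regions are Voigt mixtures sharing the adipose and
    smooth-muscle phases; the fibre phase is the collagen-rich fascia
    distally and its 75%-reduced elastin-rich variant proximally.
    """
    constituents = load_fascia_constituents()
    structures = load_pelvic_structures()
    mixtures = {
        "collagen_rich_fascia": structures["collagen_rich_fascia"],
        "elastin_rich_fascia": structures["elastin_rich_fascia"],
    }
    materials: dict[str, Material] = {
        region: VoigtMixture.from_composition(
            config.fascia_composition,
            fas=fibre,
            ad=constituents["adipose"],
            sm=constituents["smooth_muscle"],
        )
        for region, fibre in mixtures.items()
    }
    materials["vesica"] = structures["vesica_urethra"]
    materials["urethra"] = structures["vesica_urethra"]
    materials["pubourethral_ligament"] = structures["pubourethral_ligament"]
    materials["uterosacral_ligament"] = structures["uterosacral_ligament"]
    materials["cardinal_ligament"] = structures["cardinal_ligament"]
    return materials


def build_idealized_pelvis(
    config: PelvicConfig | None = None, seed: int = 0
) -> PelvicModel:
    """Construct the idealized pelvic-floor model.

    Deterministic for a given (config, seed); the seed is reserved for
    future stochastic geometry variants and does not currently alter the
    mesh.
    """
    del seed  # geometry is fully deterministic
    config = config or PelvicConfig()
    w, d, t = config.hammock_span, config.hammock_depth, config.hammock_thickness
    nx, ny, nz = config.n_span, config.n_depth, config.n_thickness
    dx, dy = w / nx, d / ny

    nodes_h, index_h = box_grid((-w / 2.0, 0.0, -t), (w, d, t), (nx, ny, nz))
    nodes = [nodes_h]
    n_running = nodes_h.shape[0]

    # ---- organ block sharing the hammock top-surface nodes -----------------
    ox, oy, ozn = config.organ_divisions
    y0 = config.organ_anterior_y - config.organ_depth
    i0 = _grid_index(-config.organ_span / 2.0, -w / 2.0, dx, "organ left edge")
    j0 = _grid_index(y0, 0.0, dy, "organ posterior edge")
    i1 = _grid_index(config.organ_span / 2.0, -w / 2.0, dx, "organ right edge")
    j1 = _grid_index(config.organ_anterior_y, 0.0, dy, "organ anterior edge")
    if not (0 <= i0 < i1 <= nx and 0 <= j0 < j1 <= ny):
        raise ConfigurationError("organ block must lie within the hammock")
    if (i1 - i0, j1 - j0) != (ox, oy):
        raise ConfigurationError(
            "organ_divisions must match the hammock grid spacing under the organ"
        )
    xs = np.linspace(-config.organ_span / 2.0, config.organ_span / 2.0, ox + 1)
    ys = np.linspace(y0, config.organ_anterior_y, oy + 1)
    zs = np.linspace(0.0, config.organ_height, ozn + 1)
    index_o = np.empty((ox + 1, oy + 1, ozn + 1), dtype=int)
    index_o[:, :, 0] = index_h[i0 : i1 + 1, j0 : j1 + 1, nz]
    new_xyz = []
    for k in range(1, ozn + 1):
        for i in range(ox + 1):
            for j in range(oy + 1):
                index_o[i, j, k] = n_running
                new_xyz.append((xs[i], ys[j], zs[k]))
                n_running += 1
    nodes.append(np.array(new_xyz))

    # ---- extra fixed points: meatus, ligament anchors, midpubic line -------
    ur = math.radians(config.urethral_rest_angle_deg)
    uvj_xyz = np.array([0.0, config.organ_anterior_y, 0.0])
    meatus_xyz = uvj_xyz + config.urethra_length * np.array(
        [0.0, math.sin(ur), -math.cos(ur)]
    )
    tilt = math.radians(config.midpubic_tilt_deg)
    mp0 = np.asarray(config.midpubic_point, dtype=float)
    mp1 = mp0 + 20.0 * np.array([0.0, math.sin(tilt), math.cos(tilt)])
    cl_y, cl_z = config.cl_anchor
    extra = {
        "meatus": meatus_xyz,
        "pul_anchor": np.asarray(config.pul_anchor, dtype=float),
        "usl_anchor": np.asarray(config.usl_anchor, dtype=float),
        "cl_anchor_left": np.array([-config.cl_anchor_halfspan, cl_y, cl_z]),
        "cl_anchor_right": np.array([config.cl_anchor_halfspan, cl_y, cl_z]),
        "midpubic_0": mp0,
        "midpubic_1": mp1,
    }
    extra_idx = {}
    for name, xyz in extra.items():
        extra_idx[name] = n_running
        nodes.append(xyz[None, :])
        n_running += 1
    all_nodes = np.vstack(nodes)

    for name in ("pul_anchor", "usl_anchor", "cl_anchor_left", "cl_anchor_right"):
        xyz = extra[name]
        inside = (
            abs(xyz[0]) < w / 2.0
            and 0.0 < xyz[1] < d
            and -t < xyz[2] < (config.organ_height if abs(xyz[0]) < config.organ_span / 2 else 0.0)
        )
        if inside:
            raise ConfigurationError(f"{name} lies inside the solid geometry")

    # ---- tets and regions --------------------------------------------------
    tets_h = kuhn_tets(index_h, all_nodes)
    centroids_y = all_nodes[tets_h, 1].mean(axis=1)
    strip_start = d - config.collagen_strip_length
    regions_h = np.where(
        centroids_y > strip_start, "collagen_rich_fascia", "elastin_rich_fascia"
    ).astype(object)
    tets_o = kuhn_tets(index_o, all_nodes)
    regions_o = np.full(tets_o.shape[0], "vesica", dtype=object)
    tets = np.vstack([tets_h, tets_o])
    regions = np.concatenate([regions_h, regions_o])

    # ---- landmark nodes ----------------------------------------------------
    uvj = int(index_o[ox // 2, oy, 0])
    organ_post_top = int(index_o[ox // 2, 0, ozn])
    organ_left_top = int(index_o[0, oy // 2, ozn])
    organ_right_top = int(index_o[ox, oy // 2, ozn])
    coccyx = int(index_h[nx // 2, 0, nz])
    j_anorectal = _grid_index(config.levator_line_length, 0.0, dy, "levator line end")
    anorectal = int(index_h[nx // 2, j_anorectal, nz])
    if not np.allclose(all_nodes[uvj], uvj_xyz):
        raise ConfigurationError("UVJ landmark does not fall on a mesh node")

    # ---- trusses -----------------------------------------------------------
    trusses = np.array(
        [
            [uvj, extra_idx["meatus"]],
            [uvj, extra_idx["pul_anchor"]],
            [organ_post_top, extra_idx["usl_anchor"]],
            [organ_left_top, extra_idx["cl_anchor_left"]],
            [organ_right_top, extra_idx["cl_anchor_right"]],
        ],
        dtype=int,
    )
    truss_regions = np.array(
        [
            "urethra",
            "pubourethral_ligament",
            "uterosacral_ligament",
            "cardinal_ligament",
            "cardinal_ligament",
        ],
        dtype=object,
    )
    truss_areas = np.array(
        [
            config.urethra_area,
            config.pul_area,
            config.usl_area,
            config.cl_area,
            config.cl_area,
        ]
    )

    node_sets = {
        "sidewall": np.concatenate(
            [index_h[0].ravel(), index_h[nx].ravel()]
        ),
        "sacrum": index_h[:, 0, :].ravel(),
        "pubis": index_h[:, ny, :].ravel(),
        "anchors": np.array(
            [extra_idx[k] for k in extra_idx], dtype=int
        ),
        "uvj": np.array([uvj]),
        "levator_line": np.array([coccyx, anorectal]),
    }

    mesh = Mesh(
        nodes=all_nodes,
        tets=tets,
        tet_regions=regions,
        trusses=trusses,
        truss_regions=truss_regions,
        truss_areas=truss_areas,
        node_sets=node_sets,
    )

    # ---- boundary conditions ----------------------------------------------
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fixed[node_sets["sidewall"]] = True
    fixed[node_sets["sacrum"]] = True
    # the distal fascia fuses with the perineal membrane at the pubis
    # (Level III support): the anterior margin is anchored as well
    fixed[node_sets["pubis"]] = True
    fixed[node_sets["anchors"]] = True

    faces = boundary_triangles(mesh)
    x = all_nodes[faces]
    normals = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    up = normals[:, 2] > 0.5 * np.linalg.norm(normals, axis=1)
    top_faces = faces[up]
    iap = cmh2o_to_mpa(config.iap_cmh2o)
    face_pressures = np.full(top_faces.shape[0], iap)

    forces = np.zeros((mesh.n_nodes, 3))
    forces[uvj, 1] -= config.lp_force_n  # levator plate: posterior pull
    forces[anorectal, 2] -= config.lma_force_n  # longitudinal anal muscle: caudal
    if config.neck_pressure_cmh2o > 0.0:
        # micturition load case: bladder-neck fluid pressure as an opening
        # force along the urethral axis (mean of the linear neck-to-exit
        # profile acting on the urethral cross-section)
        axis = meatus_xyz - uvj_xyz
        axis /= np.linalg.norm(axis)
        magnitude = (
            0.5 * cmh2o_to_mpa(config.neck_pressure_cmh2o) * config.urethra_area
        )
        forces[uvj] += magnitude * axis

    bc = BoundaryConditions(
        fixed_mask=fixed,
        nodal_forces=forces,
        pressure_faces=top_faces,
        face_pressures=face_pressures,
    )
    bc.validate_against(mesh)

    landmarks = Landmarks(
        uvj=uvj,
        urethra_proximal=uvj,
        urethra_distal=extra_idx["meatus"],
        midpubic_line=(extra_idx["midpubic_0"], extra_idx["midpubic_1"]),
        levator_line=(coccyx, anorectal),
    )
    return PelvicModel(
        config=config,
        mesh=mesh,
        bc=bc,
        landmarks=landmarks,
        materials=default_materials(config),
    )


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


class DegenerateLandmarkError(ValueError):
    """Raised when landmark geometry does not define the requested angle."""


def _require_converged(solution: SolutionField) -> np.ndarray:
    if not solution.converged:
        raise SolverError(
            f"measurement on unconverged solution: {solution.diagnostics}"
        )
    return solution.final_displacement


def uvj_resultant(vuvj: float, huvj: float) -> float:
    """Resultant UVJ mobility sqrt(VUVJ^2 + HUVJ^2) in mm."""
    return math.hypot(vuvj, huvj)


def measure_uvj(
    solution: SolutionField, landmarks: Landmarks
) -> tuple[float, float, float]:
    """(VUVJ, HUVJ, UVJ) in mm: vertical, horizontal and resultant
    displacement of the urethrovesical junction (inferior and posterior
    movements positive)."""
    u = _require_converged(solution)[landmarks.uvj]
    vuvj = abs(float(u[2]))
    huvj = abs(float(u[1]))
    return vuvj, huvj, uvj_resultant(vuvj, huvj)


def measure_urethral_angle(
    solution: SolutionField, mesh: Mesh, landmarks: Landmarks
) -> float:
    """Urethral axis angle Ur from the vertical, degrees in [0, 90]."""
    u = _require_converged(solution)
    prox = mesh.nodes[landmarks.urethra_proximal] + u[landmarks.urethra_proximal]
    dist = mesh.nodes[landmarks.urethra_distal] + u[landmarks.urethra_distal]
    axis = prox - dist
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateLandmarkError("urethral axis nodes coincide")
    return math.degrees(math.acos(min(1.0, abs(axis[2]) / norm)))


def measure_alpha(
    solution: SolutionField, mesh: Mesh, landmarks: Landmarks
) -> float:
    """Angle alpha (degrees) at the pubic reference point between the fixed
    midpubic line and the segment to the displaced bladder neck."""
    u = _require_converged(solution)
    p0, p1 = landmarks.midpubic_line
    line = mesh.nodes[p1] - mesh.nodes[p0]
    to_neck = mesh.nodes[landmarks.uvj] + u[landmarks.uvj] - mesh.nodes[p0]
    nl, nn = np.linalg.norm(line), np.linalg.norm(to_neck)
    if nl < 1e-12 or nn < 1e-12:
        raise DegenerateLandmarkError("bladder neck lies on the pubic reference")
    cosang = float(np.clip(np.dot(line, to_neck) / (nl * nn), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def measure_lpa(
    solution: SolutionField, mesh: Mesh, landmarks: Landmarks
) -> float:
    """Levator plate angle (degrees) of the coccyx-to-anorectal line
    against the horizontal; caudal (downward) inclination positive."""
    u = _require_converged(solution)
    c, a = landmarks.levator_line
    v = (mesh.nodes[a] + u[a]) - (mesh.nodes[c] + u[c])
    horizontal = math.hypot(v[0], v[1])
    if horizontal < 1e-12 and abs(v[2]) < 1e-12:
        raise DegenerateLandmarkError("levator line nodes coincide")
    return math.degrees(math.atan2(-v[2], horizontal))


# ---------------------------------------------------------------------------
# solving and sweeping
# ---------------------------------------------------------------------------


def solve_healthy(
    model: PelvicModel, settings: SolverSettings | None = None
) -> SolutionField:
    """Solve the model with unimpaired materials."""
    return solve_quasistatic(model.mesh, model.bc, model.materials, settings)


def _target_regions(model: PelvicModel, target_set: str) -> tuple[str, ...]:
    if target_set == "fasciae":
        return FASCIA_REGIONS
    if target_set == "ligaments":
        return LIGAMENT_REGIONS
    if target_set == "all":
        return FASCIA_REGIONS + LIGAMENT_REGIONS
    known = set(model.materials)
    if target_set in known:
        return (target_set,)
    raise ValueError(
        f"unknown impairment target {target_set!r}; "
        f"expected 'fasciae', 'ligaments', 'all' or one of {sorted(known)}"
    )


def impaired_materials(
    model: PelvicModel, target_set: str, level: float
) -> dict[str, Material]:
    """Material map with the target regions weakened by *level*."""
    if not (0.0 <= level <= 0.95):
        raise ValueError(f"impairment level must lie in [0, 0.95], got {level}")
    targets = _target_regions(model, target_set)
    factor = 1.0 - level
    return {
        region: (mat.scaled(factor) if region in targets else mat)
        for region, mat in model.materials.items()
    }


def _measure_row(
    model: PelvicModel, solution: SolutionField
) -> dict[str, float | bool]:
    vuvj, huvj, uvj = measure_uvj(solution, model.landmarks)
    return {
        "vuvj_mm": vuvj,
        "huvj_mm": huvj,
        "uvj_mm": uvj,
        "ur_deg": measure_urethral_angle(solution, model.mesh, model.landmarks),
        "alpha_deg": measure_alpha(solution, model.mesh, model.landmarks),
        "lpa_deg": measure_lpa(solution, model.mesh, model.landmarks),
        "converged": True,
    }


def impairment_sweep(
    model: PelvicModel,
    target_set: str,
    levels,
    settings: SolverSettings | None = None,
    on_solution=None,
) -> pd.DataFrame:
    """Re-solve the model across impairment levels of one target set.

    Returns a table with one row per level (columns ``impairment, target,
    vuvj_mm, huvj_mm, uvj_mm, ur_deg, alpha_deg, lpa_deg, converged``);
    an unconverged level is flagged (NaN measurements) and the sweep
    continues.  Levels are solved in order with warm starts (continuation
    in the impairment parameter).  ``on_solution(level, solution)`` is
    called for every converged level (e.g. to export displacement fields).
    """
    rows = []
    u_prev: np.ndarray | None = None
    level_prev = 0.0
    for level in levels:
        level = float(level)
        row: dict = {"impairment": level, "target": target_set}
        try:
            solution = _solve_level_continuation(
                model, target_set, level, settings, u_prev, level_prev
            )
            row.update(_measure_row(model, solution))
            u_prev = solution.final_displacement
            level_prev = level
            if on_solution is not None:
                on_solution(level, solution)
        except SolverError:
            row.update(
                dict.fromkeys(
                    ("vuvj_mm", "huvj_mm", "uvj_mm", "ur_deg", "alpha_deg", "lpa_deg"),
                    float("nan"),
                )
            )
            row["converged"] = False
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


_MAX_CONTINUATION_SUBSTEPS = 24


def _solve_level_continuation(
    model: PelvicModel,
    target_set: str,
    level: float,
    settings: SolverSettings | None,
    u_start: np.ndarray | None,
    level_start: float,
) -> SolutionField:
    """Solve one impairment level, warm-starting from a previous level.

    A cold solve ramps the load from zero.  With a warm start the solve is
    a homotopy in the impairment parameter: if the target level is not
    reachable in one jump, intermediate levels are inserted by bisection
    (bounded, so a genuinely unsolvable level still fails cleanly).
    """
    if u_start is None:
        return solve_quasistatic(model.mesh, model.bc,
                                 impaired_materials(model, target_set, level),
                                 settings)
    pending = [level]
    u_prev = u_start
    solution: SolutionField | None = None
    current = level_start
    budget = _MAX_CONTINUATION_SUBSTEPS
    while pending:
        nxt = pending[-1]
        try:
            solution = solve_quasistatic(
                model.mesh,
                model.bc,
                impaired_materials(model, target_set, nxt),
                settings,
                initial_displacements=u_prev,
            )
        except SolverError:
            budget -= 1
            mid = 0.5 * (current + nxt)
            if budget <= 0 or abs(nxt - mid) < 1e-4:
                raise
            pending.append(mid)
            continue
        pending.pop()
        u_prev = solution.final_displacement
        current = nxt
    assert solution is not None
    return solution


def ur_crossing_level(sweep: pd.DataFrame, threshold: float = 30.0) -> float:
    """Smallest impairment level whose urethral angle exceeds *threshold*
    degrees (the positive Q-tip analogue); ``inf`` if never crossed."""
    crossed = sweep[(sweep["converged"]) & (sweep["ur_deg"] > threshold)]
    if crossed.empty:
        return float("inf")
    return float(crossed["impairment"].min())
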