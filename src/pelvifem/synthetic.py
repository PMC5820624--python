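"""Synthetic inputs: stress-stretch curves and structured tet meshes.

The curve generator samples the closed-form uniaxial nominal stress of a
known parameter set (optionally as a Voigt mixture) on an even stretch
grid and adds Gaussian noise, standing in for the digitized literature
experiments the bundled coefficients were fitted from.  Meshes are
structured boxes subdivided into six tetrahedra per cell (Kuhn
subdivision, conforming across cells), used for verification cubes and
for the idealized pelvic geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .constitutive import Material, uniaxial_nominal_stress
from .fitting import StressStretchCurve
from .mesh import Mesh

__all__ = ["CurveGenSpec", "box_grid", "fixture_cube", "generate_curve", "kuhn_tets"]


# ---------------------------------------------------------------------------
# stress-stretch curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveGenSpec:
    """Recipe for one synthetic uniaxial stress-stretch curve.

    ``noise_sd`` is the Gaussian standard deviation as a fraction of the
    curve's maximum absolute stress (additive by default; multiplicative
    noise scales each sample by ``1 + eps`` instead).
    """

    material: Material
    lambda_range: tuple[float, float] = (1.0, 1.3)
    n_points: int = 50
    noise_sd: float = 0.0
    seed: int = 0
    multiplicative: bool = False
    source: str = "synthetic"

    def __post_init__(self) -> None:
        lo, hi = self.lambda_range
        if not (0.7 <= lo < hi):
            raise ValueError(f"invalid lambda range {self.lambda_range}")
        if self.n_points < 4:
            raise ValueError("need at least 4 points")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


def generate_curve(spec: CurveGenSpec) -> StressStretchCurve:
    """Sample the closed-form uniaxial stress with seeded Gaussian noise."""
    lam = np.linspace(*spec.lambda_range, spec.n_points)
    stress = np.asarray(uniaxial_nominal_stress(spec.material, lam), dtype=float)
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        eps = rng.normal(0.0, spec.noise_sd, size=lam.shape)
        if spec.multiplicative:
            stress = stress * (1.0 + eps)
        else:
            stress = stress + eps * np.abs(stress).max()
    return StressStretchCurve(stretch=lam, nominal_stress=stress, source=spec.source)


# ---------------------------------------------------------------------------
# structured tet meshes
# ---------------------------------------------------------------------------

_KUHN_PATHS = []
for perm in permutations(range(3)):
    p0 = np.zeros(3, dtype=int)
    p1 = p0.copy()
    p1[perm[0]] = 1
    p2 = p1.copy()
    p2[perm[1]] = 1
    _KUHN_PATHS.append((tuple(p0), tuple(p1), tuple(p2), (1, 1, 1)))


def box_grid(
    origin: tuple[float, float, float],
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Structured node grid of a box.

    Returns ``(nodes, index)`` where ``index[i, j, k]`` is the row of the
    grid point with integer coordinates (i, j, k).
    """
    nx, ny, nz = divisions
    xs = np.linspace(origin[0], origin[0] + lengths[0], nx + 1)
    ys = np.linspace(origin[1], origin[1] + lengths[1], ny + 1)
    zs = np.linspace(origin[2], origin[2] + lengths[2], nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    index = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    return nodes, index


def kuhn_tets(index: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Six-tet (Kuhn) subdivision of every cell of a structured grid.

    The subdivision is translation invariant, hence conforming across
    cells; vertex order is fixed up so that all reference volumes are
    positive.
    """
    nx, ny, nz = (s - 1 for s in index.shape)
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                for path in _KUHN_PATHS:
                    tets.append(
                        [index[i + d[0], j + d[1], k + d[2]] for d in path]
                    )
    tets = np.asarray(tets, dtype=int)
    # flip negatively oriented tets (depends on the permutation parity)
    x = nodes[tets]
    vols = np.linalg.det(np.swapaxes(x[:, 1:, :] - x[:, :1, :], 1, 2))
    flip = vols < 0.0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def fixture_cube(n_divisions: int = 1, side: float = 10.0) -> Mesh:
    """A side x side x side mm cube of tets with face node sets.

    Face sets are named ``xmin, xmax, ymin, ymax, zmin, zmax`` for
    uniaxial verification tests.
    """
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    nodes, index = box_grid((0.0, 0.0, 0.0), (side,) * 3, (n_divisions,) * 3)
    tets = kuhn_tets(index, nodes)
    tol = 1e-9 * side
    node_sets = {
        "xmin": np.flatnonzero(np.abs(nodes[:, 0]) < tol),
        "xmax": np.flatnonzero(np.abs(nodes[:, 0] - side) < tol),
        "ymin": np.flatnonzero(np.abs(nodes[:, 1]) < tol),
        "ymax": np.flatnonzero(np.abs(nodes[:, 1] - side) < tol),
        "zmin": np.flatnonzero(np.abs(nodes[:, 2]) < tol),
        "zmax": np.flatnonzero(np.abs(nodes[:, 2] - side) < tol),
    }
    return Mesh(
        nodes=nodes,
        tets=tets,
        tet_regions=np.full(tets.shape[0], "bulk", dtype=object),
        node_sets=node_sets,
    )
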