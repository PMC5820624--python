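"""Unstructured mesh container (4-node tetrahedra + 2-node trusses).

Coordinates are in mm, with z vertical (positive cranial) and y positive
anterior.  Tetrahedra carry a region label mapping to a bulk material;
trusses model ligaments as one-dimensional load paths and carry a region
label plus a reference cross-section area in mm^2.

Field output is written in the legacy VTK ASCII format, readable by
ParaView and by the usual scientific VTK readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Mesh", "MeshError", "boundary_triangles", "tet_volumes", "write_vtk"]


class MeshError(ValueError):
    """Raised for inconsistent mesh topology or geometry."""


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed reference volumes of 4-node tetrahedra (mm^3)."""
    x = nodes[tets]  # (M, 4, 3)
    e = x[:, 1:, :] - x[:, :1, :]  # (M, 3, 3) edge vectors from node 0
    return np.linalg.det(e) / 6.0


@dataclass
class Mesh:
    """Tet + truss mesh with region labels and named node sets."""

    nodes: np.ndarray  # (N, 3) mm
    tets: np.ndarray  # (M, 4) int
    tet_regions: np.ndarray  # (M,) str labels
    trusses: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 2), dtype=int)
    )
    truss_regions: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    truss_areas: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=int).reshape(-1, 4)
        self.tet_regions = np.asarray(self.tet_regions, dtype=object)
        self.trusses = np.asarray(self.trusses, dtype=int).reshape(-1, 2)
        self.truss_regions = np.asarray(self.truss_regions, dtype=object)
        self.truss_areas = np.asarray(self.truss_areas, dtype=float)
        self.validate()

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        n = self.n_nodes
        if self.tets.size and (self.tets.min() < 0 or self.tets.max() >= n):
            raise MeshError("tet connectivity index out of range")
        if self.trusses.size and (self.trusses.min() < 0 or self.trusses.max() >= n):
            raise MeshError("truss connectivity index out of range")
        if self.tet_regions.shape[0] != self.n_tets:
            raise MeshError("one region label required per tet")
        if self.truss_regions.shape[0] != self.n_trusses:
            raise MeshError("one region label required per truss")
        if self.truss_areas.shape[0] != self.n_trusses:
            raise MeshError("one reference area required per truss")
        if self.n_tets:
            vols = tet_volumes(self.nodes, self.tets)
            if np.any(vols <= 0.0):
                bad = int(np.argmin(vols))
                raise MeshError(
                    f"tet {bad} has non-positive reference volume {vols[bad]:.3g}"
                )
        if self.n_trusses:
            if np.any(self.truss_areas <= 0.0):
                raise MeshError("truss reference areas must be positive")
            lengths = self.truss_lengths()
            if np.any(lengths <= 0.0):
                raise MeshError("truss reference lengths must be positive")
        for name, members in self.node_sets.items():
            members = np.asarray(members, dtype=int)
            if members.size and (members.min() < 0 or members.max() >= n):
                raise MeshError(f"node set {name!r} references missing nodes")
            self.node_sets[name] = members

    # -- derived quantities --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_tets(self) -> int:
        return int(self.tets.shape[0])

    @property
    def n_trusses(self) -> int:
        return int(self.trusses.shape[0])

    def truss_lengths(self) -> np.ndarray:
        d = self.nodes[self.trusses[:, 1]] - self.nodes[self.trusses[:, 0]]
        return np.linalg.norm(d, axis=1)

    def total_tet_volume(self) -> float:
        return float(tet_volumes(self.nodes, self.tets).sum())

    def region_tets(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.tet_regions == region)

    def region_trusses(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.truss_regions == region)


#: Faces of a positively oriented tet, ordered with outward right-hand normals.
_TET_FACES = ((0, 2, 1), (0, 1, 3), (0, 3, 2), (1, 2, 3))


def boundary_triangles(mesh: Mesh) -> np.ndarray:
    """Outward-oriented surface triangles of the tet mesh, shape (T, 3).

    A triangle is on the boundary iff it belongs to exactly one tet; the
    returned node order gives right-hand normals pointing out of the body.
    """
    faces = np.concatenate([mesh.tets[:, f] for f in _TET_FACES], axis=0)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    return faces[first[counts == 1]]


def write_vtk(
    mesh: Mesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "pelvifem mesh",
) -> None:
    """Write the mesh and optional per-node vector/scalar fields to legacy VTK."""
    path = Path(path)
    lines: list[str] = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines.extend(" ".join(f"{v:.9g}" for v in row) for row in mesh.nodes)

    n_cells = mesh.n_tets + mesh.n_trusses
    n_ints = 5 * mesh.n_tets + 3 * mesh.n_trusses
    lines.append(f"CELLS {n_cells} {n_ints}")
    lines.extend("4 " + " ".join(map(str, tet)) for tet in mesh.tets)
    lines.extend("2 " + " ".join(map(str, tr)) for tr in mesh.trusses)
    lines.append(f"CELL_TYPES {n_cells}")
    lines.extend(["10"] * mesh.n_tets)  # VTK_TETRA
    lines.extend(["3"] * mesh.n_trusses)  # VTK_LINE

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, data in point_data.items():
            data = np.asarray(data, dtype=float)
            if data.ndim == 2 and data.shape == (mesh.n_nodes, 3):
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in data)
            elif data.ndim == 1 and data.shape[0] == mesh.n_nodes:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in data)
            else:
                raise ValueError(f"point data {name!r} has shape {data.shape}")

    path.write_text("\n".join(lines) + "\n")
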