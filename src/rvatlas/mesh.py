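"""Right-ventricular surface mesh geometry.

The cohort is represented on a single corresponded triangulated surface of
the RV wall: every subject's motion is expressed on the same vertex set, so
vertex ``i`` refers to the same anatomical location in every subject.  The
mesh carries two anatomical landmarks — the apex vertex and the tricuspid
annulus ring — which define the ventricular long axis, and a four-chamber
imaging plane used to restrict marker candidates to locations measurable on
a conventional 2D scan.

Coordinates are millimetres in an arbitrary right-handed frame; areas are
reported in cm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MeshGeometry",
    "AxialCoordinate",
    "build_adjacency",
    "surface_area",
    "face_areas",
    "axial_coordinate",
    "plane_vertices",
    "mean_correspondence_distance",
]


@dataclass
class MeshGeometry:
    """Corresponded triangulated RV surface with landmarks.

    Parameters
    ----------
    vertex_positions : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices
    landmark_apex : index of the apex vertex
    landmark_annulus : indices of the tricuspid-annulus ring
    plane_point, plane_normal : the four-chamber plane (point + unit normal)
    """

    vertex_positions: np.ndarray
    faces: np.ndarray
    landmark_apex: int
    landmark_annulus: np.ndarray
    plane_point: np.ndarray
    plane_normal: np.ndarray
    plane_name: str = "four-chamber"
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_positions = np.asarray(self.vertex_positions, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.landmark_annulus = np.asarray(self.landmark_annulus, dtype=np.int64)
        self.plane_point = np.asarray(self.plane_point, dtype=float)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float)
        if self.vertex_positions.ndim != 2 or self.vertex_positions.shape[1] != 3:
            raise ValueError("vertex_positions must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        V = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= V):
            raise ValueError("face indices out of range")
        if int(self.landmark_apex) in set(self.landmark_annulus.tolist()):
            raise ValueError("apex landmark must not lie on the annulus ring")
        nrm = float(np.linalg.norm(self.plane_normal))
        if abs(nrm - 1.0) > 1e-9:
            if nrm == 0:
                raise ValueError("plane normal must be non-zero")
            self.plane_normal = self.plane_normal / nrm

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def adjacency(self) -> sp.csr_matrix:
        if self._adjacency is None:
            self._adjacency = build_adjacency(self)
        return self._adjacency

    def annulus_centroid(self) -> np.ndarray:
        return self.vertex_positions[self.landmark_annulus].mean(axis=0)

    def long_axis(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (base point, unit base→apex direction, axis length mm)."""
        base = self.annulus_centroid()
        apex = self.vertex_positions[self.landmark_apex]
        vec = apex - base
        length = float(np.linalg.norm(vec))
        if length <= 1e-12:
            raise ValueError("degenerate long axis: apex coincides with annulus centroid")
        return base, vec / length, length


@dataclass
class AxialCoordinate:
    """Per-vertex position along the ventricular long axis.

    ``fraction`` is the base-to-apex fraction: 0 at the projection of the
    annulus centroid, 1 at the apex (clipped to [0, 1]).
    ``distance_from_apex`` is the axial-projection distance in mm,
    (1 - fraction) * axis length.
    """

    fraction: np.ndarray
    distance_from_apex: np.ndarray
    axis_length: float


def build_adjacency(mesh: MeshGeometry) -> sp.csr_matrix:
    """Vertex adjacency: i ~ j iff they share an edge of some face.

    Rejects degenerate faces (repeated vertex indices) with a diagnostic.
    """
    f = mesh.faces
    degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    if degenerate.any():
        bad = np.flatnonzero(degenerate)
        raise ValueError(f"degenerate faces with repeated vertex indices: {bad[:10].tolist()}")
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.ones(i.shape[0], dtype=np.int8)
    adj = sp.coo_matrix((data, (i, j)), shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()
    adj.data[:] = 1  # collapse duplicate edge entries
    return adj


def face_areas(mesh: MeshGeometry) -> np.ndarray:
    """Area of every triangular face in mm²."""
    p = mesh.vertex_positions
    a, b, c = p[mesh.faces[:, 0]], p[mesh.faces[:, 1]], p[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def surface_area(mesh: MeshGeometry, vertex_subset: np.ndarray | None = None) -> float:
    """Surface area of a vertex subset in cm².

    A face contributes its full area iff all three of its vertices are in
    the subset; the whole-mesh call (subset None) returns the total surface
    area.  This all-three rule keeps patch area and the total-area
    denominator consistent (see docs).
    """
    areas_mm2 = face_areas(mesh)
    if vertex_subset is None:
        return float(areas_mm2.sum()) / 100.0
    subset = np.asarray(vertex_subset, dtype=np.int64)
    if subset.size == 0:
        warnings.warn("surface_area of an empty vertex subset is 0", stacklevel=2)
        return 0.0
    if subset.min() < 0 or subset.max() >= mesh.n_vertices:
        raise ValueError("vertex_subset contains out-of-range indices")
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[subset] = True
    keep = member[mesh.faces].all(axis=1)
    return float(areas_mm2[keep].sum()) / 100.0


def axial_coordinate(mesh: MeshGeometry) -> AxialCoordinate:
    """Project every vertex onto the annulus-centroid→apex axis.

    The scalar projection is clipped to [0, 1] and reported as the
    base-to-apex fraction; the distance from the apex is the axial-projection
    distance (1 - fraction) × axis length, not a geodesic distance.
    """
    base, u, length = mesh.long_axis()
    t = (mesh.vertex_positions - base) @ u / length
    fraction = np.clip(t, 0.0, 1.0)
    return AxialCoordinate(
        fraction=fraction,
        distance_from_apex=(1.0 - fraction) * length,
        axis_length=length,
    )


def plane_vertices(mesh: MeshGeometry, tolerance: float = 2.0) -> np.ndarray:
    """Indices of vertices within ``tolerance`` mm of the four-chamber plane.

    The 2 mm default matches one in-plane acquisition voxel.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive (mm)")
    d = np.abs((mesh.vertex_positions - mesh.plane_point) @ mesh.plane_normal)
    idx = np.flatnonzero(d <= tolerance)
    if idx.size == 0:
        warnings.warn(
            "no vertices coincide with the plane at this tolerance; "
            "marker selection will fail downstream",
            stacklevel=2,
        )
    return idx


def mean_correspondence_distance(
    positions_a: np.ndarray, positions_b: np.ndarray
) -> dict[str, float]:
    """Mean, SD and normal-approximation 95% CI of per-vertex distance (mm).

    Both position arrays must be corresponded (equal vertex counts).
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vertex count mismatch: {a.shape} vs {b.shape}")
    d = np.linalg.norm(a - b, axis=1)
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    half = 1.959963984540054 * sd / np.sqrt(d.size)
    return {
        "mean_mm": mean,
        "sd_mm": sd,
        "ci95_low_mm": mean - half,
        "ci95_high_mm": mean + half,
        "n_vertices": int(d.size),
    }


def connected_vertex_components(mesh: MeshGeometry, vertex_mask: np.ndarray) -> list[np.ndarray]:
    """Connected components of a vertex mask under mesh adjacency.

    Returns a list of sorted index arrays, in decreasing order of size.
    """
    mask = np.asarray(vertex_mask, dtype=bool)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = mesh.adjacency[np.ix_(idx, idx)]
    n_comp, labels = connected_components(sub, directed=False)
    comps = [np.sort(idx[labels == k]) for k in range(n_comp)]
    comps.sort(key=lambda c: c.size, reverse=True)
    return comps
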