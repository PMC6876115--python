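"""Indexed triangle mesh: the universal currency of the pipeline.

All coordinates are millimetres. Counter-clockwise winding (seen from
outside) defines the outward normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0  # fractional part drives low-discrepancy sampling


@dataclass
class TriangleMesh:
    """Triangle surface with shared, indexed vertices.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of vertex indices, CCW winding = outward normal.
    name : free-form label carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidParameterError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidParameterError("faces must be an (m, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidParameterError("vertex coordinates must be finite")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise InvalidParameterError("face index out of range")

    # -- basic measures -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        tri = self.triangles
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_normals(self) -> np.ndarray:
        cr = self.face_cross()
        nrm = np.linalg.norm(cr, axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        return cr / nrm

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        a = self.face_areas()
        total = a.sum()
        if total == 0.0:
            return self.vertices.mean(axis=0)
        return (self.face_centroids() * a[:, None]).sum(axis=0) / total

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward-wound watertight meshes."""
        tri = self.triangles
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] corner."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def extents(self) -> np.ndarray:
        b = self.bounds()
        return b[1] - b[0]

    # -- topology -------------------------------------------------------

    def edges(self) -> np.ndarray:
        """(3m, 2) directed edge list in face order."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0)

    def unique_edges(self) -> np.ndarray:
        e = np.sort(self.edges(), axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        used = np.unique(self.faces)
        return int(len(used) - len(self.unique_edges()) + self.n_faces)

    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        e = np.sort(self.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(len(counts) > 0 and np.all(counts == 2))

    def is_consistently_wound(self) -> bool:
        """Each undirected edge appears once per direction (orientable, consistent)."""
        e = self.edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (unit where defined)."""
        cr = self.face_cross()  # |cross| = 2*area, so summing cross = area weighting
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], cr)
        nrm = np.linalg.norm(vn, axis=1, keepdims=True)
        nrm[nrm == 0.0] = 1.0
        return vn / nrm

    # -- editing --------------------------------------------------------

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        v = self.vertices @ np.asarray(rotation, dtype=np.float64).T + np.asarray(
            translation, dtype=np.float64
        )
        return TriangleMesh(v, self.faces.copy(), self.name)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=np.float64), self.faces.copy(), self.name)

    def submesh(self, face_mask: np.ndarray, name: str | None = None) -> "TriangleMesh":
        """Faces selected by mask/indices, with unreferenced vertices dropped."""
        faces = self.faces[face_mask]
        used, inverse = np.unique(faces, return_inverse=True)
        return TriangleMesh(self.vertices[used], inverse.reshape(-1, 3), name or self.name)

    def remove_degenerate_faces(self, eps: float = 0.0) -> "TriangleMesh":
        areas = self.face_areas()
        return self.submesh(areas > eps)

    def merged_vertices(self, decimals: int | None = None) -> "TriangleMesh":
        """Merge exactly-equal (or rounded-equal) vertices and re-index faces."""
        v = self.vertices if decimals is None else np.round(self.vertices, decimals)
        uniq, inverse = np.unique(v, axis=0, return_inverse=True)
        mesh = TriangleMesh(uniq, inverse[self.faces], self.name)
        areas = mesh.face_areas()
        if np.any(areas == 0.0):
            mesh = mesh.remove_degenerate_faces()
        return mesh


def concatenate(meshes, name: str = "") -> TriangleMesh:
    """Concatenate meshes into one (vertices appended, faces re-indexed)."""
    meshes = list(meshes)
    if not meshes:
        raise InvalidParameterError("cannot concatenate zero meshes")
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
    return TriangleMesh(np.concatenate(verts), np.concatenate(faces), name)


def subdivide(mesh: TriangleMesh) -> TriangleMesh:
    """One midpoint (1-to-4) subdivision pass; edge midpoints are shared."""
    v, f = mesh.vertices, mesh.faces
    e = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=0), axis=1
    )
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    mid = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    m01, m12, m20 = np.split(inverse + len(v), 3)
    new_faces = np.concatenate(
        [
            np.stack([f[:, 0], m01, m20], axis=1),
            np.stack([f[:, 1], m12, m01], axis=1),
            np.stack([f[:, 2], m20, m12], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ]
    )
    return TriangleMesh(np.concatenate([v, mid]), new_faces, mesh.name)


def subdivide_to_spacing(mesh: TriangleMesh, spacing: float, max_faces: int = 400_000) -> TriangleMesh:
    """Subdivide until the mean edge length drops to ~spacing (face-count capped)."""
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    out = mesh
    while out.n_faces * 4 <= max_faces:
        e = out.unique_edges()
        mean_edge = float(np.linalg.norm(out.vertices[e[:, 0]] - out.vertices[e[:, 1]], axis=1).mean())
        if mean_edge <= spacing:
            break
        out = subdivide(out)
    return out


def _low_discrepancy_barycentric(n: int) -> np.ndarray:
    """Deterministic (n, 3) barycentric pattern, roughly uniform over the triangle."""
    i = np.arange(n, dtype=np.float64)
    u = (i + 0.5) / n
    v = np.mod((i + 1) * _GOLDEN, 1.0)
    s = np.sqrt(u)
    b0 = 1.0 - s
    b1 = s * (1.0 - v)
    b2 = s * v
    return np.stack([b0, b1, b2], axis=1)


def deterministic_surface_samples(mesh: TriangleMesh, spacing: float) -> np.ndarray:
    """Area-weighted deterministic samples at ~one point per spacing^2 of surface.

    Systematic sampling along the cumulative-area sequence with a fixed
    low-discrepancy barycentric pattern, so the result depends only on
    (mesh, spacing): no random state involved, and tessellation density
    cannot bias the sample distribution.
    """
    if spacing <= 0:
        raise InvalidParameterError("spacing must be positive")
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise InvalidParameterError("mesh has zero surface area")
    n = max(1, int(np.rint(total / spacing**2)))
    cum = np.cumsum(areas)
    u = (np.arange(n) + 0.5) / n * total  # systematic positions over area
    fidx = np.minimum(np.searchsorted(cum, u, side="right"), len(areas) - 1)
    bary = _low_discrepancy_barycentric(n)
    return np.einsum("nj,njc->nc", bary, mesh.triangles[fidx])


def random_surface_samples(mesh: TriangleMesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform random samples on the surface."""
    areas = mesh.face_areas()
    p = areas / areas.sum()
    fidx = rng.choice(mesh.n_faces, size=n, p=p)
    r1, r2 = rng.random(n), rng.random(n)
    s = np.sqrt(r1)
    bary = np.stack([1.0 - s, s * (1.0 - r2), s * r2], axis=1)
    return np.einsum("nj,njc->nc", bary, mesh.triangles[fidx])


def vertex_adjacency(mesh: TriangleMesh):
    """CSR-style (indptr, indices) of vertex one-ring neighbourhoods."""
    e = mesh.unique_edges()
    both = np.concatenate([e, e[:, ::-1]])
    order = np.argsort(both[:, 0], kind="stable")
    src = both[order, 0]
    dst = both[order, 1]
    indptr = np.zeros(mesh.n_vertices + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, dst


def laplacian_smooth(mesh: TriangleMesh, iterations: int, lam: float = 0.5) -> TriangleMesh:
    """Uniform-Laplacian smoothing: v <- v + lam * (mean(neighbours) - v)."""
    if iterations < 0:
        raise InvalidParameterError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy()
    indptr, nbr = vertex_adjacency(mesh)
    deg = np.diff(indptr).astype(np.float64)
    safe_deg = np.where(deg == 0, 1.0, deg)
    v = mesh.vertices.copy()
    seg = np.repeat(np.arange(mesh.n_vertices), np.diff(indptr))
    for _ in range(iterations):
        acc = np.zeros_like(v)
        np.add.at(acc, seg, v[nbr])
        mean = acc / safe_deg[:, None]
        moved = v + lam * (mean - v)
        v = np.where(deg[:, None] > 0, moved, v)
    return TriangleMesh(v, mesh.faces.copy(), mesh.name)
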