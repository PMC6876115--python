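"""Mesh utilities for segmentation and normal inversion.

Normal inversion turns an impression (negative mould) surface into its
positive counterpart; cropping stands in for interactive segmentation,
using declarative plane/box regions with a face-centroid rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .errors import EmptySelectionError, InvalidParameterError
from .mesh import TriangleMesh


def invert_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Reverse every face's winding order; vertex positions are untouched.

    An involution; on watertight meshes it negates the signed volume.
    """
    if mesh.n_faces == 0:
        raise InvalidParameterError("mesh is empty")
    return TriangleMesh(mesh.vertices.copy(), mesh.faces[:, ::-1].copy(), mesh.name)


def face_adjacency_components(mesh: TriangleMesh) -> np.ndarray:
    """Label faces by edge-connected component (labels are arbitrary ints)."""
    e = np.sort(
        np.concatenate(
            [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]], axis=0
        ),
        axis=1,
    )
    face_of_edge = np.tile(np.arange(mesh.n_faces), 3)
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    # faces sharing an undirected edge are adjacent
    order = np.argsort(inverse, kind="stable")
    inv_sorted = inverse[order]
    faces_sorted = face_of_edge[order]
    starts = np.searchsorted(inv_sorted, np.arange(len(uniq)))
    ends = np.append(starts[1:], len(inv_sorted))
    rows, cols = [], []
    for s, t in zip(starts, ends):
        group = faces_sorted[s:t]
        if len(group) > 1:
            rows.append(np.repeat(group[0], len(group) - 1))
            cols.append(group[1:])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    graph = coo_matrix(
        (np.ones(len(r)), (r, c)), shape=(mesh.n_faces, mesh.n_faces)
    )
    _, labels = _cc(graph, directed=False)
    return labels


def connected_components(mesh: TriangleMesh) -> list[TriangleMesh]:
    """Split into edge-connected face components, largest (by face count) first."""
    if mesh.n_faces == 0:
        raise InvalidParameterError("mesh is empty")
    labels = face_adjacency_components(mesh)
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return [
        mesh.submesh(labels == uniq[i], name=f"{mesh.name}_cc{rank}")
        for rank, i in enumerate(order)
    ]


@dataclass(frozen=True)
class HalfSpace:
    """Keep faces with centroid c satisfying normal . c >= offset."""

    normal: tuple
    offset: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=np.float64)
        return points @ n >= self.offset


@dataclass(frozen=True)
class Box:
    """Axis-aligned box [lo, hi] (inclusive), face-centroid rule."""

    lo: tuple
    hi: tuple

    def contains(self, points: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo, dtype=np.float64)
        hi = np.asarray(self.hi, dtype=np.float64)
        return np.all((points >= lo) & (points <= hi), axis=1)


def crop(mesh: TriangleMesh, region) -> TriangleMesh:
    """Keep faces whose centroid lies in ``region`` (HalfSpace or Box).

    Boundary triangles are kept or dropped whole — no re-meshing. Raises
    EmptySelectionError when nothing is selected.
    """
    if mesh.n_faces == 0:
        raise InvalidParameterError("mesh is empty")
    mask = region.contains(mesh.face_centroids())
    if not np.any(mask):
        raise EmptySelectionError("crop region selects no faces")
    return mesh.submesh(mask, name=f"{mesh.name}_crop")
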