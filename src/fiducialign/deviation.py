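"""Surface-deviation metrics: point-to-triangle distance and RMSE reports.

The deviation between two aligned surfaces is summarized by the RMSE of
unsigned nearest point-to-surface distances, the pipeline's accuracy
metric [mm].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyReportError, InvalidParameterError
from .mesh import TriangleMesh, deterministic_surface_samples

SOURCE_TO_REFERENCE = "source_to_reference"
SYMMETRIC = "symmetric"

_EXHAUSTIVE_FACE_LIMIT = 512  # below this, skip the spatial index entirely
_POINT_CHUNK = 1024


def closest_points_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each closed triangle to each query point.

    Vectorized region classification (vertex / edge / interior regions of
    the triangle's Voronoi decomposition). ``p`` broadcasts against
    ``tri``: p is (..., 3), tri is (..., 3, 3); output matches p.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty(np.broadcast(p, a).shape, dtype=np.float64)
    done = np.zeros(out.shape[:-1], dtype=bool)

    def assign(mask, value):
        use = mask & ~done
        out[use] = np.broadcast_to(value, out.shape)[use]
        done[use] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab, nan=0.0, posinf=0.0, neginf=0.0)[..., None] * ab)
        v_ac = d2 / (d2 - d6)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(v_ac, nan=0.0, posinf=0.0, neginf=0.0)[..., None] * ac)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        assign(
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            b + np.nan_to_num(w_bc, nan=0.0, posinf=0.0, neginf=0.0)[..., None] * (c - b),
        )
        denom = va + vb + vc
        v = np.nan_to_num(vb / denom, nan=0.0, posinf=0.0, neginf=0.0)
        w = np.nan_to_num(vc / denom, nan=0.0, posinf=0.0, neginf=0.0)
    assign(np.ones_like(done), a + v[..., None] * ab + w[..., None] * ac)
    return out


def point_to_triangle(p, tri) -> float:
    """Exact Euclidean distance from a point to a closed triangle."""
    tri = np.asarray(tri, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    area2 = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if area2 == 0.0:
        raise InvalidParameterError("degenerate triangle")
    cp = closest_points_on_triangles(p[None, :], tri[None, :, :])[0]
    return float(np.linalg.norm(p - cp))


class SurfaceIndex:
    """Nearest-point-on-surface queries against a fixed reference mesh.

    Small meshes are searched exhaustively; larger meshes are pruned with a
    k-nearest-vertex candidate set (faces incident to the k nearest
    vertices), which is exact in practice at scan-mesh densities.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 8):
        if mesh.n_faces == 0:
            raise InvalidParameterError("reference mesh is empty")
        self.mesh = mesh
        self.k = min(k, mesh.n_vertices)
        self.triangles = mesh.triangles
        self._exhaustive = mesh.n_faces <= _EXHAUSTIVE_FACE_LIMIT
        if not self._exhaustive:
            self._tree = cKDTree(mesh.vertices)
            # padded vertex -> incident-face table (-1 = empty slot)
            vi = mesh.faces.ravel()
            fi = np.repeat(np.arange(mesh.n_faces), 3)
            order = np.argsort(vi, kind="stable")
            counts = np.bincount(vi, minlength=mesh.n_vertices)
            max_inc = int(counts.max())
            inc = np.full((mesh.n_vertices, max_inc), -1, dtype=np.int64)
            slot = np.concatenate([np.arange(c) for c in counts])
            inc[vi[order], slot] = fi[order]
            self._inc_pad = inc

    def query(self, points: np.ndarray):
        """Return (distances, closest_points) for an (n, 3) query array."""
        points = np.asarray(points, dtype=np.float64)
        dists = np.empty(len(points))
        closest = np.empty((len(points), 3))
        for s in range(0, len(points), _POINT_CHUNK):
            e = min(s + _POINT_CHUNK, len(points))
            d, c = self._query_chunk(points[s:e])
            dists[s:e] = d
            closest[s:e] = c
        return dists, closest

    def _query_chunk(self, pts: np.ndarray):
        if self._exhaustive:
            cand_tri = np.broadcast_to(
                self.triangles[None], (len(pts), len(self.triangles), 3, 3)
            )
            cp = closest_points_on_triangles(pts[:, None, :], cand_tri)
        else:
            _, knn = self._tree.query(pts, k=self.k)
            knn = np.atleast_2d(knn)
            cand = self._inc_pad[knn].reshape(len(pts), -1)  # (n, k * max_inc)
            valid = cand >= 0
            cand = np.where(valid, cand, 0)
            cand_tri = self.triangles[cand]
            cp = closest_points_on_triangles(pts[:, None, :], cand_tri)
            diff = pts[:, None, :] - cp
            d2 = np.einsum("nkc,nkc->nk", diff, diff)
            d2[~valid] = np.inf
            best = np.argmin(d2, axis=1)
            idx = np.arange(len(pts))
            return np.sqrt(d2[idx, best]), cp[idx, best]
        diff = pts[:, None, :] - cp
        d2 = np.einsum("nkc,nkc->nk", diff, diff)
        best = np.argmin(d2, axis=1)
        idx = np.arange(len(pts))
        return np.sqrt(d2[idx, best]), cp[idx, best]


def nearest_on_surface(points: np.ndarray, mesh: TriangleMesh):
    """One-shot (distances, closest_points) query; builds a SurfaceIndex."""
    return SurfaceIndex(mesh).query(points)


@dataclass
class DeviationReport:
    """Unsigned distances between two surfaces plus summary statistics [mm]."""

    distances: np.ndarray
    rmse: float
    mean_abs: float
    max_abs: float
    n_points: int
    cutoff: float | None = None
    n_beyond_cutoff: int = 0
    direction: str = SOURCE_TO_REFERENCE

    @classmethod
    def from_distances(
        cls,
        distances: np.ndarray,
        cutoff: float | None = None,
        direction: str = SOURCE_TO_REFERENCE,
    ) -> "DeviationReport":
        distances = np.asarray(distances, dtype=np.float64)
        n_beyond = 0
        if cutoff is not None:
            beyond = distances > cutoff
            n_beyond = int(beyond.sum())
            distances = distances[~beyond]
        if len(distances) == 0:
            raise EmptyReportError("no sample points within cutoff")
        return cls(
            distances=distances,
            rmse=float(np.sqrt(np.mean(distances**2))),
            mean_abs=float(np.mean(distances)),
            max_abs=float(np.max(distances)),
            n_points=len(distances),
            cutoff=cutoff,
            n_beyond_cutoff=n_beyond,
            direction=direction,
        )

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mean_abs": self.mean_abs,
            "max_abs": self.max_abs,
            "n_points": self.n_points,
            "cutoff": self.cutoff,
            "n_beyond_cutoff": self.n_beyond_cutoff,
            "direction": self.direction,
        }


def _directed_distances(
    source: TriangleMesh,
    reference: TriangleMesh,
    sample_spacing: float,
    vertices_only: bool,
) -> np.ndarray:
    if vertices_only:
        samples = source.vertices
    else:
        samples = deterministic_surface_samples(source, sample_spacing)
    d, _ = SurfaceIndex(reference).query(samples)
    return d


def surface_deviation(
    source: TriangleMesh,
    reference: TriangleMesh,
    sample_spacing: float = 0.5,
    cutoff: float | None = None,
    direction: str = SOURCE_TO_REFERENCE,
    vertices_only: bool = False,
) -> DeviationReport:
    """Deviation of ``source`` from ``reference`` (already in a common frame).

    Samples the source surface (area-weighted, deterministic) at roughly one
    point per sample_spacing^2 and measures nearest distance to the
    reference surface. ``direction=SYMMETRIC`` evaluates both directions and
    returns the directed report with the larger RMSE, so the reported rmse
    is max(rmse(A->B), rmse(B->A)). ``vertices_only`` uses source vertices
    as samples (for small-case oracles).
    """
    if source.n_faces == 0 or reference.n_faces == 0:
        raise InvalidParameterError("meshes must be non-empty")
    if direction not in (SOURCE_TO_REFERENCE, SYMMETRIC):
        raise InvalidParameterError(f"unknown direction: {direction!r}")
    fwd = DeviationReport.from_distances(
        _directed_distances(source, reference, sample_spacing, vertices_only),
        cutoff=cutoff,
        direction=direction,
    )
    if direction == SOURCE_TO_REFERENCE:
        return fwd
    rev = DeviationReport.from_distances(
        _directed_distances(reference, source, sample_spacing, vertices_only),
        cutoff=cutoff,
        direction=direction,
    )
    return fwd if fwd.rmse >= rev.rmse else rev


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.355 -> 0.36), as used in the result tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_mm(value: float, ndigits: int = 2) -> str:
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def report_round(report: DeviationReport, ndigits: int = 2) -> dict:
    """Table-style rounded summary (half-up, 2 decimals); raw values retained."""
    return {
        "rmse": format_mm(report.rmse, ndigits),
        "mean_abs": format_mm(report.mean_abs, ndigits),
        "max_abs": format_mm(report.max_abs, ndigits),
        "raw": report,
    }
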