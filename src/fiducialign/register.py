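"""Rigid registration: landmark-seeded coarse alignment plus ICP refinement.

The interactive "point selection" alignment of the original workflow is
made reproducible here: landmarks are explicit inputs, the coarse fit is
a closed-form least-squares rigid fit (Kabsch), and refinement is
point-to-point ICP with distance-based correspondence rejection. No
scaling, no reflection, anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deviation import SurfaceIndex
from .errors import (
    DegenerateConfigurationError,
    InvalidParameterError,
    RegistrationFailureError,
    WorkflowStepError,
)
from .mesh import TriangleMesh

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation), mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise InvalidParameterError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise InvalidParameterError("rotation determinant must be +1 (no reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return mesh.transformed(self.rotation, self.translation)

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """compose(T1, T2): apply T2 first, then T1."""
    return RigidTransform(t1.rotation @ t2.rotation, t1.rotation @ t2.translation + t1.translation)


def invert(t: RigidTransform) -> RigidTransform:
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation)


@dataclass
class LandmarkSet:
    """Ordered, labelled 3D points used for coarse pose estimation."""

    points: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not self.labels:
            self.labels = [f"p{i}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise InvalidParameterError("labels and points length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def validate_for_pose(self) -> None:
        if len(self.points) < 3:
            raise DegenerateConfigurationError("pose estimation needs >= 3 landmarks")
        centred = self.points - self.points.mean(axis=0)
        smallest_two = np.linalg.svd(centred, compute_uv=False)[-2]
        if smallest_two <= 1e-9:
            raise DegenerateConfigurationError("landmarks are collinear")

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(t.apply(self.points), list(self.labels))

    @classmethod
    def read(cls, path) -> "LandmarkSet":
        """Plain-text landmarks: one 'label x y z' per line, millimetres."""
        labels, pts = [], []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise InvalidParameterError(f"{path}:{lineno}: expected 'label x y z'")
            labels.append(parts[0])
            pts.append([float(x) for x in parts[1:]])
        return cls(np.asarray(pts), labels)

    def write(self, path) -> None:
        lines = [
            f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}"
            for lab, p in zip(self.labels, self.points)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_rms: float
    iterations: int
    converged: bool
    correspondences_used: int

    def to_dict(self) -> dict:
        return {
            "matrix": self.transform.matrix().tolist(),
            "final_rms": self.final_rms,
            "iterations": self.iterations,
            "converged": self.converged,
            "correspondences_used": self.correspondences_used,
        }


def kabsch(src, dst) -> RigidTransform:
    """Least-squares rigid fit: minimizes sum ||R src_i + t - dst_i||^2.

    Accepts LandmarkSets or (n, 3) arrays. Reflections are excluded by the
    usual sign correction on the smallest singular direction.
    """
    src = src if isinstance(src, LandmarkSet) else LandmarkSet(np.asarray(src))
    dst = dst if isinstance(dst, LandmarkSet) else LandmarkSet(np.asarray(dst))
    if len(src) != len(dst):
        raise DegenerateConfigurationError("landmark sets must correspond index-wise")
    src.validate_for_pose()
    dst.validate_for_pose()
    p = src.points - src.points.mean(axis=0)
    q = dst.points - dst.points.mean(axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    sign = np.diag([1.0, 1.0, d])
    rot = vt.T @ sign @ u.T
    trans = dst.points.mean(axis=0) - rot @ src.points.mean(axis=0)
    return RigidTransform(rot, trans)


def _source_samples(source: TriangleMesh, max_points: int | None) -> np.ndarray:
    pts = source.vertices
    if max_points is not None and len(pts) > max_points:
        stride = int(np.ceil(len(pts) / max_points))
        pts = pts[::stride]
    return pts


def icp(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 100,
    tolerance_mm: float = 1e-6,
    reject_distance_mm: float = 1.0,
    max_points: int | None = 2000,
    source_points: np.ndarray | None = None,
) -> RegistrationResult:
    """Point-to-point ICP from source samples to nearest points on target.

    Correspondences farther than ``reject_distance_mm`` are excluded each
    iteration. The recorded RMS trace is monotone non-increasing by
    construction: an iterate that would raise the RMS is discarded and
    iteration stops. ``source_points`` overrides the default vertex
    subsample (e.g. to restrict to a fiducial region).
    """
    if source.n_faces == 0 or target.n_faces == 0:
        raise RegistrationFailureError("source and target must be non-empty")
    init = init or RigidTransform.identity()
    pts = source_points if source_points is not None else _source_samples(source, max_points)
    pts = np.asarray(pts, dtype=np.float64).reshape(-1, 3)
    if len(pts) == 0:
        raise RegistrationFailureError("no source sample points")
    index = SurfaceIndex(target)

    transform = init
    prev_rms = np.inf
    rms = np.inf
    used = 0
    converged = False
    iterations = 0
    trace: list[float] = []
    for iterations in range(1, max_iterations + 1):
        moved = transform.apply(pts)
        dists, closest = index.query(moved)
        keep = dists <= reject_distance_mm
        if not np.any(keep):
            raise RegistrationFailureError(
                f"no correspondences within {reject_distance_mm} mm"
            )
        rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
        if rms > prev_rms + 1e-12:  # monotone-descent guard: refuse the step
            transform = prev_transform
            rms = prev_rms
            iterations -= 1
            converged = True
            break
        trace.append(rms)
        used = int(keep.sum())
        if abs(prev_rms - rms) < tolerance_mm or rms < tolerance_mm:
            converged = True
            break
        prev_rms = rms
        prev_transform = transform
        step = kabsch(moved[keep], closest[keep])
        transform = compose(step, transform)
    result = RegistrationResult(
        transform=transform,
        final_rms=rms,
        iterations=iterations,
        converged=converged,
        correspondences_used=used,
    )
    result.rms_trace = trace
    return result


def _region_mask(points: np.ndarray, landmarks: LandmarkSet, radius: float) -> np.ndarray:
    d2 = ((points[:, None, :] - landmarks.points[None, :, :]) ** 2).sum(axis=2)
    return d2.min(axis=1) <= radius**2


def align_by_fiducial(
    scan_a: TriangleMesh,
    scan_b: TriangleMesh,
    landmarks_a: LandmarkSet,
    landmarks_b: LandmarkSet,
    region_radius_mm: float = 10.0,
    **icp_params,
) -> RegistrationResult:
    """Coarse landmark fit, then ICP restricted to the fiducial region.

    The fiducial region of scan_a is the set of its vertices within
    ``region_radius_mm`` of any landmark in ``landmarks_a``.
    """
    if len(landmarks_a) != len(landmarks_b):
        raise DegenerateConfigurationError("landmark sets must correspond index-wise")
    coarse = kabsch(landmarks_a, landmarks_b)
    mask = _region_mask(scan_a.vertices, landmarks_a, region_radius_mm)
    if not np.any(mask):
        raise RegistrationFailureError("no scan_a vertices within the fiducial region")
    region_points = scan_a.vertices[mask]
    max_points = icp_params.pop("max_points", 2000)
    if len(region_points) > max_points:
        stride = int(np.ceil(len(region_points) / max_points))
        region_points = region_points[::stride]
    return icp(
        scan_a,
        scan_b,
        init=coarse,
        source_points=region_points,
        **icp_params,
    )


def chain_to_face_frame(
    face_scan: TriangleMesh,
    tray_scan: TriangleMesh,
    fiducial_landmarks_tray: LandmarkSet,
    fiducial_landmarks_face: LandmarkSet,
    impression_region,
    maxilla_model: TriangleMesh,
    mandible_model: TriangleMesh,
    occlusion_landmarks_mandible: LandmarkSet,
    occlusion_landmarks_maxilla: LandmarkSet,
    gumline_landmarks_model: LandmarkSet | None = None,
    gumline_landmarks_impression: LandmarkSet | None = None,
    gumline_radius_mm: float = 10.0,
    icp_params: dict | None = None,
    details: dict | None = None,
) -> dict[str, RigidTransform]:
    """Place both dental models in the face-scan frame (workflow steps 4-6).

    Returns {"maxilla": T, "mandible": T}. The mandible transform is, by
    construction, compose(maxilla transform in the tray chain, occlusal
    fit). Failures raise WorkflowStepError naming the failed step.
    """
    from .meshops import crop, invert_normals

    icp_params = dict(icp_params or {})

    # step 4: fiducial alignment tray scan -> face scan
    try:
        fiducial_result = align_by_fiducial(
            tray_scan,
            face_scan,
            fiducial_landmarks_tray,
            fiducial_landmarks_face,
            **icp_params,
        )
        tray_to_face = fiducial_result.transform
    except Exception as exc:  # noqa: BLE001 - re-raised with step context
        raise WorkflowStepError(4, f"fiducial alignment failed: {exc}") from exc

    # step 5: impression crop + normal inversion + gumline model alignment
    try:
        impression = crop(tray_scan, impression_region)
        positive = invert_normals(impression)
        if gumline_landmarks_model is not None and gumline_landmarks_impression is not None:
            init = kabsch(gumline_landmarks_model, gumline_landmarks_impression)
            gum_mask = _region_mask(
                maxilla_model.vertices, gumline_landmarks_model, gumline_radius_mm
            )
            src_pts = maxilla_model.vertices[gum_mask] if np.any(gum_mask) else None
        else:
            init = RigidTransform.identity()
            src_pts = None
        fit = icp(maxilla_model, positive, init=init, source_points=src_pts, **icp_params)
        maxilla_in_tray = fit.transform
    except WorkflowStepError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise WorkflowStepError(5, f"impression/model alignment failed: {exc}") from exc
    maxilla_in_face = compose(tray_to_face, maxilla_in_tray)

    # step 6: mandible via occlusion-landmark fit against the posed maxilla
    try:
        occlusal = kabsch(occlusion_landmarks_mandible, occlusion_landmarks_maxilla)
        try:  # optional surface refinement at the occlusal contacts
            refine = icp(
                mandible_model,
                maxilla_model,
                init=occlusal,
                source_points=occlusion_landmarks_mandible.points,
                **{**icp_params, "max_iterations": 10},
            )
            occlusal = refine.transform
        except (RegistrationFailureError, DegenerateConfigurationError):
            pass  # landmark fit alone is acceptable at sparse contact
    except WorkflowStepError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise WorkflowStepError(6, f"occlusal alignment failed: {exc}") from exc
    mandible_in_face = compose(maxilla_in_face, occlusal)

    if details is not None:
        details.update(
            fiducial_result=fiducial_result,
            gumline_result=fit,
            tray_to_face=tray_to_face,
            maxilla_in_tray=maxilla_in_tray,
            occlusal_fit=occlusal,
        )
    return {"maxilla": maxilla_in_face, "mandible": mandible_in_face}
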