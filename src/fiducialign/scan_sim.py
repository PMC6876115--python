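"""Virtual structured-light scanner and synthetic face/arch surrogates.

The scanner model: densify the surface to ~sample_spacing, displace each
sample along its surface normal by N(0, noise_sigma^2), apply uniform
Laplacian smoothing passes (emulating the edge radiusing that real scans
show on sharp features), and cull faces back-facing every view direction.
Defaults mirror a scanner with 0.1 mm resolution and 0.05 mm point
accuracy. One integer seed drives one pseudo-random stream per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyScanError, InvalidParameterError
from .fiducial_factory import FiducialSpec, make_cross_marker, make_sphere_marker
from .mesh import TriangleMesh, laplacian_smooth, subdivide_to_spacing
from .register import RigidTransform


@dataclass(frozen=True)
class ScanConfig:
    """Virtual-scanner parameters (all lengths in millimetres)."""

    noise_sigma: float = 0.05
    sample_spacing: float = 0.1
    smoothing_iters: int = 0
    coverage_dirs: tuple = ()  # empty = full coverage
    seed: int = 0
    isotropic_noise: bool = False  # default: noise along surface normals
    smoothing_lambda: float = 0.5
    max_faces: int = 400_000

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.sample_spacing <= 0:
            raise InvalidParameterError("sample_spacing must be > 0")
        if self.smoothing_iters < 0:
            raise InvalidParameterError("smoothing_iters must be >= 0")

    def with_seed(self, seed: int) -> "ScanConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class GroundTruthPose:
    """A rigid motion applied to an object before scanning, kept for scoring."""

    transform: RigidTransform
    label: str = ""


def simulate_scan(mesh: TriangleMesh, config: ScanConfig) -> TriangleMesh:
    """Produce a synthetic scan surface of ``mesh``.

    Deterministic given (mesh, config): the same seed yields bitwise
    identical vertex arrays. Raises EmptyScanError if coverage culling
    removes every face.
    """
    if mesh.n_faces == 0:
        raise InvalidParameterError("cannot scan an empty mesh")
    scan = subdivide_to_spacing(mesh, config.sample_spacing, config.max_faces)

    rng = np.random.default_rng(config.seed)
    if config.isotropic_noise:
        offsets = rng.normal(0.0, config.noise_sigma, size=scan.vertices.shape)
    else:
        eps = rng.normal(0.0, config.noise_sigma, size=scan.n_vertices)
        offsets = scan.vertex_normals() * eps[:, None]
    scan = TriangleMesh(scan.vertices + offsets, scan.faces, f"{mesh.name}_scan")

    if config.smoothing_iters > 0:
        scan = laplacian_smooth(scan, config.smoothing_iters, config.smoothing_lambda)

    if config.coverage_dirs:
        normals = scan.face_normals()
        visible = np.zeros(scan.n_faces, dtype=bool)
        for view in config.coverage_dirs:
            v = np.asarray(view, dtype=np.float64)
            v = v / np.linalg.norm(v)
            visible |= normals @ v < 0.0  # facing the scanner
        if not np.any(visible):
            raise EmptyScanError("coverage directions eliminate all faces")
        scan = scan.submesh(visible)
    return scan


def pose_and_scan(
    mesh: TriangleMesh, pose: GroundTruthPose, config: ScanConfig
) -> tuple[TriangleMesh, GroundTruthPose]:
    """Scan the posed object; echo the pose for later recovery scoring."""
    posed = pose.transform.apply_mesh(mesh)
    return simulate_scan(posed, config), pose


def edge_rounding_bias(marker_kind: str, config: ScanConfig) -> float:
    """Scan-vs-original RMSE for a default marker under the given config.

    Quantifies how much the virtual scanner distorts each marker shape;
    with smoothing the cross (sharp edges) fares worse than the sphere.
    """
    from .deviation import surface_deviation

    if marker_kind == "sphere":
        marker = make_sphere_marker(FiducialSpec().sphere_radius)
    elif marker_kind == "cross":
        marker = make_cross_marker(FiducialSpec(kind="cross"))
    else:
        raise InvalidParameterError(f"unknown marker kind: {marker_kind!r}")
    scan = simulate_scan(marker, config)
    report = surface_deviation(
        scan, marker, sample_spacing=max(config.sample_spacing, 0.3), vertices_only=True
    )
    return report.rmse


def make_face_surrogate(seed: int = 0) -> TriangleMesh:
    """Smooth half-ellipsoid face stand-in (~180 x 120 x 90 mm) with a nose.

    Deterministic per seed; the seed jitters the global proportions by a
    few percent only, so the construction bounds always hold.
    """
    rng = np.random.default_rng(seed)
    scale = 1.0 + rng.uniform(-0.04, 0.04, size=3)
    a, b, c = 60.0 * scale[0], 90.0 * scale[1], 90.0 * scale[2]  # x, y, z semi-axes
    nose_amp = 12.0 * (1.0 + rng.uniform(-0.1, 0.1))

    n_u, n_v = 48, 48
    u = np.linspace(0.0, np.pi, n_u)  # polar angle from +y (head top)
    v = np.linspace(0.0, np.pi, n_v)  # azimuth over the front half (z >= 0)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = a * np.sin(uu) * np.cos(vv)
    y = b * np.cos(uu)
    z = c * np.sin(uu) * np.sin(vv)
    # nose: forward bump near the facial midline, slightly below centre
    bump = nose_amp * np.exp(-((x / 12.0) ** 2) - (((y + 10.0) / 15.0) ** 2))
    z = z + bump * np.clip(np.sin(uu) * np.sin(vv), 0.0, None)

    verts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    faces = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            q = i * n_v + j
            faces.append([q, q + n_v, q + n_v + 1])
            faces.append([q, q + n_v + 1, q + 1])
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64), f"face_{seed}")
    return mesh.merged_vertices().remove_degenerate_faces()


def _arch_params(n_teeth: int, seed: int) -> dict:
    if not 6 <= n_teeth <= 16:
        raise InvalidParameterError("n_teeth must be in [6, 16]")
    rng = np.random.default_rng(seed)
    return {
        "half_width": 21.0 * (1.0 + rng.uniform(-0.04, 0.04)),  # arch + band span ~50 mm in x
        "depth": 40.0 * (1.0 + rng.uniform(-0.04, 0.04)),  # arch extends in +y
        "band": 5.0,  # half-width of the ridge band [mm]
        "ridge_height": 6.0,
        "cusp_amp": 3.0,
        "centres": (np.arange(n_teeth) + 0.5) / n_teeth * 2.0 - 1.0,
        "sigma_t": 0.5 / n_teeth,
    }


def arch_cusp_tips(n_teeth: int = 14, seed: int = 0) -> np.ndarray:
    """Analytic cusp-tip coordinates of the arch surrogate (model frame)."""
    p = _arch_params(n_teeth, seed)
    c = p["centres"]
    x = p["half_width"] * c
    y = p["depth"] * (1.0 - c**2)
    cusps = np.zeros_like(c)
    for c0 in p["centres"]:
        cusps += np.exp(-(((c - c0) / p["sigma_t"]) ** 2))
    z = p["ridge_height"] + p["cusp_amp"] * cusps
    return np.stack([x, y, z], axis=1)


def make_arch_surrogate(n_teeth: int = 14, seed: int = 0) -> TriangleMesh:
    """Parabolic dental-arch ridge (~50 mm wide) with hemispherical cusps.

    The ridge line carries exactly ``n_teeth`` local height maxima (one per
    cusp) by construction. Deterministic per seed.
    """
    p = _arch_params(n_teeth, seed)
    half_width = p["half_width"]
    depth = p["depth"]
    band = p["band"]
    ridge_height = p["ridge_height"]
    cusp_amp = p["cusp_amp"]

    n_t, n_s = 160, 14
    t = np.linspace(-1.0, 1.0, n_t)  # arch parameter, follows the parabola
    s = np.linspace(-band, band, n_s)  # transverse offset
    tt, ss = np.meshgrid(t, s, indexing="ij")

    cx = half_width * tt
    cy = depth * (1.0 - tt**2)
    # transverse direction = unit normal of the parabola in the xy-plane
    dx = np.full_like(tt, half_width)
    dy = -2.0 * depth * tt
    norm = np.sqrt(dx**2 + dy**2)
    nx_, ny_ = -dy / norm, dx / norm

    x = cx + ss * nx_
    y = cy + ss * ny_
    cusps = np.zeros_like(tt)
    for c0 in p["centres"]:
        cusps += np.exp(-(((tt - c0) / p["sigma_t"]) ** 2))
    z = (ridge_height + cusp_amp * cusps) * np.exp(-((ss / band) ** 2) * 2.0)

    verts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    faces = []
    for i in range(n_t - 1):
        for j in range(n_s - 1):
            q = i * n_s + j
            faces.append([q, q + n_s, q + n_s + 1])
            faces.append([q, q + n_s + 1, q + 1])
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64), f"arch_{n_teeth}_{seed}")
    return mesh.remove_degenerate_faces()


def ridge_line_heights(n_teeth: int = 14, seed: int = 0) -> np.ndarray:
    """Heights along the arch surrogate's ridge centreline (for cusp counting)."""
    arch = make_arch_surrogate(n_teeth, seed)
    n_s = 14
    verts = arch.vertices.reshape(-1, n_s, 3) if arch.n_vertices % n_s == 0 else None
    if verts is None:
        raise InvalidParameterError("arch surrogate layout changed")
    mid = n_s // 2
    return verts[:, mid, 2]
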