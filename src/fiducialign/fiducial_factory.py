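"""Parametric sphere and cross fiducial markers and their cylindrical mount.

Dimensions default to: sphere radius 10 mm; cross arms 20 mm long with a
6 x 6 mm section; base cylinder 8 mm diameter x 10 mm; marker mounted
15 mm above the base origin. All configurable through FiducialSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .mesh import TriangleMesh, concatenate
from .stlio import read_stl, write_stl  # noqa: F401  (module-level I/O surface)

SPHERE = "sphere"
CROSS = "cross"


@dataclass(frozen=True)
class FiducialSpec:
    """Dimensions of a fiducial marker and its mounting base, millimetres."""

    kind: str = SPHERE
    sphere_radius: float = 10.0
    cross_arm_length: float = 20.0
    cross_arm_width: float = 6.0
    cross_arm_depth: float = 6.0
    base_diameter: float = 8.0
    base_height: float = 10.0
    mount_offset: tuple = (0.0, 0.0, 15.0)

    def __post_init__(self):
        if self.kind not in (SPHERE, CROSS):
            raise InvalidParameterError(f"unknown fiducial kind: {self.kind!r}")
        dims = (
            self.sphere_radius,
            self.cross_arm_length,
            self.cross_arm_width,
            self.cross_arm_depth,
            self.base_diameter,
            self.base_height,
        )
        if any(d <= 0 for d in dims):
            raise InvalidParameterError("all fiducial dimensions must be strictly positive")
        if self.cross_arm_width >= self.cross_arm_length:
            raise InvalidParameterError("cross_arm_width must be < cross_arm_length")


def make_sphere_marker(radius: float = 10.0, refinement: int = 3) -> TriangleMesh:
    """Watertight icosphere of the given radius centred at the origin.

    ``refinement`` midpoint-subdivision levels are applied to a unit
    icosahedron before scaling; vertex count grows ~4x per level.
    """
    if radius <= 0:
        raise InvalidParameterError("sphere radius must be positive")
    if refinement < 0:
        raise InvalidParameterError("refinement must be >= 0")
    mesh = _icosahedron()
    for _ in range(refinement):
        mesh = _subdivide_on_sphere(mesh)
    return TriangleMesh(mesh.vertices * radius, mesh.faces, name=f"sphere_r{radius:g}")


def _icosahedron() -> TriangleMesh:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return TriangleMesh(v, f, "icosahedron")


def _subdivide_on_sphere(mesh: TriangleMesh) -> TriangleMesh:
    from .mesh import subdivide

    out = subdivide(mesh)
    v = out.vertices / np.linalg.norm(out.vertices, axis=1, keepdims=True)
    return TriangleMesh(v, out.faces, mesh.name)


def make_cross_marker(spec: FiducialSpec | None = None, **overrides) -> TriangleMesh:
    """Watertight cross: two orthogonal rectangular arms sharing a centre.

    Built as a plus-shaped 12-gon prism (the exact union of the two boxes),
    centred at the origin with arms along x and y and depth along z.
    """
    if spec is None:
        spec = FiducialSpec(kind=CROSS, **overrides)
    if spec.kind != CROSS:
        raise InvalidParameterError("spec.kind must be 'cross'")
    hl = spec.cross_arm_length / 2.0  # arm half-length
    hw = spec.cross_arm_width / 2.0  # arm half-width
    hd = spec.cross_arm_depth / 2.0  # half-depth (z)

    # plus-sign polygon, CCW starting at the +x arm's lower corner
    poly = np.array(
        [
            [hl, -hw], [hl, hw], [hw, hw], [hw, hl], [-hw, hl], [-hw, hw],
            [-hl, hw], [-hl, -hw], [-hw, -hw], [-hw, -hl], [hw, -hl], [hw, -hw],
        ],
        dtype=np.float64,
    )
    n = len(poly)
    top = np.column_stack([poly, np.full(n, hd)])
    bot = np.column_stack([poly, np.full(n, -hd)])
    vertices = np.concatenate([top, bot])

    # cap triangulation: central square + four arm rectangles (indices into poly)
    cap_quads = [
        (11, 2, 5, 8),   # central square: (hw,-hw),(hw,hw),(-hw,hw),(-hw,-hw)
        (0, 1, 2, 11),   # +x arm
        (3, 4, 5, 2),    # +y arm
        (6, 7, 8, 5),    # -x arm
        (9, 10, 11, 8),  # -y arm
    ]
    faces = []
    for a, b, c, d in cap_quads:  # top cap, CCW seen from +z
        faces.append([a, b, c])
        faces.append([a, c, d])
    for a, b, c, d in cap_quads:  # bottom cap, reversed winding
        faces.append([a + n, c + n, b + n])
        faces.append([a + n, d + n, c + n])
    for i in range(n):  # side walls
        j = (i + 1) % n
        faces.append([i, i + n, j + n])
        faces.append([i, j + n, j])
    name = f"cross_{spec.cross_arm_length:g}x{spec.cross_arm_width:g}x{spec.cross_arm_depth:g}"
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64), name)


def make_cylinder(diameter: float, height: float, segments: int = 48) -> TriangleMesh:
    """Watertight z-aligned cylinder with its base at z=0."""
    if diameter <= 0 or height <= 0:
        raise InvalidParameterError("cylinder dimensions must be positive")
    if segments < 3:
        raise InvalidParameterError("segments must be >= 3")
    r = diameter / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, segments, endpoint=False)
    ring = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    bottom = np.column_stack([ring, np.zeros(segments)])
    top = np.column_stack([ring, np.full(segments, height)])
    centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, height]])
    vertices = np.concatenate([bottom, top, centers])
    cb, ct = 2 * segments, 2 * segments + 1
    faces = []
    for i in range(segments):
        j = (i + 1) % segments
        faces.append([i, j, j + segments])
        faces.append([i, j + segments, i + segments])
        faces.append([cb, j, i])                      # bottom cap (normal -z)
        faces.append([ct, i + segments, j + segments])  # top cap (normal +z)
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64), "cylinder")


def make_marker(spec: FiducialSpec) -> TriangleMesh:
    """Dispatch on spec.kind."""
    if spec.kind == SPHERE:
        return make_sphere_marker(spec.sphere_radius)
    return make_cross_marker(spec)


def marker_landmarks(spec: FiducialSpec) -> np.ndarray:
    """Canonical registration landmarks on the marker surface (marker frame).

    Sphere: four points on the surface spanning three axes. Cross: the four
    arm-tip top edge midpoints plus the centre of the top face.
    """
    if spec.kind == SPHERE:
        r = spec.sphere_radius
        return np.array(
            [[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, 0, r]], dtype=np.float64
        )
    hl = spec.cross_arm_length / 2.0
    hd = spec.cross_arm_depth / 2.0
    return np.array(
        [[hl, 0, hd], [-hl, 0, hd], [0, hl, hd], [0, -hl, hd], [0, 0, hd]],
        dtype=np.float64,
    )


def attach_to_base(marker: TriangleMesh, spec: FiducialSpec, boolean_union: bool = False) -> TriangleMesh:
    """Assemble marker (translated by spec.mount_offset) with its cylinder base.

    The default assembly is a concatenation: two connected components whose
    relative pose is exactly ``mount_offset``. ``boolean_union=True`` is a
    reserved flag — robust mesh booleans are out of scope here.
    """
    if marker.n_faces == 0:
        raise InvalidParameterError("marker mesh is empty")
    if boolean_union:
        raise NotImplementedError(
            "boolean union of marker and base is not implemented; use concatenation"
        )
    base = make_cylinder(spec.base_diameter, spec.base_height)
    placed = marker.translated(np.asarray(spec.mount_offset, dtype=np.float64))
    assembly = concatenate([placed, base], name=f"{marker.name}_assembly")
    return assembly
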