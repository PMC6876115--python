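"""STL (standard tessellation language) reading and writing.

Both dialects of the de-facto standard are supported: binary (80-byte
header, little-endian float32 triples, uint16 attribute) and ASCII.
Units are fixed to millimetres package-wide and stated in the header.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import STLParseError
from .mesh import TriangleMesh

_BINARY_HEADER = b"fiducialign STL (units: mm)"
_RECORD = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("v0", "<f4", (3,)),
        ("v1", "<f4", (3,)),
        ("v2", "<f4", (3,)),
        ("attr", "<u2"),
    ]
)


def _soup_to_mesh(triangles: np.ndarray, name: str) -> TriangleMesh:
    """Index a (m, 3, 3) float32 triangle soup by merging exactly-equal vertices."""
    flat = triangles.reshape(-1, 3).astype(np.float64)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    return TriangleMesh(uniq, inverse.reshape(-1, 3), name)


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file into an indexed TriangleMesh.

    Exactly-coincident triangle corners are merged into shared vertices.
    Raises STLParseError naming the byte offset (binary) or line (ASCII)
    on malformed input.
    """
    path = Path(path)
    raw = path.read_bytes()
    if _looks_ascii(raw):
        return _read_ascii(raw, path.stem)
    return _read_binary(raw, path.stem)


def _looks_ascii(raw: bytes) -> bool:
    if not raw.lstrip().startswith(b"solid"):
        return False
    # binary files may also begin with "solid"; require a facet/endsolid keyword
    head = raw[:2048]
    return b"facet" in head or b"endsolid" in head


def _read_binary(raw: bytes, name: str) -> TriangleMesh:
    if len(raw) < 84:
        raise STLParseError(
            f"binary STL truncated: need 84 header bytes, got {len(raw)} (byte offset {len(raw)})"
        )
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) < expected:
        raise STLParseError(
            f"binary STL truncated: header declares {count} triangles "
            f"({expected} bytes) but file ends at byte offset {len(raw)}"
        )
    records = np.frombuffer(raw, dtype=_RECORD, count=count, offset=84)
    soup = np.stack([records["v0"], records["v1"], records["v2"]], axis=1)
    return _soup_to_mesh(soup, name)


def _read_ascii(raw: bytes, name: str) -> TriangleMesh:
    verts: list[list[float]] = []
    solid_name = name
    current: list[list[float]] = []
    for lineno, line in enumerate(raw.decode("ascii", errors="replace").splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0].lower()
        if key == "solid":
            solid_name = tokens[1] if len(tokens) > 1 else name
        elif key == "vertex":
            if len(tokens) != 4:
                raise STLParseError(f"ASCII STL line {lineno}: expected 'vertex x y z'")
            try:
                current.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise STLParseError(f"ASCII STL line {lineno}: bad coordinate ({exc})") from exc
        elif key == "endfacet":
            if len(current) != 3:
                raise STLParseError(
                    f"ASCII STL line {lineno}: facet closed with {len(current)} vertices"
                )
            verts.extend(current)
            current = []
    if current:
        raise STLParseError("ASCII STL ended inside an open facet")
    if not verts:
        raise STLParseError("ASCII STL contains no facets")
    soup = np.asarray(verts, dtype=np.float32).reshape(-1, 3, 3)
    return _soup_to_mesh(soup, solid_name or name)


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a TriangleMesh as STL. ``dialect`` is "binary" or "ascii"."""
    path = Path(path)
    if dialect == "binary":
        _write_binary(mesh, path)
    elif dialect == "ascii":
        _write_ascii(mesh, path)
    else:
        raise ValueError(f"unknown STL dialect: {dialect!r}")


def _write_binary(mesh: TriangleMesh, path: Path) -> None:
    records = np.zeros(mesh.n_faces, dtype=_RECORD)
    tri = mesh.triangles.astype(np.float32)
    records["normal"] = mesh.face_normals().astype(np.float32)
    records["v0"], records["v1"], records["v2"] = tri[:, 0], tri[:, 1], tri[:, 2]
    header = _BINARY_HEADER.ljust(80, b"\0")[:80]
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", mesh.n_faces))
        fh.write(records.tobytes())


def _write_ascii(mesh: TriangleMesh, path: Path) -> None:
    name = mesh.name or "mesh"
    tri = mesh.triangles.astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    lines = [f"solid {name}"]
    for n, t in zip(normals, tri):
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in t:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {name}\n")
    Path(path).write_text("\n".join(lines))
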