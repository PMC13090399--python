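"""Triangular mesh and landmark I/O, topology validation, and basic mesh edits.

Supports ASCII/binary-little-endian PLY, OBJ and ASCII/binary STL.  All face
indexing is 0-based internally; OBJ's 1-based indices are converted at the
boundary.  Coordinates are passed through unmodified and assumed to be in
millimetres.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TriMesh",
    "LandmarkSet",
    "ValidationReport",
    "REQUIRED_LANDMARKS",
    "MeshFormatError",
    "LandmarkValidationError",
    "load_mesh",
    "save_mesh",
    "load_ply_with_attributes",
    "save_ply",
    "validate_single_layer",
    "extract_submesh",
    "reflect_across_plane",
    "load_landmarks",
    "save_landmarks",
    "convert_simple_landmark_text",
    "mean_edge_length",
]

#: Canonical landmark names required for initial registration, in fixed order.
REQUIRED_LANDMARKS = (
    "bregma",
    "ophryon",
    "frontotemporale_L",
    "frontotemporale_R",
    "stephanion_L",
    "stephanion_R",
)


class MeshFormatError(ValueError):
    """Raised for malformed or unsupported mesh file content."""


class LandmarkValidationError(ValueError):
    """Raised when a landmark set does not satisfy registration requirements."""


@dataclass
class TriMesh:
    """A single-specimen triangular surface mesh (mm units).

    Parameters
    ----------
    specimen_id
        Identifier of the specimen the mesh belongs to.
    vertices
        ``(n, 3)`` float array of vertex coordinates.
    faces
        ``(m, 3)`` int array of 0-based vertex index triples.
    """

    specimen_id: str
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshFormatError(
                    f"mesh '{self.specimen_id}': face index out of range"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriMesh":
        return TriMesh(self.specimen_id, self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same topology, new coordinates."""
        v = np.asarray(vertices, dtype=float).reshape(-1, 3)
        if len(v) != self.n_vertices:
            raise ValueError("vertex count mismatch")
        return TriMesh(self.specimen_id, v, self.faces.copy())


@dataclass
class LandmarkSet:
    """Named 3D landmarks on one specimen, in the mesh coordinate frame."""

    specimen_id: str
    points: dict[str, np.ndarray]
    observer_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def array(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Stack landmarks as a ``(k, 3)`` array in the given name order."""
        names = tuple(order) if order is not None else self.names
        missing = [n for n in names if n not in self.points]
        if missing:
            raise LandmarkValidationError(
                f"specimen '{self.specimen_id}' missing landmark(s): {', '.join(missing)}"
            )
        return np.stack([self.points[n] for n in names])

    def require_registration_landmarks(self) -> np.ndarray:
        """Validate against the canonical 6-landmark protocol; return (6, 3) array.

        Checks presence of all six names, pairwise distinctness and
        non-coplanarity (a 3D thin-plate spline needs full-rank controls).
        """
        pts = self.array(REQUIRED_LANDMARKS)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        iu = np.triu_indices(len(pts), 1)
        if np.any(d[iu] < 1e-9):
            raise LandmarkValidationError(
                f"specimen '{self.specimen_id}': coincident registration landmarks"
            )
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(pts).max())) < 3:
            raise LandmarkValidationError(
                f"specimen '{self.specimen_id}': registration landmarks are coplanar"
            )
        return pts

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.specimen_id,
            {k: v.copy() for k, v in self.points.items()},
            self.observer_id,
            self.session_id,
        )


@dataclass
class ValidationReport:
    """Topology summary for the single-layer mesh requirement."""

    connected_components: int
    nonmanifold_edges: int
    duplicate_faces: int
    boundary_loops: int
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = (
            self.connected_components == 1
            and self.nonmanifold_edges == 0
            and self.duplicate_faces == 0
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "connected_components": self.connected_components,
                "nonmanifold_edges": self.nonmanifold_edges,
                "duplicate_faces": self.duplicate_faces,
                "boundary_loops": self.boundary_loops,
                "passed": self.passed,
            }
        )


# ---------------------------------------------------------------------------
# Mesh readers / writers
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "b", "int8": "b",
    "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h",
    "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i",
    "uint": "I", "uint32": "I",
    "float": "f", "float32": "f",
    "double": "d", "float64": "d",
}


def _sniff_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "obj", "stl"):
        return suffix
    raise MeshFormatError(f"cannot infer mesh format from '{path.name}'")


def load_mesh(path: str | Path, fmt: str = "auto", specimen_id: str | None = None) -> TriMesh:
    """Read a triangular mesh from PLY, OBJ or STL.

    Raises
    ------
    OSError
        If the file cannot be read.
    MeshFormatError
        On malformed content or non-triangular faces (the offending face is
        named in the message).
    """
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    sid = specimen_id if specimen_id is not None else path.stem
    if fmt == "ply":
        mesh, _ = load_ply_with_attributes(path, specimen_id=sid)
        return mesh
    if fmt == "obj":
        return _load_obj(path, sid)
    if fmt == "stl":
        return _load_stl(path, sid)
    raise MeshFormatError(f"unsupported mesh format '{fmt}'")


def save_mesh(mesh: TriMesh, path: str | Path, fmt: str = "auto", *, binary: bool = True) -> None:
    """Write a mesh.  PLY output defaults to binary little-endian; OBJ and
    ASCII STL are text formats."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    if fmt == "ply":
        save_ply(mesh, path, binary=binary)
    elif fmt == "obj":
        _save_obj(mesh, path)
    elif fmt == "stl":
        _save_stl(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format '{fmt}'")


def load_ply_with_attributes(
    path: str | Path, specimen_id: str | None = None
) -> tuple[TriMesh, dict[str, np.ndarray]]:
    """Read a PLY file, returning the mesh plus any extra per-vertex scalar
    properties (e.g. ``quality``, ``red``) keyed by property name."""
    path = Path(path)
    sid = specimen_id if specimen_id is not None else path.stem
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshFormatError(f"'{path.name}' is not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list]] = []  # (name, count, props)
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"'{path.name}': unexpected end of header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise MeshFormatError(f"'{path.name}': property before element")
                if tokens[1] == "list":
                    elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
                else:
                    elements[-1][2].append(("scalar", tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise MeshFormatError(f"'{path.name}': unsupported PLY format '{fmt}'")
        if fmt == "ascii":
            data = _read_ply_ascii(fh, elements, path)
        else:
            data = _read_ply_binary(fh, elements, path)

    if "vertex" not in data:
        raise MeshFormatError(f"'{path.name}': no vertex element")
    vprops = data["vertex"]
    try:
        verts = np.column_stack([vprops["x"], vprops["y"], vprops["z"]])
    except KeyError as exc:
        raise MeshFormatError(f"'{path.name}': vertex element missing {exc}") from exc
    faces_rows = data.get("face", {}).get("vertex_indices", [])
    faces = []
    for i, row in enumerate(faces_rows):
        if len(row) != 3:
            raise MeshFormatError(f"'{path.name}': face {i} is not a triangle")
        faces.append(row)
    extra = {
        k: np.asarray(v, dtype=float)
        for k, v in vprops.items()
        if k not in ("x", "y", "z")
    }
    return TriMesh(sid, verts, np.asarray(faces, dtype=np.int64).reshape(-1, 3)), extra


def _read_ply_ascii(fh, elements, path: Path) -> dict:
    out: dict[str, dict] = {}
    text = fh.read().decode("ascii", "replace").split()
    pos = 0

    def take(n):
        nonlocal pos
        vals = text[pos : pos + n]
        pos += n
        if len(vals) < n:
            raise MeshFormatError(f"'{path.name}': truncated ASCII body")
        return vals

    for name, count, props in elements:
        cols: dict[str, list] = {p[-1] if p[0] == "scalar" else p[3]: [] for p in props}
        for _ in range(count):
            for p in props:
                if p[0] == "scalar":
                    cols[p[2]].append(float(take(1)[0]))
                else:
                    n = int(float(take(1)[0]))
                    cols[p[3]].append([int(float(v)) for v in take(n)])
        out[name] = cols
    return out


def _read_ply_binary(fh, elements, path: Path) -> dict:
    out: dict[str, dict] = {}
    for name, count, props in elements:
        if all(p[0] == "scalar" for p in props):
            fmt = "<" + "".join(_PLY_TYPES[p[1]] for p in props)
            size = struct.calcsize(fmt)
            raw = fh.read(size * count)
            if len(raw) < size * count:
                raise MeshFormatError(f"'{path.name}': truncated binary body")
            rows = list(struct.iter_unpack(fmt, raw))
            out[name] = {
                p[2]: np.array([r[i] for r in rows]) for i, p in enumerate(props)
            }
        else:
            cols: dict[str, list] = {p[-1] if p[0] == "scalar" else p[3]: [] for p in props}
            for _ in range(count):
                for p in props:
                    if p[0] == "scalar":
                        code = _PLY_TYPES[p[1]]
                        (val,) = struct.unpack("<" + code, fh.read(struct.calcsize(code)))
                        cols[p[2]].append(val)
                    else:
                        ccode, icode = _PLY_TYPES[p[1]], _PLY_TYPES[p[2]]
                        (n,) = struct.unpack("<" + ccode, fh.read(struct.calcsize(ccode)))
                        vals = struct.unpack(
                            "<" + icode * n, fh.read(struct.calcsize(icode) * n)
                        )
                        cols[p[3]].append(list(vals))
            out[name] = cols
    return out


def save_ply(
    mesh: TriMesh,
    path: str | Path,
    *,
    binary: bool = True,
    vertex_attributes: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write PLY.  ``vertex_attributes`` adds extra per-vertex properties;
    names ``red``/``green``/``blue`` are written as uchar, others as float."""
    path = Path(path)
    attrs = dict(vertex_attributes or {})
    for k, v in attrs.items():
        v = np.asarray(v)
        if len(v) != mesh.n_vertices:
            raise ValueError(f"vertex attribute '{k}' length mismatch")
        attrs[k] = v
    color_names = {"red", "green", "blue", "alpha"}
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {mesh.n_vertices}")
    header += ["property double x", "property double y", "property double z"]
    for k in attrs:
        header.append(
            f"property uchar {k}" if k in color_names else f"property double {k}"
        )
    header.append(f"element face {mesh.n_faces}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            vfmt = "<ddd" + "".join("B" if k in color_names else "d" for k in attrs)
            for i in range(mesh.n_vertices):
                vals = list(mesh.vertices[i])
                for k in attrs:
                    vals.append(
                        int(attrs[k][i]) if k in color_names else float(attrs[k][i])
                    )
                fh.write(struct.pack(vfmt, *vals))
            for f in mesh.faces:
                fh.write(struct.pack("<Biii", 3, *[int(v) for v in f]))
        else:
            lines = []
            for i in range(mesh.n_vertices):
                parts = [f"{c:.17g}" for c in mesh.vertices[i]]
                for k in attrs:
                    parts.append(
                        str(int(attrs[k][i])) if k in color_names else f"{float(attrs[k][i]):.17g}"
                    )
                lines.append(" ".join(parts))
            for f in mesh.faces:
                lines.append("3 " + " ".join(str(int(v)) for v in f))
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def _load_obj(path: Path, sid: str) -> TriMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if tokens[0] == "v":
                verts.append([float(v) for v in tokens[1:4]])
            elif tokens[0] == "f":
                idx = [int(t.split("/")[0]) for t in tokens[1:]]
                if len(idx) != 3:
                    raise MeshFormatError(
                        f"'{path.name}' line {lineno}: face with {len(idx)} vertices "
                        "(triangles only)"
                    )
                # OBJ is 1-based; negative indices count from the end
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                faces.append(idx)
    return TriMesh(sid, np.asarray(verts), np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def _save_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {mesh.specimen_id}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _load_stl(path: Path, sid: str) -> TriMesh:
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head == b"solid":
        try:
            return _load_stl_ascii(path, sid)
        except UnicodeDecodeError:
            pass  # binary file that happens to start with "solid"
    return _load_stl_binary(path, sid)


def _load_stl_ascii(path: Path, sid: str) -> TriMesh:
    tri_pts: list[list[float]] = []
    with open(path, encoding="ascii") as fh:
        for line in fh:
            tokens = line.split()
            if tokens and tokens[0] == "vertex":
                tri_pts.append([float(v) for v in tokens[1:4]])
    if len(tri_pts) % 3:
        raise MeshFormatError(f"'{path.name}': vertex count not a multiple of 3")
    return _weld_stl(np.asarray(tri_pts), sid)


def _load_stl_binary(path: Path, sid: str) -> TriMesh:
    with open(path, "rb") as fh:
        fh.read(80)
        (n,) = struct.unpack("<I", fh.read(4))
        raw = fh.read(50 * n)
    if len(raw) < 50 * n:
        raise MeshFormatError(f"'{path.name}': truncated binary STL")
    arr = np.frombuffer(raw, dtype=np.uint8).reshape(n, 50)
    tri = arr[:, 12:48].copy().view("<f4").reshape(n, 3, 3).astype(float)
    return _weld_stl(tri.reshape(-1, 3), sid)


def _weld_stl(tri_pts: np.ndarray, sid: str) -> TriMesh:
    """Merge exactly-equal vertices (STL stores each triangle independently)."""
    verts, inv = np.unique(tri_pts, axis=0, return_inverse=True)
    faces = inv.reshape(-1, 3)
    bad = np.nonzero(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )[0]
    if bad.size:
        raise MeshFormatError(f"degenerate STL facet {int(bad[0])}")
    return TriMesh(sid, verts, faces)


def _save_stl(mesh: TriMesh, path: Path) -> None:
    # ASCII with full precision so write/read round-trips within 1e-6 mm
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write(f"solid {mesh.specimen_id}\n")
        for a, b, c in f:
            n = np.cross(v[b] - v[a], v[c] - v[a])
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            fh.write("    outer loop\n")
            for idx in (a, b, c):
                p = v[idx]
                fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {mesh.specimen_id}\n")


# ---------------------------------------------------------------------------
# Topology validation and edits
# ---------------------------------------------------------------------------


def _face_edges(faces: np.ndarray) -> np.ndarray:
    """All face edges as sorted (lo, hi) vertex pairs, shape (3m, 2)."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def validate_single_layer(mesh: TriMesh) -> ValidationReport:
    """Check the mesh is one connected, manifold, duplicate-free layer.

    Components are counted by union-find over faces that share an edge; an
    edge shared by more than two faces is non-manifold; duplicate faces are
    extra occurrences of the same unordered vertex triple.
    """
    faces = mesh.faces
    if faces.size == 0:
        return ValidationReport(0, 0, 0, 0)
    if np.any(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    ):
        raise MeshFormatError(f"mesh '{mesh.specimen_id}': face repeats a vertex")

    sorted_faces = np.sort(faces, axis=1)
    _, counts = np.unique(sorted_faces, axis=0, return_counts=True)
    duplicate_faces = int((counts - 1).sum())

    edges = _face_edges(faces)
    uniq_edges, edge_inv, edge_counts = np.unique(
        edges, axis=0, return_inverse=True, return_counts=True
    )
    nonmanifold = int((edge_counts > 2).sum())

    # union-find over faces via shared edges
    parent = np.arange(len(faces))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    face_of_edge_slot = np.repeat(np.arange(len(faces)), 1)
    face_ids = np.concatenate([face_of_edge_slot] * 3)
    order = np.argsort(edge_inv, kind="stable")
    sorted_eids = edge_inv[order]
    sorted_fids = face_ids[order]
    boundaries = np.nonzero(np.diff(sorted_eids))[0] + 1
    groups = np.split(sorted_fids, boundaries)
    for grp in groups:
        r = find(int(grp[0]))
        for fid in grp[1:]:
            r2 = find(int(fid))
            if r2 != r:
                parent[r2] = r
    components = len({find(i) for i in range(len(faces))})

    boundary_edge_idx = np.nonzero(edge_counts == 1)[0]
    boundary_loops = _count_boundary_loops(uniq_edges[boundary_edge_idx])
    return ValidationReport(components, nonmanifold, duplicate_faces, boundary_loops)


def _count_boundary_loops(boundary_edges: np.ndarray) -> int:
    if len(boundary_edges) == 0:
        return 0
    verts = np.unique(boundary_edges)
    index = {int(v): i for i, v in enumerate(verts)}
    parent = list(range(len(verts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in boundary_edges:
        ra, rb = find(index[int(a)]), find(index[int(b)])
        if ra != rb:
            parent[ra] = rb
    return len({find(i) for i in range(len(verts))})


def extract_submesh(
    mesh: TriMesh, keep: Iterable[int]
) -> tuple[TriMesh, np.ndarray]:
    """Keep the given vertices and every face fully inside the kept set.

    Returns the compacted submesh and an ``old → new`` index map (length =
    original vertex count, -1 where dropped).
    """
    keep_idx = np.unique(np.asarray(list(keep), dtype=np.int64))
    if keep_idx.size == 0:
        raise ValueError("keep set is empty")
    if keep_idx.min() < 0 or keep_idx.max() >= mesh.n_vertices:
        raise ValueError("keep contains out-of-range vertex indices")
    mapping = np.full(mesh.n_vertices, -1, dtype=np.int64)
    mapping[keep_idx] = np.arange(keep_idx.size)
    mask = np.all(mapping[mesh.faces] >= 0, axis=1) if mesh.faces.size else np.zeros(0, bool)
    new_faces = mapping[mesh.faces[mask]]
    sub = TriMesh(mesh.specimen_id, mesh.vertices[keep_idx], new_faces)
    return sub, mapping


def reflect_across_plane(
    mesh: TriMesh, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> TriMesh:
    """Mirror the mesh across the plane through three points.

    Face winding is flipped so outward normals are preserved under the
    orientation-reversing map.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p1), 1e-30)
    if nn < 1e-12 * scale * scale:
        raise ValueError("plane points are collinear (degenerate plane)")
    n = n / nn
    d = (mesh.vertices - p1) @ n
    reflected = mesh.vertices - 2.0 * d[:, None] * n
    flipped = mesh.faces[:, [0, 2, 1]]
    return TriMesh(mesh.specimen_id, reflected, flipped)


def mean_edge_length(mesh: TriMesh) -> float:
    """Mean length over unique mesh edges (mm)."""
    edges = np.unique(_face_edges(mesh.faces), axis=0)
    d = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    return float(d.mean())


# ---------------------------------------------------------------------------
# Landmark I/O (CSV interchange)
# ---------------------------------------------------------------------------

_LM_COLUMNS = ("specimen_id", "landmark", "x", "y", "z")


def load_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read landmark CSV (columns specimen_id, landmark, x, y, z, optional
    observer_id/session_id), grouped by (specimen, observer, session).

    Sets containing all six registration landmarks are reordered to the
    canonical order.
    """
    path = Path(path)
    groups: dict[tuple, dict[str, np.ndarray]] = {}
    order: list[tuple] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_LM_COLUMNS) <= set(reader.fieldnames):
            raise LandmarkValidationError(
                f"'{path.name}': landmark CSV needs columns {', '.join(_LM_COLUMNS)}"
            )
        for row in reader:
            key = (
                row["specimen_id"],
                row.get("observer_id") or None,
                row.get("session_id") or None,
            )
            if key not in groups:
                groups[key] = {}
                order.append(key)
            groups[key][row["landmark"]] = np.array(
                [float(row["x"]), float(row["y"]), float(row["z"])]
            )
    out = []
    for key in order:
        pts = groups[key]
        if set(REQUIRED_LANDMARKS) <= set(pts):
            ordered = {n: pts[n] for n in REQUIRED_LANDMARKS}
            ordered.update({n: p for n, p in pts.items() if n not in ordered})
            pts = ordered
        out.append(LandmarkSet(key[0], pts, observer_id=key[1], session_id=key[2]))
    return out


def save_landmarks(sets: Sequence[LandmarkSet], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_LM_COLUMNS) + ["observer_id", "session_id"])
        for lms in sets:
            for name, p in lms.points.items():
                writer.writerow(
                    [
                        lms.specimen_id,
                        name,
                        f"{p[0]:.17g}",
                        f"{p[1]:.17g}",
                        f"{p[2]:.17g}",
                        lms.observer_id or "",
                        lms.session_id or "",
                    ]
                )


def convert_simple_landmark_text(path: str | Path, specimen_id: str) -> LandmarkSet:
    """Convert plain "name x y z" landmark text (one per line) to a LandmarkSet."""
    pts: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 4:
                raise LandmarkValidationError(f"bad landmark line: {line.rstrip()}")
            pts[tokens[0]] = np.array([float(v) for v in tokens[1:4]])
    return LandmarkSet(specimen_id, pts)
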