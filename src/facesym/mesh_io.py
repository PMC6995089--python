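"""Triangulated facial surfaces, landmarks and scalar overlays.

Meshes are plain vertex/face arrays in millimetres.  Reading OBJ and
ASCII PLY goes through :mod:`trimesh`; legacy-ASCII VTK polydata (the
format produced by common craniofacial toolchains) is parsed and written
here.  Writers emit full double precision so that write→read round-trips
preserve geometry to well below 1e-6 mm.

Landmarks are named anatomical points.  Five of them drive the midface
registration: subnasale plus the inner (endocanthion) and outer
(exocanthion) eye corners bilaterally.  The chin apex (pogonion) is the
substrate of the chin-asymmetry score.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyRoiError, FormatError, MeshIOError, ValidationError

#: Landmarks required for midface mirror registration.
REGISTRATION_LANDMARKS = (
    "subnasale",
    "endocanthion_left",
    "endocanthion_right",
    "exocanthion_left",
    "exocanthion_right",
)

_COLLINEARITY_TOL = 1e-8


@dataclass
class TriangleMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm, ``faces`` (m, 3) indices.

    Counter-clockwise face winding encodes the outward normal.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def validate(self) -> "TriangleMesh":
        if len(self.vertices) < 3 or len(self.faces) < 1:
            raise FormatError(
                f"mesh needs >=3 vertices and >=1 face, got "
                f"{len(self.vertices)} vertices / {len(self.faces)} faces"
            )
        if not np.isfinite(self.vertices).all():
            raise FormatError("mesh contains non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise FormatError("face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise FormatError("mesh contains degenerate faces (repeated vertex)")
        return self

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


def clean_mesh(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Drop degenerate (repeated-vertex) faces and unreferenced vertices."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    keep = ~(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    faces = faces[keep]
    if len(faces) == 0:
        raise FormatError("no non-degenerate faces left after cleaning")
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices[used], remap[faces]).validate()


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) with a bilateral-pair registry.

    The registry maps each ``*_left`` name to its ``*_right`` partner and
    is rebuilt automatically from the name suffixes.
    """

    points: dict[str, np.ndarray]
    bilateral_pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {
            str(k): np.asarray(v, dtype=float).reshape(3)
            for k, v in self.points.items()
        }
        if not self.bilateral_pairs:
            self.bilateral_pairs = {
                name: name[: -len("_left")] + "_right"
                for name in self.points
                if name.endswith("_left")
                and name[: -len("_left")] + "_right" in self.points
            }

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self) -> list[str]:
        return list(self.points)

    def coords(self, names) -> np.ndarray:
        return np.stack([self.points[n] for n in names])

    def validate(self) -> "LandmarkSet":
        missing = [n for n in REGISTRATION_LANDMARKS if n not in self.points]
        if missing:
            raise ValidationError(
                "missing required landmark(s): " + ", ".join(missing)
            )
        pts = self.coords(REGISTRATION_LANDMARKS)
        if len(np.unique(np.round(pts, 9), axis=0)) < 5:
            raise ValidationError("registration landmarks are not mutually distinct")
        centred = pts - pts.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        if s[1] <= _COLLINEARITY_TOL * max(s[0], 1.0):
            raise ValidationError(
                "registration landmarks are collinear: degenerate basis"
            )
        return self

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            {k: v.copy() for k, v in self.points.items()},
            dict(self.bilateral_pairs),
        )


@dataclass
class ScalarOverlay:
    """One scalar (mm) per vertex of an ROI mesh, for colour-coded export."""

    mesh: TriangleMesh
    values: np.ndarray
    name: str = "distance"
    units: str = "mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)

    def validate(self) -> "ScalarOverlay":
        if len(self.values) == 0:
            raise ValidationError("empty overlay: no scalar values")
        if len(self.values) != self.mesh.n_vertices:
            raise ValidationError(
                f"overlay has {len(self.values)} values for "
                f"{self.mesh.n_vertices} vertices"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("overlay contains non-finite values")
        return self


# ---------------------------------------------------------------------------
# readers / writers


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower().lstrip(".")
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("obj", "ply", "vtk"):
        return suffix
    try:
        head = path.open("rb").read(256).decode("ascii", "replace")
    except OSError as exc:
        raise MeshIOError(f"cannot read {path}: {exc}") from exc
    if head.startswith("ply"):
        return "ply"
    if head.startswith("# vtk DataFile"):
        return "vtk"
    return "obj"


def read_mesh(path, format_hint: str | None = None) -> TriangleMesh:
    """Read OBJ, ASCII PLY or legacy-ASCII VTK polydata into a TriangleMesh.

    Quads are fan-triangulated; normals, texture coordinates and material
    records are ignored; negative (relative) OBJ indices are accepted.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"mesh file not found: {path}")
    fmt = _detect_format(path, format_hint)
    if fmt == "vtk":
        vertices, faces, _ = _parse_vtk(path)
    elif fmt in ("obj", "ply"):
        try:
            loaded = trimesh.load(
                str(path), file_type=fmt, process=False, maintain_order=True
            )
        except Exception as exc:  # trimesh raises assorted types
            raise FormatError(f"cannot parse {fmt} file {path}: {exc}") from exc
        if not hasattr(loaded, "faces") or len(getattr(loaded, "faces", ())) == 0:
            raise FormatError(f"no triangulatable geometry in {path}")
        vertices, faces = loaded.vertices, loaded.faces
    else:
        raise FormatError(f"unsupported mesh format {fmt!r} for {path}")
    try:
        return TriangleMesh(vertices, faces).validate()
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write a mesh as OBJ, ASCII PLY or legacy-ASCII VTK polydata.

    Coordinates are written with 17 significant digits, so a read-back
    reproduces the geometry exactly to double precision.
    """
    mesh.validate()
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        text = _format_obj(mesh)
    elif fmt == "ply":
        text = _format_ply(mesh)
    elif fmt == "vtk":
        text = _format_vtk(mesh)
    else:
        raise FormatError(f"unsupported mesh format {fmt!r}")
    try:
        path.write_text(text)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


def _fmt_row(row: np.ndarray) -> str:
    return " ".join(f"{c:.17g}" for c in row)


def _format_obj(mesh: TriangleMesh) -> str:
    buf = io.StringIO()
    for v in mesh.vertices:
        buf.write(f"v {_fmt_row(v)}\n")
    for f in mesh.faces:
        buf.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    return buf.getvalue()


def _format_ply(mesh: TriangleMesh) -> str:
    buf = io.StringIO()
    buf.write(
        "ply\nformat ascii 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    for v in mesh.vertices:
        buf.write(_fmt_row(v) + "\n")
    for f in mesh.faces:
        buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return buf.getvalue()


def _format_vtk(mesh: TriangleMesh, scalars: np.ndarray | None = None,
                scalar_name: str = "distance") -> str:
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\nfacesym surface\nASCII\n")
    buf.write("DATASET POLYDATA\n")
    buf.write(f"POINTS {mesh.n_vertices} double\n")
    for v in mesh.vertices:
        buf.write(_fmt_row(v) + "\n")
    buf.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
    for f in mesh.faces:
        buf.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    if scalars is not None:
        buf.write(f"POINT_DATA {mesh.n_vertices}\n")
        buf.write(f"SCALARS {scalar_name} double 1\nLOOKUP_TABLE default\n")
        for s in scalars:
            buf.write(f"{s:.17g}\n")
    return buf.getvalue()


def _parse_vtk(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Parse legacy-ASCII VTK polydata; returns (vertices, faces, scalars)."""
    try:
        tokens = path.read_text().split("\n")
    except OSError as exc:
        raise MeshIOError(f"cannot read {path}: {exc}") from exc
    if not tokens or not tokens[0].startswith("# vtk DataFile"):
        raise FormatError(f"{path}: missing '# vtk DataFile' header")
    flat: list[str] = []
    # header: title line and ASCII marker are positional; the rest is a
    # whitespace-separated token stream
    for line in tokens[2:]:
        flat.extend(line.split())
    idx = {t.upper(): i for i, t in enumerate(flat)}
    if flat and flat[0].upper() != "ASCII":
        raise FormatError(f"{path}: only ASCII legacy VTK is supported")
    if "POLYDATA" not in idx:
        raise FormatError(f"{path}: DATASET POLYDATA expected")
    try:
        p = idx["POINTS"]
        n_pts = int(flat[p + 1])
        coords = np.array(flat[p + 3 : p + 3 + 3 * n_pts], dtype=float)
        vertices = coords.reshape(n_pts, 3)
        q = idx["POLYGONS"]
        n_poly = int(flat[q + 1])
        size = int(flat[q + 2])
        conn = np.array(flat[q + 3 : q + 3 + size], dtype=np.int64)
    except (KeyError, ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed VTK polydata: {exc}") from exc
    faces: list[list[int]] = []
    pos = 0
    for _ in range(n_poly):
        k = int(conn[pos])
        poly = conn[pos + 1 : pos + 1 + k]
        # fan-triangulate polygons with more than three corners
        for j in range(1, k - 1):
            faces.append([poly[0], poly[j], poly[j + 1]])
        pos += 1 + k
    scalars = None
    if "POINT_DATA" in idx and "SCALARS" in idx:
        s = idx["SCALARS"]
        # SCALARS name type [components] LOOKUP_TABLE name, then values
        off = s + 3
        if flat[off].upper() != "LOOKUP_TABLE":
            off += 1
        scalars = np.array(flat[off + 2 : off + 2 + n_pts], dtype=float)
    return vertices, np.asarray(faces, dtype=np.int64).reshape(-1, 3), scalars


def read_landmarks(path) -> LandmarkSet:
    """Read a ``name,x,y,z`` landmark table (mm) into a validated LandmarkSet."""
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"landmark file not found: {path}")
    points: dict[str, np.ndarray] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in re.split(r"[,\t;]|\s+", line) if p.strip()]
        if lineno == 1 and parts[0].lower() == "name":
            continue
        if len(parts) != 4:
            raise ValidationError(
                f"{path}:{lineno}: expected 'name,x,y,z', got {raw!r}"
            )
        name = parts[0]
        if name in points:
            raise ValidationError(f"{path}: duplicate landmark name {name!r}")
        try:
            points[name] = np.array([float(c) for c in parts[1:]])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: non-numeric coordinate") from exc
    return LandmarkSet(points).validate()


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    lines = ["name,x,y,z"]
    for name, p in landmarks.points.items():
        lines.append(f"{name},{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


def crop_halfspace(mesh: TriangleMesh, plane_point, plane_normal) -> TriangleMesh:
    """Keep faces whose three vertices satisfy dot(v − p, n) ≤ 0.

    Straddling faces are dropped whole (no re-triangulation); unreferenced
    vertices are removed.  Raises :class:`EmptyRoiError` if nothing remains.
    """
    plane_point = np.asarray(plane_point, dtype=float).reshape(3)
    plane_normal = np.asarray(plane_normal, dtype=float).reshape(3)
    if np.linalg.norm(plane_normal) == 0:
        raise ValidationError("crop plane normal must be nonzero")
    side = (mesh.vertices - plane_point) @ plane_normal
    inside = side <= 0
    keep = inside[mesh.faces].all(axis=1)
    if not keep.any():
        raise EmptyRoiError("half-space crop removed every face")
    return clean_mesh(mesh.vertices, mesh.faces[keep])


def write_scalar_overlay(overlay: ScalarOverlay, path) -> None:
    """Write the overlay as legacy-ASCII VTK polydata with POINT_DATA scalars."""
    overlay.validate()
    path = Path(path)
    text = _format_vtk(overlay.mesh, scalars=overlay.values,
                       scalar_name=overlay.name)
    try:
        path.write_text(text)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


def read_scalar_overlay(path) -> ScalarOverlay:
    """Read back a VTK overlay written by :func:`write_scalar_overlay`."""
    path = Path(path)
    vertices, faces, scalars = _parse_vtk(path)
    if scalars is None:
        raise FormatError(f"{path}: no SCALARS point data found")
    return ScalarOverlay(TriangleMesh(vertices, faces), scalars).validate()
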