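"""Core coordinate, mesh, landmark and optode types plus file readers/writers.

All coordinates are millimetres. Every positional container carries a frame
tag, either ``"photo"`` (the arbitrary frame of a photogrammetric
reconstruction) or ``"mni"`` (MNI152 space, x negative toward the left
hemisphere, y anterior-positive, z dorsal-positive). Operations that would
silently mix frames raise :class:`~optoreg.errors.FrameMismatchError`.

Supported mesh formats are triangular PLY (ASCII or binary little-endian)
and OBJ; quad faces are rejected rather than triangulated. Tabular data is
CSV with a required header, UTF-8, ``.`` decimal separator; lines starting
with ``#`` are treated as comments.
"""

from __future__ import annotations

import csv
import io
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, FrameMismatchError, ValidationError

#: The two coordinate frames the pipeline distinguishes.
PHOTO = "photo"
MNI = "mni"
FRAMES = (PHOTO, MNI)

#: Canonical fiducial landmark names (10-20 style); "lpa"/"rpa" are the left
#: and right preauricular points.
LANDMARK_NAMES = ("nasion", "inion", "cz", "lpa", "rpa")

OPTODE_ROLES = ("source", "detector")


def _check_frame(frame: str) -> str:
    f = str(frame).lower()
    if f not in FRAMES:
        raise ValidationError(f"unknown frame {frame!r}; expected one of {FRAMES}")
    return f


def check_same_frame(*objs) -> str:
    """Return the shared frame of ``objs`` or raise :class:`FrameMismatchError`."""
    frames = {o.frame for o in objs}
    if len(frames) > 1:
        raise FrameMismatchError(f"mixed coordinate frames: {sorted(frames)}")
    return frames.pop()


@dataclass(frozen=True)
class Point3:
    """A single position in millimetres within a named frame."""

    x: float
    y: float
    z: float
    frame: str = MNI

    def __post_init__(self):
        object.__setattr__(self, "frame", _check_frame(self.frame))
        for axis in (self.x, self.y, self.z):
            if not math.isfinite(axis):
                raise ValidationError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a, frame: str = MNI) -> "Point3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)

    def distance_to(self, other: "Point3") -> float:
        check_same_frame(self, other)
        return float(np.linalg.norm(self.as_array() - other.as_array()))


@dataclass
class PointTable:
    """An ordered table of identified points sharing one frame."""

    ids: list[str]
    coords: np.ndarray  # (n, 3) float64, millimetres
    frame: str = MNI

    def __post_init__(self):
        self.frame = _check_frame(self.frame)
        self.ids = [str(i) for i in self.ids]
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.shape != (len(self.ids), 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {len(self.ids)} ids"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates in point table")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate point ids: {dupes}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        for i, pid in enumerate(self.ids):
            yield pid, self.coords[i]

    def position(self, pid: str) -> np.ndarray:
        try:
            return self.coords[self.ids.index(str(pid))]
        except ValueError:
            raise KeyError(f"no point with id {pid!r}") from None

    def point(self, pid: str) -> Point3:
        return Point3.from_array(self.position(pid), self.frame)

    def subset(self, ids: Sequence[str]) -> "PointTable":
        idx = [self.ids.index(str(i)) for i in ids]
        return PointTable([self.ids[i] for i in idx], self.coords[idx], self.frame)

    def with_coords(self, coords: np.ndarray, frame: str | None = None) -> "PointTable":
        return PointTable(list(self.ids), coords, frame or self.frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids,
             "x": self.coords[:, 0],
             "y": self.coords[:, 1],
             "z": self.coords[:, 2]}
        )


@dataclass
class SurfaceMesh:
    """A triangulated surface (scalp or cortex) in one frame."""

    vertices: np.ndarray  # (n, 3) float64, millimetres
    faces: np.ndarray     # (m, 3) int64, vertex indices
    frame: str = MNI

    def __post_init__(self):
        self.frame = _check_frame(self.frame)
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("non-finite vertex coordinates")
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                bad = int(np.argmax((self.faces < 0) | (self.faces >= n)) // 3)
                raise ValidationError(
                    f"face {bad} references vertex index outside [0, {n})"
                )
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise ValidationError(
                    f"face {int(np.argmax(same))} repeats a vertex index"
                )
            areas = self.face_areas()
            if np.any(areas <= 0):
                raise ValidationError(
                    f"face {int(np.argmax(areas <= 0))} has zero area"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return cross / np.linalg.norm(cross, axis=1, keepdims=True)

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        tri = self.triangles()
        areas = self.face_areas()
        centers = tri.mean(axis=1)
        return (centers * areas[:, None]).sum(axis=0) / areas.sum()


@dataclass
class LandmarkSet:
    """The five fiducial landmarks anchoring the affine registration.

    Exactly nasion, inion, cz, lpa and rpa must be present and must not be
    coplanar (a coplanar set cannot constrain a 3-D affine fit).
    """

    points: dict[str, Point3] = field(default_factory=dict)

    def __post_init__(self):
        names = [n.lower() for n in self.points]
        pts = {n.lower(): p for n, p in self.points.items()}
        missing = [n for n in LANDMARK_NAMES if n not in names]
        if missing:
            raise ValidationError(f"missing landmark(s): {missing}")
        extra = [n for n in names if n not in LANDMARK_NAMES]
        if extra:
            raise ValidationError(f"unknown landmark name(s): {extra}")
        self.points = {n: pts[n] for n in LANDMARK_NAMES}
        check_same_frame(*self.points.values())
        if self.coplanar():
            raise ValidationError(
                "landmarks are coplanar; a 3-D affine fit is degenerate"
            )

    @property
    def frame(self) -> str:
        return next(iter(self.points.values())).frame

    def coords(self) -> np.ndarray:
        """(5, 3) array in canonical landmark order."""
        return np.array([self.points[n].as_array() for n in LANDMARK_NAMES])

    def coplanar(self, rtol: float = 1e-8) -> bool:
        c = self.coords()
        centered = c - c.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        return bool(s[2] <= rtol * max(s[0], 1.0))

    def to_point_table(self) -> PointTable:
        return PointTable(list(LANDMARK_NAMES), self.coords(), self.frame)

    @classmethod
    def from_arrays(cls, coords, frame: str = MNI) -> "LandmarkSet":
        coords = np.asarray(coords, dtype=float).reshape(5, 3)
        return cls({n: Point3.from_array(coords[i], frame)
                    for i, n in enumerate(LANDMARK_NAMES)})


@dataclass
class Optode:
    id: str
    role: str  # "source" | "detector"
    position: Point3

    def __post_init__(self):
        self.role = str(self.role).lower()
        if self.role not in OPTODE_ROLES:
            raise ValidationError(
                f"optode {self.id!r}: role {self.role!r} not in {OPTODE_ROLES}"
            )


@dataclass
class OptodeSet:
    """An ordered collection of sources and detectors in one frame."""

    optodes: list[Optode] = field(default_factory=list)

    def __post_init__(self):
        ids = [o.id for o in self.optodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate optode id(s): {dupes}")
        if self.optodes:
            check_same_frame(*(o.position for o in self.optodes))

    def __len__(self) -> int:
        return len(self.optodes)

    def __iter__(self):
        return iter(self.optodes)

    @property
    def frame(self) -> str:
        if not self.optodes:
            raise ValidationError("empty optode set has no frame")
        return self.optodes[0].position.frame

    def ids(self) -> list[str]:
        return [o.id for o in self.optodes]

    def sources(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "source"]

    def detectors(self) -> list[Optode]:
        return [o for o in self.optodes if o.role == "detector"]

    def to_point_table(self) -> PointTable:
        coords = np.array([o.position.as_array() for o in self.optodes]).reshape(-1, 3)
        return PointTable(self.ids(), coords, self.frame if self.optodes else MNI)

    def with_positions(self, table: PointTable) -> "OptodeSet":
        """Same ids/roles with positions taken from ``table``."""
        return OptodeSet([
            Optode(o.id, o.role, table.point(o.id)) for o in self.optodes
        ])

    @classmethod
    def from_arrays(cls, ids, roles, coords, frame: str = MNI) -> "OptodeSet":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        return cls([
            Optode(str(i), r, Point3.from_array(c, frame))
            for i, r, c in zip(ids, roles, coords, strict=True)
        ])


# ---------------------------------------------------------------------------
# Mesh I/O


def read_mesh(path, frame: str = MNI) -> SurfaceMesh:
    """Read a triangular PLY (ASCII/binary little-endian) or OBJ mesh.

    Vertex order is preserved. Non-triangular faces raise
    :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".ply":
        vertices, faces = _read_ply(path)
    elif suffix == ".obj":
        vertices, faces = _read_obj(path)
    else:
        raise FormatError(f"unsupported mesh format {suffix!r} (expected .ply/.obj)")
    try:
        return SurfaceMesh(vertices, faces, frame)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_mesh(mesh: SurfaceMesh, path) -> Path:
    """Write a mesh as ASCII PLY or OBJ depending on the file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        _write_ply(mesh, path)
    elif suffix == ".obj":
        _write_obj(mesh, path)
    else:
        raise FormatError(f"unsupported mesh format {suffix!r} (expected .ply/.obj)")
    return path


_PLY_TYPES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def _read_ply(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path}: not a PLY file")
        fmt = None
        elements = []  # (name, count, [(prop_name, type, list_count_type|None)])
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: unexpected end of PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise FormatError(f"{path}: property before element in header")
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[4], tokens[3], tokens[2]))
                else:
                    elements[-1][2].append((tokens[2], tokens[1], None))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise FormatError(f"{path}: unsupported PLY format {fmt!r}")
        if fmt == "ascii":
            data = _read_ply_ascii(fh, elements, path)
        else:
            data = _read_ply_binary(fh, elements, path)
    vertices = data.get("vertex")
    faces = data.get("face", [])
    if vertices is None:
        raise FormatError(f"{path}: PLY file has no vertex element")
    return np.asarray(vertices, dtype=float), np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _vertex_xyz(props, values, path, record):
    try:
        names = [p[0] for p in props]
        return [values[names.index(a)] for a in ("x", "y", "z")]
    except ValueError:
        raise FormatError(f"{path}: vertex element lacks x/y/z ({record})") from None


def _read_ply_ascii(fh, elements, path):
    out = {}
    text = io.TextIOWrapper(fh, encoding="ascii", errors="replace")
    for name, count, props in elements:
        rows = []
        for i in range(count):
            line = text.readline()
            if not line:
                raise FormatError(f"{path}: truncated PLY, {name} record {i}")
            tokens = line.split()
            if name == "vertex":
                rows.append(_vertex_xyz(props, [float(t) for t in tokens], path, i))
            elif name == "face":
                n = int(tokens[0])
                if n != 3:
                    raise FormatError(
                        f"{path}: face record {i} has {n} vertices; only triangles supported"
                    )
                rows.append([int(t) for t in tokens[1:4]])
            # other elements are skipped line-wise
        if name in ("vertex", "face"):
            out[name] = rows
    return out


def _read_ply_binary(fh, elements, path):
    out = {}
    for name, count, props in elements:
        rows = []
        for i in range(count):
            values = []
            for pname, ptype, list_count_type in props:
                if list_count_type is None:
                    code = _PLY_TYPES[ptype]
                    (v,) = struct.unpack("<" + code, fh.read(struct.calcsize(code)))
                    values.append(v)
                else:
                    ccode = _PLY_TYPES[list_count_type]
                    (n,) = struct.unpack("<" + ccode, fh.read(struct.calcsize(ccode)))
                    icode = _PLY_TYPES[ptype]
                    items = struct.unpack(
                        f"<{n}{icode}", fh.read(n * struct.calcsize(icode))
                    )
                    if name == "face" and n != 3:
                        raise FormatError(
                            f"{path}: face record {i} has {n} vertices; "
                            "only triangles supported"
                        )
                    values.append(list(items))
            if name == "vertex":
                rows.append(_vertex_xyz(props, values, path, i))
            elif name == "face":
                rows.append(values[0])
        if name in ("vertex", "face"):
            out[name] = rows
    return out


def _write_ply(mesh: SurfaceMesh, path: Path):
    with open(path, "w", encoding="ascii") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_obj(path: Path):
    vertices, faces = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if tokens[0] == "v":
                if len(tokens) < 4:
                    raise FormatError(f"{path}:{lineno}: malformed vertex line")
                vertices.append([float(t) for t in tokens[1:4]])
            elif tokens[0] == "f":
                refs = tokens[1:]
                if len(refs) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: face has {len(refs)} vertices; "
                        "only triangles supported"
                    )
                idx = []
                for r in refs:
                    i = int(r.split("/")[0])
                    # OBJ indices are 1-based; negatives count from the end
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                faces.append(idx)
    return np.asarray(vertices, dtype=float), np.asarray(faces, dtype=np.int64).reshape(-1, 3)


def _write_obj(mesh: SurfaceMesh, path: Path):
    with open(path, "w", encoding="utf-8") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Tabular I/O


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_landmarks(path, frame: str = PHOTO) -> LandmarkSet:
    """Read a landmark CSV with header ``name,x,y,z`` (case-insensitive names)."""
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, ("name", "x", "y", "z"), path)
    points: dict[str, Point3] = {}
    for _, row in df.iterrows():
        name = str(row["name"]).strip().lower()
        if name in points:
            raise ValidationError(f"{path}: duplicate landmark {name!r}")
        try:
            points[name] = Point3(float(row["x"]), float(row["y"]), float(row["z"]), frame)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric coordinate for {name!r}") from exc
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for name in LANDMARK_NAMES:
            p = landmarks.points[name]
            w.writerow([name, repr(p.x), repr(p.y), repr(p.z)])
    return path


def read_optodes(path, frame: str = PHOTO) -> OptodeSet:
    """Read an optode CSV with header ``id,role,x,y,z``; order is preserved."""
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, ("id", "role", "x", "y", "z"), path)
    optodes = []
    for i, row in df.iterrows():
        try:
            pos = Point3(float(row["x"]), float(row["y"]), float(row["z"]), frame)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric coordinate in row {i}") from exc
        optodes.append(Optode(str(row["id"]).strip(), str(row["role"]).strip(), pos))
    return OptodeSet(optodes)


def write_optodes(optodes: OptodeSet, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "role", "x", "y", "z"])
        for o in optodes:
            p = o.position
            w.writerow([o.id, o.role, repr(p.x), repr(p.y), repr(p.z)])
    return path


def read_points(path, frame: str = MNI) -> PointTable:
    """Read a generic point CSV with header ``id,x,y,z``."""
    df = _read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, ("id", "x", "y", "z"), path)
    ids = [str(i).strip() for i in df["id"]]
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return PointTable(ids, coords, frame)


def write_points(table: PointTable, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "z"])
        for pid, c in table:
            w.writerow([pid, repr(float(c[0])), repr(float(c[1])), repr(float(c[2]))])
    return path
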