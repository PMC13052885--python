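"""Readers and writers for the formats the pipeline touches.

Meshes travel as OFF (both common header dialects), point clouds as ASCII or
binary-little-endian PLY and plain-text XYZ, per-point part labels as
one-integer-per-line ``.seg`` files, and dataset manifests as JSON. Readers
validate their invariants and refuse malformed input rather than repairing
it silently; parse errors carry 1-based line numbers.

``sample_mesh_surface`` converts a triangle mesh to a point cloud by
area-weighted triangle selection followed by uniform barycentric sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import PointCloud

__all__ = [
    "Mesh", "ParseError", "DatasetManifest", "ManifestRecord",
    "read_off", "write_off", "sample_mesh_surface",
    "read_ply", "write_ply", "read_xyz", "write_xyz",
    "read_seg_labels", "write_seg_labels", "attach_labels",
    "read_manifest", "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class Mesh:
    """Triangle mesh: (V, 3) float vertices, (F, 3) integer faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be triangles (F, 3)")
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")

    def drop_degenerate_faces(self) -> "Mesh":
        areas = _triangle_areas(self.vertices, self.faces)
        return Mesh(self.vertices, self.faces[areas > 0.0])


# -- OFF ----------------------------------------------------------------------


def read_off(path) -> Mesh:
    """Read an OFF mesh, accepting both the two-line header dialect
    (``OFF`` then counts) and the counts-on-header-line dialect
    (``OFF 4 4 0``). Zero-area faces are filtered at load time."""
    lines = Path(path).read_text().splitlines()
    tokens: list[tuple[int, str]] = []   # (1-based line number, token)
    for i, line in enumerate(lines, start=1):
        body = line.split("#", 1)[0]
        tokens.extend((i, t) for t in body.split())
    if not tokens or not tokens[0][1].upper().startswith("OFF"):
        raise ParseError(f"{path}: line 1: missing OFF sentinel")
    first = tokens[0][1]
    pos = 1
    if first.upper() != "OFF":       # fused dialect like "OFF4" is not a thing;
        if first[:3].upper() != "OFF" or not first[3:].lstrip("-").isdigit():
            raise ParseError(f"{path}: line 1: unrecognized header {first!r}")
        tokens.insert(1, (tokens[0][0], first[3:]))  # e.g. "OFF4" -> counts
    def take(n, kind, what):
        nonlocal pos
        if pos + n > len(tokens):
            ln = tokens[-1][0]
            raise ParseError(f"{path}: line {ln}: unexpected end of file reading {what}")
        out = []
        for j in range(n):
            ln, tok = tokens[pos + j]
            try:
                out.append(kind(tok))
            except ValueError:
                raise ParseError(f"{path}: line {ln}: bad {what} token {tok!r}") from None
        pos += n
        return out
    n_v, n_f, _ = take(3, int, "counts")
    if n_v < 0 or n_f < 0:
        raise ParseError(f"{path}: line {tokens[1][0]}: negative counts")
    verts = np.array(take(3 * n_v, float, "vertex"), dtype=np.float64).reshape(n_v, 3)
    faces = []
    for _ in range(n_f):
        ln = tokens[pos][0]
        (nv,) = take(1, int, "face size")
        idx = take(nv, int, "face index")
        if nv != 3:
            raise ParseError(f"{path}: line {ln}: only triangular faces supported, got {nv}")
        if min(idx) < 0 or max(idx) >= n_v:
            raise ParseError(f"{path}: line {ln}: face index out of range [0, {n_v})")
        faces.append(idx)
    faces = np.array(faces, dtype=np.int64).reshape(n_f, 3)
    return Mesh(verts, faces).drop_degenerate_faces()


def write_off(mesh: Mesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def sample_mesh_surface(mesh: Mesh, n_points: int, seed: int) -> PointCloud:
    """Uniform surface sampling: triangles chosen with probability
    proportional to area, points placed by uniform barycentric coordinates.
    Deterministic given ``seed``; the result is not normalized."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    areas = _triangle_areas(mesh.vertices, mesh.faces)
    total = areas.sum()
    if total <= 0.0:
        raise ValueError("mesh has zero total surface area")
    rng = np.random.default_rng(seed)
    tri = rng.choice(len(areas), size=n_points, p=areas / total)
    u = rng.random(n_points)
    v = rng.random(n_points)
    flip = u + v > 1.0          # reflect into the lower barycentric triangle
    u[flip], v[flip] = 1.0 - u[flip], 1.0 - v[flip]
    a = mesh.vertices[mesh.faces[tri, 0]]
    b = mesh.vertices[mesh.faces[tri, 1]]
    c = mesh.vertices[mesh.faces[tri, 2]]
    pts = a + u[:, None] * (b - a) + v[:, None] * (c - a)
    return PointCloud(pts)


# -- PLY ----------------------------------------------------------------------


def write_ply(pc: PointCloud, path, binary: bool = False) -> None:
    """Write a point cloud as PLY; part labels (when present) are stored as a
    per-vertex integer property ``part``. ASCII keeps full float precision;
    binary uses 32-bit floats."""
    has_parts = pc.part_labels is not None
    n = len(pc)
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply", f"format {fmt} 1.0",
        f"element vertex {n}",
        "property double x" if not binary else "property float x",
        "property double y" if not binary else "property float y",
        "property double z" if not binary else "property float z",
    ]
    if has_parts:
        header.append("property int part")
    header.append("end_header")
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
            if has_parts:
                fields.append(("part", "<i4"))
            rec = np.empty(n, dtype=fields)
            rec["x"], rec["y"], rec["z"] = pc.coords.T.astype(np.float32)
            if has_parts:
                rec["part"] = pc.part_labels.astype(np.int32)
            fh.write(rec.tobytes())
        return
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in range(n):
            x, y, z = pc.coords[i]
            row = f"{float(x)!r} {float(y)!r} {float(z)!r}"
            if has_parts:
                row += f" {int(pc.part_labels[i])}"
            fh.write(row + "\n")


def read_ply(path) -> PointCloud:
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if end < 0:
        raise ParseError(f"{path}: missing end_header")
    header_lines = raw[:end].decode("ascii", errors="replace").splitlines()
    body_start = raw.index(b"\n", end) + 1
    fmt = None
    n = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for ln, line in enumerate(header_lines, start=1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            props.append((parts[1], parts[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
    if n is None:
        raise ParseError(f"{path}: no vertex element declared")
    names = [name for _, name in props]
    for axis in "xyz":
        if axis not in names:
            raise ParseError(f"{path}: vertex element lacks property {axis!r}")
    np_types = {"float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
                "int": "<i4", "int32": "<i4", "uchar": "u1", "uint8": "u1"}
    if fmt == "binary_little_endian":
        dtype = np.dtype([(name, np_types[t]) for t, name in props])
        rec = np.frombuffer(raw[body_start:body_start + dtype.itemsize * n],
                            dtype=dtype, count=n)
        cols = {name: rec[name] for _, name in props}
    else:
        rows = raw[body_start:].decode("ascii").split()
        want = n * len(props)
        if len(rows) < want:
            raise ParseError(f"{path}: expected {want} values, found {len(rows)}")
        arr = np.array(rows[:want], dtype=np.float64).reshape(n, len(props))
        cols = {name: arr[:, j] for j, (_, name) in enumerate(props)}
    coords = np.stack([cols["x"], cols["y"], cols["z"]], axis=1).astype(np.float64)
    labels = cols["part"].astype(np.int64) if "part" in cols else None
    return PointCloud(coords, labels)


# -- XYZ and .seg -------------------------------------------------------------


def write_xyz(pc: PointCloud, path) -> None:
    with open(path, "w") as fh:
        for x, y, z in pc.coords:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path) -> PointCloud:
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 3:
            raise ParseError(f"{path}: line {ln}: expected 3 coordinates, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise ParseError(f"{path}: line {ln}: non-numeric coordinate") from None
    return PointCloud(np.array(rows, dtype=np.float64).reshape(len(rows), 3))


def write_seg_labels(labels: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(labels, dtype=np.int64):
            fh.write(f"{v}\n")


def read_seg_labels(path, expected_n: int | None = None) -> np.ndarray:
    values = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tok = line.strip()
        if not tok:
            continue
        try:
            values.append(int(tok))
        except ValueError:
            raise ParseError(f"{path}: line {ln}: non-integer label {tok!r}") from None
    labels = np.array(values, dtype=np.int64)
    if expected_n is not None and len(labels) != expected_n:
        raise ValueError(
            f"{path}: label count {len(labels)} does not match cloud size {expected_n}")
    return labels


def attach_labels(pc: PointCloud, labels: np.ndarray) -> PointCloud:
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) != len(pc):
        raise ValueError(
            f"label count {len(labels)} does not match cloud size {len(pc)}")
    return PointCloud(pc.coords.copy(), labels, pc.category, pc.instance_id)


# -- manifest -----------------------------------------------------------------


@dataclass
class ManifestRecord:
    instance_id: str
    category: str
    split: str                       # "train" | "test"
    cloud_path: str
    label_path: str | None = None
    seed: int | None = None


@dataclass
class DatasetManifest:
    records: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.instance_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate instance_id in manifest")

    def split(self, which: str) -> list:
        return [r for r in self.records if r.split == which]


def write_manifest(manifest: DatasetManifest, path) -> None:
    payload = {
        "metadata": manifest.metadata,
        "records": [vars(r) for r in manifest.records],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path, check_files: bool = True) -> DatasetManifest:
    with open(path) as fh:
        payload = json.load(fh)
    records = [ManifestRecord(**r) for r in payload["records"]]
    manifest = DatasetManifest(records, payload.get("metadata", {}))
    if check_files:
        base = Path(path).parent
        for r in records:
            for p in (r.cloud_path, r.label_path):
                if p is not None and not (base / p).exists():
                    raise FileNotFoundError(
                        f"manifest references missing file {p!r} (instance {r.instance_id})")
    return manifest
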