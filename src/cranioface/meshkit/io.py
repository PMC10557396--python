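"""Mesh, landmark and label file I/O.

Supported mesh formats: OBJ (``v``/``f`` records, 1-based indices) and PLY
(ASCII and binary little-endian, ``vertex``/``face`` elements). Landmarks
travel as UTF-8 CSV with a ``name,x,y,z`` header; component labels as
``vertex_index,label`` CSV.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .mesh import MeshError, TriangleMesh


class ParseError(ValueError):
    """Raised when a mesh or table file cannot be parsed."""


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Read a PLY or OBJ triangle mesh; format inferred from suffix if omitted."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        return _read_obj(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ParseError(f"unsupported mesh format: {fmt!r}")


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None,
               binary: bool = False) -> None:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, binary=binary)
    else:
        raise ParseError(f"unsupported mesh format: {fmt!r}")


# -- OBJ -----------------------------------------------------------------


def _read_obj(path: Path) -> TriangleMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(p) for p in parts[1:4]])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad vertex coordinate") from exc
            elif tag == "f":
                if len(parts) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: only triangular faces are supported"
                    )
                try:
                    idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad face index") from exc
                faces.append(idx)
    if not vertices:
        raise ParseError(f"{path}: no vertices found")
    try:
        return TriangleMesh(np.array(vertices), np.array(faces, dtype=np.int64).reshape(-1, 3))
    except MeshError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# -- PLY -----------------------------------------------------------------

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "char": "<i1", "int8": "<i1", "uchar": "<u1", "uint8": "<u1",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def _read_ply(path: Path) -> TriangleMesh:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list]] = []  # (name, count, props)
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unexpected end of header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise ParseError(f"{path}: property before element")
                elements[-1][2].append(tokens[1:])
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        data = {}
        for name, count, props in elements:
            if fmt == "ascii":
                data[name] = _ply_read_ascii(fh, count, props, path)
            else:
                data[name] = _ply_read_binary(fh, count, props, path)
    if "vertex" not in data:
        raise ParseError(f"{path}: no vertex element")
    vx = data["vertex"]
    vertices = np.column_stack([vx["x"], vx["y"], vx["z"]])
    normals = None
    if "nx" in vx and "ny" in vx and "nz" in vx:
        normals = np.column_stack([vx["nx"], vx["ny"], vx["nz"]])
    faces = np.zeros((0, 3), dtype=np.int64)
    if "face" in data and len(data["face"]["__list__"]):
        rows = data["face"]["__list__"]
        if any(len(r) != 3 for r in rows):
            raise ParseError(f"{path}: non-triangular face encountered")
        faces = np.array(rows, dtype=np.int64)
    try:
        return TriangleMesh(vertices, faces, normals)
    except MeshError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _ply_read_ascii(fh, count, props, path):
    out: dict = {p[-1]: [] for p in props if p[0] != "list"}
    is_list = any(p[0] == "list" for p in props)
    if is_list:
        out["__list__"] = []
    for _ in range(count):
        tokens = fh.readline().split()
        if is_list:
            n = int(tokens[0])
            out["__list__"].append([int(t) for t in tokens[1 : 1 + n]])
        else:
            if len(tokens) < len(props):
                raise ParseError(f"{path}: short vertex row")
            for p, t in zip(props, tokens):
                out[p[-1]].append(float(t))
    return {k: (np.asarray(v) if k != "__list__" else v) for k, v in out.items()}


def _ply_read_binary(fh, count, props, path):
    if any(p[0] == "list" for p in props):
        if len(props) != 1:
            raise ParseError(f"{path}: mixed list/scalar properties unsupported")
        count_t = np.dtype(_PLY_DTYPES[props[0][1]])
        index_t = np.dtype(_PLY_DTYPES[props[0][2]])
        rows = []
        for _ in range(count):
            n = int(np.frombuffer(fh.read(count_t.itemsize), count_t)[0])
            rows.append(np.frombuffer(fh.read(index_t.itemsize * n), index_t).tolist())
        return {"__list__": rows}
    dtype = np.dtype([(p[-1], _PLY_DTYPES[p[0]]) for p in props])
    buf = fh.read(dtype.itemsize * count)
    if len(buf) != dtype.itemsize * count:
        raise ParseError(f"{path}: truncated binary payload")
    arr = np.frombuffer(buf, dtype)
    return {name: arr[name].astype(float) for name in arr.dtype.names}


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool = False) -> None:
    has_normals = mesh.normals is not None
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {mesh.n_vertices}")
    header += ["property double x", "property double y", "property double z"]
    if has_normals:
        header += ["property double nx", "property double ny", "property double nz"]
    header.append(f"element face {mesh.n_faces}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        cols = [mesh.vertices]
        if has_normals:
            cols.append(mesh.normals)
        vdata = np.column_stack(cols)
        if binary:
            fh.write(vdata.astype("<f8").tobytes())
            for f in mesh.faces:
                fh.write(np.uint8(3).tobytes())
                fh.write(f.astype("<i4").tobytes())
        else:
            for row in vdata:
                fh.write((" ".join(f"{x:.17g}" for x in row) + "\n").encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


# -- landmark and label tables -------------------------------------------


def read_points_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a ``name,x,y,z`` CSV, preserving row order."""
    path = Path(path)
    names: list[str] = []
    pts: list[list[float]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty landmark file") from None
        if [h.strip().lower() for h in header[:4]] != ["name", "x", "y", "z"]:
            raise ParseError(f"{path}: expected header name,x,y,z")
        for lineno, row in enumerate(reader, 2):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                pts.append([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate") from exc
            names.append(row[0].strip())
    if not names:
        raise ParseError(f"{path}: no landmark rows")
    return names, np.asarray(pts)


def write_points_csv(path: str | Path, names: list[str], points: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for name, p in zip(names, np.asarray(points)):
            writer.writerow([name, f"{p[0]:.9g}", f"{p[1]:.9g}", f"{p[2]:.9g}"])


def read_labels_csv(path: str | Path, n_vertices: int | None = None) -> np.ndarray:
    """Read ``vertex_index,label`` CSV into a per-vertex string array."""
    path = Path(path)
    pairs: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: empty label file")
        for lineno, row in enumerate(reader, 2):
            if not row or not "".join(row).strip():
                continue
            try:
                pairs.append((int(row[0]), row[1].strip()))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: bad label row") from exc
    n = n_vertices if n_vertices is not None else max(i for i, _ in pairs) + 1
    labels = np.array(["excluded"] * n, dtype=object)
    for i, lab in pairs:
        if i >= n:
            raise ParseError(f"{path}: vertex index {i} out of range")
        labels[i] = lab
    return labels


def write_labels_csv(path: str | Path, labels: np.ndarray) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["vertex_index", "label"])
        for i, lab in enumerate(labels):
            writer.writerow([i, lab])
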