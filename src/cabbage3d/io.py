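"""Reading and writing single-plant point clouds.

Supported on-disk formats:

* **PLY** — ascii and binary_little_endian, ``float``/``double`` coordinates,
  optional ``uchar`` colors named ``red/green/blue`` (``r/g/b`` accepted on
  read).  Written as binary little-endian by default.
* **PCD** — v0.7 ascii with fields ``x y z`` and optionally the PCL packed
  ``rgb`` float field.
* **XYZ** — plain text, whitespace or comma separated, 3 (coordinates) or 6
  (coordinates + RGB) columns, ``#`` comments skipped.  Colors may be 0–255
  integers or [0, 1] floats on disk.

Colors are always [0, 1] floats in memory.  Reading is strictly
order-preserving — point *i* on disk is row *i* of ``coords`` — and no
cleaning, deduplication or reordering ever happens at read time.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .cloud import PointCloud
from .errors import PointCloudParseError, ValidationError

__all__ = ["read_pointcloud", "write_pointcloud"]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}
_COLOR_ALIASES = {"red": "red", "green": "green", "blue": "blue",
                  "r": "red", "g": "green", "b": "blue"}


def _detect_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("ply", "pcd", "xyz"):
        return ext
    if ext in ("txt", "csv", "asc", "pts"):
        return "xyz"
    # header sniffing
    with open(path, "rb") as fh:
        head = fh.read(256)
    if head.startswith(b"ply"):
        return "ply"
    if b"VERSION" in head and b"FIELDS" in head:
        return "pcd"
    return "xyz"


def read_pointcloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud from ``path``.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"auto", "ply", "pcd", "xyz"}
        ``"auto"`` resolves by extension, then by header sniffing.

    Returns
    -------
    PointCloud
        Validated cloud; colors, when present on disk, rescaled to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such point-cloud file: {path}")
    if format == "auto":
        format = _detect_format(path)
    if format == "ply":
        coords, colors = _read_ply(path)
    elif format == "pcd":
        coords, colors = _read_pcd(path)
    elif format == "xyz":
        coords, colors = _read_xyz(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if coords.shape[0] == 0:
        raise ValidationError(f"{path}: file contains zero points")
    try:
        return PointCloud(coords, colors, source=str(path))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_pointcloud(pc: PointCloud, path, format: str = "auto",
                     binary: bool = True) -> None:
    """Write ``pc`` to ``path``.

    PLY is binary little-endian unless ``binary=False``; colors are encoded as
    0–255 ``uchar`` (PLY), packed ``rgb`` float (PCD) or 0–255 integers (XYZ).
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format_for_write(path)
    if format == "ply":
        _write_ply(pc, path, binary=binary)
    elif format == "pcd":
        _write_pcd(pc, path)
    elif format == "xyz":
        _write_xyz(pc, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _detect_format_for_write(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("ply", "pcd"):
        return ext
    return "xyz" if ext else "ply"


# ---------------------------------------------------------------------------
# PLY

def _read_ply(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.strip().startswith(b"ply"):
            raise PointCloudParseError(f"{path}: not a PLY file (bad magic line 1)")
        fmt = None
        elements = []  # list of (name, count, [(prop_name, dtype_or_list)])
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise PointCloudParseError(f"{path}: unexpected EOF in header at line {lineno}")
            line = raw.decode("ascii", errors="replace").strip()
            if not line or line.startswith("comment") or line.startswith("obj_info"):
                continue
            tok = line.split()
            if tok[0] == "format":
                if tok[1] not in ("ascii", "binary_little_endian"):
                    raise PointCloudParseError(
                        f"{path}: unsupported PLY format {tok[1]!r} (line {lineno})")
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if not elements:
                    raise PointCloudParseError(
                        f"{path}: property before element (line {lineno})")
                if tok[1] == "list":
                    elements[-1][2].append((tok[4], ("list", _PLY_DTYPES[tok[2]],
                                                     _PLY_DTYPES[tok[3]])))
                else:
                    if tok[1] not in _PLY_DTYPES:
                        raise PointCloudParseError(
                            f"{path}: unknown property type {tok[1]!r} (line {lineno})")
                    elements[-1][2].append((tok[2], _PLY_DTYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
            elif tok[0] == "ply":
                continue
            else:
                raise PointCloudParseError(
                    f"{path}: unrecognized header keyword {tok[0]!r} (line {lineno})")
        if fmt is None:
            raise PointCloudParseError(f"{path}: PLY header has no format line")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise PointCloudParseError(f"{path}: PLY file has no vertex element")
        if elements.index(vertex) != 0:
            raise PointCloudParseError(
                f"{path}: vertex element must come first")
        name, count, props = vertex
        if any(isinstance(d, tuple) for _, d in props):
            raise PointCloudParseError(f"{path}: list properties on vertices unsupported")
        names = [p for p, _ in props]
        if fmt == "ascii":
            rows = []
            for i in range(count):
                raw = fh.readline()
                lineno += 1
                vals = raw.split()
                if len(vals) < len(props):
                    raise PointCloudParseError(
                        f"{path}: line {lineno}: expected {len(props)} values, "
                        f"got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals[: len(props)]])
                except ValueError:
                    raise PointCloudParseError(
                        f"{path}: line {lineno}: non-numeric vertex value") from None
            data = {p: np.array([r[j] for r in rows]) for j, (p, _) in enumerate(props)}
            scale = {p: (255.0 if d == "u1" else 1.0) for p, d in props}
        else:
            dtype = np.dtype([(p, "<" + d) for p, d in props])
            buf = fh.read(dtype.itemsize * count)
            if len(buf) < dtype.itemsize * count:
                raise PointCloudParseError(
                    f"{path}: truncated binary vertex data at byte {len(buf)}")
            arr = np.frombuffer(buf, dtype=dtype, count=count)
            data = {p: arr[p].astype(np.float64) for p in names}
            scale = {p: (255.0 if d == "u1" else 1.0) for p, d in props}
    lower = {p.lower(): p for p in names}
    for ax in ("x", "y", "z"):
        if ax not in lower:
            raise PointCloudParseError(f"{path}: vertex element lacks property {ax!r}")
    coords = np.column_stack([data[lower["x"]], data[lower["y"]], data[lower["z"]]])
    colors = None
    color_props = {}
    for p in names:
        canon = _COLOR_ALIASES.get(p.lower())
        if canon:
            color_props[canon] = p
    if {"red", "green", "blue"} <= set(color_props):
        cols = []
        for canon in ("red", "green", "blue"):
            p = color_props[canon]
            cols.append(data[p] / scale[p])
        colors = np.column_stack(cols)
    return coords, colors


def _write_ply(pc: PointCloud, path: Path, binary: bool = True) -> None:
    n = pc.n_points
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += ["property double x", "property double y", "property double z"]
    if pc.has_colors:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")
    rgb = None
    if pc.has_colors:
        rgb = np.clip(np.rint(pc.colors * 255.0), 0, 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            if pc.has_colors:
                dtype = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                                  ("red", "u1"), ("green", "u1"), ("blue", "u1")])
                arr = np.empty(n, dtype=dtype)
                arr["x"], arr["y"], arr["z"] = pc.coords.T
                arr["red"], arr["green"], arr["blue"] = rgb.T
            else:
                dtype = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8")])
                arr = np.empty(n, dtype=dtype)
                arr["x"], arr["y"], arr["z"] = pc.coords.T
            fh.write(arr.tobytes())
        else:
            for i in range(n):
                x, y, z = (float(v) for v in pc.coords[i])
                line = f"{x!r} {y!r} {z!r}"
                if pc.has_colors:
                    line += " {} {} {}".format(*rgb[i])
                fh.write((line + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# PCD (v0.7 ascii)

def _read_pcd(path: Path):
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        header = {}
        lineno = 0
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise PointCloudParseError(f"{path}: unexpected EOF in PCD header")
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(" ")
            header[key.upper()] = rest.split()
            if key.upper() == "DATA":
                break
        if header["DATA"][0] != "ascii":
            raise PointCloudParseError(
                f"{path}: only DATA ascii PCD files are supported")
        fields = [f.lower() for f in header.get("FIELDS", [])]
        for ax in ("x", "y", "z"):
            if ax not in fields:
                raise PointCloudParseError(f"{path}: PCD FIELDS lacks {ax!r}")
        try:
            n = int(header["POINTS"][0])
        except (KeyError, ValueError):
            raise PointCloudParseError(f"{path}: PCD header lacks POINTS count") from None
        rows = np.empty((n, len(fields)), dtype=np.float64)
        for i in range(n):
            line = fh.readline()
            lineno += 1
            vals = line.split()
            if len(vals) != len(fields):
                raise PointCloudParseError(
                    f"{path}: line {lineno}: expected {len(fields)} values, got {len(vals)}")
            try:
                rows[i] = [float(v) for v in vals]
            except ValueError:
                raise PointCloudParseError(
                    f"{path}: line {lineno}: non-numeric value") from None
    ix = [fields.index(a) for a in ("x", "y", "z")]
    coords = rows[:, ix]
    colors = None
    if "rgb" in fields:
        packed = rows[:, fields.index("rgb")].astype(np.float32)
        as_int = packed.view(np.uint32)
        r = (as_int >> 16) & 0xFF
        g = (as_int >> 8) & 0xFF
        b = as_int & 0xFF
        colors = np.column_stack([r, g, b]).astype(np.float64) / 255.0
    return coords, colors


def _write_pcd(pc: PointCloud, path: Path) -> None:
    n = pc.n_points
    has_c = pc.has_colors
    fields = "x y z rgb" if has_c else "x y z"
    sizes = "4 4 4 4" if has_c else "4 4 4"
    types = "F F F F" if has_c else "F F F"
    counts = "1 1 1 1" if has_c else "1 1 1"
    lines = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        f"FIELDS {fields}",
        f"SIZE {sizes}",
        f"TYPE {types}",
        f"COUNT {counts}",
        f"WIDTH {n}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}",
        "DATA ascii",
    ]
    if has_c:
        rgb255 = np.clip(np.rint(pc.colors * 255.0), 0, 255).astype(np.uint32)
        packed = ((rgb255[:, 0] << 16) | (rgb255[:, 1] << 8) | rgb255[:, 2]).astype(np.uint32)
        packed_f = packed.view(np.float32)
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(n):
            x, y, z = pc.coords[i]
            if has_c:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {packed_f[i]:.9g}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# XYZ / CSV text

def _read_xyz(path: Path):
    coords_rows: list[list[float]] = []
    color_rows: list[list[float]] = []
    ncols = None
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            vals = re.split(r"[,\s]+", text)
            if ncols is None:
                if len(vals) not in (3, 6):
                    raise PointCloudParseError(
                        f"{path}: line {lineno}: expected 3 or 6 columns, got {len(vals)}")
                ncols = len(vals)
            elif len(vals) != ncols:
                raise PointCloudParseError(
                    f"{path}: line {lineno}: expected {ncols} columns, got {len(vals)}")
            try:
                nums = [float(v) for v in vals]
            except ValueError:
                bad = next(v for v in vals if not _is_number(v))
                raise PointCloudParseError(
                    f"{path}: line {lineno}: non-numeric token {bad!r}") from None
            coords_rows.append(nums[:3])
            if ncols == 6:
                color_rows.append(nums[3:])
    coords = np.array(coords_rows, dtype=np.float64).reshape(-1, 3)
    colors = None
    if color_rows:
        colors = np.array(color_rows, dtype=np.float64)
        if colors.max(initial=0.0) > 1.0:  # 0-255 on disk
            colors = colors / 255.0
    return coords, colors


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _write_xyz(pc: PointCloud, path: Path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        if pc.has_colors:
            rgb = np.clip(np.rint(pc.colors * 255.0), 0, 255).astype(int)
            for (x, y, z), (r, g, b) in zip(pc.coords.tolist(), rgb):
                fh.write(f"{x!r} {y!r} {z!r} {r} {g} {b}\n")
        else:
            for x, y, z in pc.coords.tolist():
                fh.write(f"{x!r} {y!r} {z!r}\n")
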