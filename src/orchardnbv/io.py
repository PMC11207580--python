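"""Readers and writers for the on-disk formats.

PLY point clouds (ascii and binary_little_endian read; binary written) with
x, y, z float properties, optional uchar red/green/blue, optional float
intensity; JSON for cameras, poses, Gaussian fields, detections, maps and
planner results; SUN-RGBD-style text labels (one box per line:
class-name cx cy cz l w h heading, axis-aligned so heading is 0.0).
All JSON is written with sorted keys and a trailing newline so identical
inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .fusion import CLASS_IDS, CLASS_NAMES, Box3D
from .geometry import CameraModel, ColoredPointCloud, RigidTransform

PathLike = Union[str, Path]

_PLY_TYPES = {
    "float": ("<f4", float), "float32": ("<f4", float),
    "double": ("<f8", float), "float64": ("<f8", float),
    "uchar": ("<u1", int), "uint8": ("<u1", int),
    "char": ("<i1", int), "int8": ("<i1", int),
    "ushort": ("<u2", int), "uint16": ("<u2", int),
    "short": ("<i2", int), "int16": ("<i2", int),
    "uint": ("<u4", int), "uint32": ("<u4", int),
    "int": ("<i4", int), "int32": ("<i4", int),
}


class PlyParseError(ValueError):
    pass


def _parse_ply_header(data: bytes, path: str):
    end = data.find(b"end_header\n")
    if not data.startswith(b"ply") or end < 0:
        raise PlyParseError(f"{path}: not a PLY file (missing header)")
    header = data[: end + len(b"end_header\n")]
    body = data[len(header):]
    fmt = None
    count = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for lineno, raw in enumerate(header.decode("ascii", "replace").splitlines(), 1):
        tok = raw.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            if tok[1] == "vertex":
                in_vertex = True
                count = int(tok[2])
            else:
                if in_vertex and props:
                    raise PlyParseError(
                        f"{path}: line {lineno}: only a single 'vertex' element "
                        f"is supported, found element '{tok[1]}'"
                    )
                in_vertex = False
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise PlyParseError(f"{path}: line {lineno}: list properties unsupported")
            if tok[1] not in _PLY_TYPES:
                raise PlyParseError(
                    f"{path}: line {lineno}: unknown property type '{tok[1]}'"
                )
            props.append((tok[2], tok[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise PlyParseError(f"{path}: unsupported format '{fmt}'")
    if count is None:
        raise PlyParseError(f"{path}: no vertex element declared")
    for need in ("x", "y", "z"):
        if need not in [n for n, _ in props]:
            raise PlyParseError(f"{path}: vertex element lacks property '{need}'")
    return fmt, count, props, body


def read_ply(path: PathLike) -> ColoredPointCloud:
    """Read an ascii or binary_little_endian PLY point cloud."""
    path = Path(path)
    data = path.read_bytes()
    fmt, count, props, body = _parse_ply_header(data, str(path))
    names = [n for n, _ in props]
    if fmt == "ascii":
        rows = body.decode("ascii", "replace").split()
        expected = count * len(props)
        if len(rows) < expected:
            raise PlyParseError(
                f"{path}: truncated ascii body: expected {count} vertices "
                f"({expected} values), found {len(rows) // len(props)}"
            )
        arr = np.array(rows[:expected], dtype=float).reshape(count, len(props))
        cols = {n: arr[:, i] for i, (n, _) in enumerate(props)}
    else:
        dtype = np.dtype([(n, _PLY_TYPES[t][0]) for n, t in props])
        expected = count * dtype.itemsize
        if len(body) < expected:
            raise PlyParseError(
                f"{path}: truncated binary body: expected {count} vertices "
                f"({expected} bytes), found {len(body)} bytes"
            )
        rec = np.frombuffer(body[:expected], dtype=dtype)
        cols = {n: rec[n].astype(float) for n in names}

    positions = np.column_stack([cols["x"], cols["y"], cols["z"]])
    colors = None
    if all(k in cols for k in ("red", "green", "blue")):
        colors = np.column_stack(
            [cols["red"], cols["green"], cols["blue"]]
        ).astype(np.uint8)
    intensity = cols.get("intensity")
    return ColoredPointCloud(positions, colors=colors, intensity=intensity)


def write_ply(path: PathLike, cloud: ColoredPointCloud, binary: bool = True) -> None:
    """Write a point cloud as PLY (binary_little_endian by default)."""
    path = Path(path)
    n = len(cloud)
    fields = [("x", "float"), ("y", "float"), ("z", "float")]
    if cloud.colors is not None:
        fields += [("red", "uchar"), ("green", "uchar"), ("blue", "uchar")]
    if cloud.intensity is not None:
        fields += [("intensity", "float")]
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {n}"]
    header += [f"property {t} {name}" for name, t in fields]
    header.append("end_header")

    dtype = np.dtype([(name, _PLY_TYPES[t][0]) for name, t in fields])
    rec = np.empty(n, dtype=dtype)
    pos32 = cloud.positions.astype("<f4")
    rec["x"], rec["y"], rec["z"] = pos32[:, 0], pos32[:, 1], pos32[:, 2]
    if cloud.colors is not None:
        rec["red"] = cloud.colors[:, 0]
        rec["green"] = cloud.colors[:, 1]
        rec["blue"] = cloud.colors[:, 2]
    if cloud.intensity is not None:
        rec["intensity"] = cloud.intensity.astype("<f4")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for row in rec:
                vals = []
                for name, t in fields:
                    v = row[name]
                    vals.append(str(int(v)) if t == "uchar" else f"{float(v):.8g}")
                fh.write((" ".join(vals) + "\n").encode("ascii"))


def write_sunrgbd_labels(boxes: Sequence[Box3D], path: PathLike) -> None:
    """One line per box: class-name cx cy cz l w h heading (heading 0.0)."""
    lines = []
    for b in boxes:
        name = CLASS_NAMES.get(b.class_id, f"class{b.class_id}")
        l, h, w = b.extents
        x, y, z = b.center
        vals = " ".join(str(float(v)) for v in (x, y, z, l, w, h))
        lines.append(f"{name} {vals} 0.0")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_sunrgbd_labels(path: PathLike) -> list:
    """Read boxes written by :func:`write_sunrgbd_labels` (confidence 1)."""
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        tok = line.split()
        if not tok:
            continue
        if len(tok) != 8:
            raise ValueError(f"{path}: line {lineno}: expected 8 fields, got {len(tok)}")
        name = tok[0]
        x, y, z, l, w, h, _heading = map(float, tok[1:])
        class_id = CLASS_IDS.get(name, 0)
        boxes.append(Box3D((x, y, z), (l, h, w), 1.0, class_id=class_id))
    return boxes


def dump_json(path: PathLike, obj: dict, meta: Optional[dict] = None) -> None:
    """Write canonical JSON (sorted keys, newline); optional meta block."""
    if meta:
        obj = dict(obj, meta=meta)
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def load_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config_dict: dict) -> str:
    """Deterministic sha256 of a canonical-JSON-encoded configuration."""
    payload = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_detections(path: PathLike, boxes: Sequence[Box3D],
                    view_id: int = 0, meta: Optional[dict] = None) -> None:
    dump_json(
        path,
        {"detections": [dict(b.to_dict(), view_id=view_id) for b in boxes]},
        meta,
    )


def load_detections(path: PathLike) -> list:
    return [Box3D.from_dict(d) for d in load_json(path)["detections"]]


def save_camera(path: PathLike, cam: CameraModel, pose: Optional[RigidTransform] = None,
                meta: Optional[dict] = None) -> None:
    obj = {"intrinsics": cam.to_dict()}
    if pose is not None:
        obj["pose"] = pose.to_dict()
    dump_json(path, obj, meta)


def load_camera(path: PathLike):
    d = load_json(path)
    cam = CameraModel.from_dict(d["intrinsics"])
    pose = RigidTransform.from_dict(d["pose"]) if "pose" in d else None
    return cam, pose
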