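"""Point-cloud and table I/O.

Clouds are stored as PLY (ascii or binary_little_endian) with float vertex
properties ``x, y, z`` in metres and an optional integer ``label`` property
carrying the per-point ground-truth class of synthetic scenes, or as bare
3-column XYZ text.  Rigid transforms are serialized as row-major JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import RigidTransform

__all__ = [
    "write_ply",
    "read_ply",
    "write_xyz",
    "read_xyz",
    "write_transforms_json",
    "read_transforms_json",
    "write_json",
    "read_herd_csv",
    "write_herd_csv",
]


def write_ply(
    path: str | Path,
    points: np.ndarray,
    labels: np.ndarray | None = None,
    binary: bool = False,
) -> None:
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise InvalidParameterError(f"points must be (n, 3), got {points.shape}")
    n = len(points)
    if labels is not None:
        labels = np.asarray(labels, dtype=np.int32)
        if labels.shape != (n,):
            raise InvalidParameterError("labels must be one integer per point")
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if labels is not None:
        header.append("property int label")
    header.append("end_header")
    path = Path(path)
    if binary:
        if labels is not None:
            dt = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "<i4")])
            rec = np.empty(n, dtype=dt)
            rec["x"], rec["y"], rec["z"] = points.T
            rec["label"] = labels
        else:
            dt = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8")])
            rec = np.empty(n, dtype=dt)
            rec["x"], rec["y"], rec["z"] = points.T
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for i in range(n):
                row = f"{points[i, 0]:.9g} {points[i, 1]:.9g} {points[i, 2]:.9g}"
                if labels is not None:
                    row += f" {int(labels[i])}"
                fh.write(row + "\n")


_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
    "short": "<i2", "ushort": "<u2", "char": "<i1", "uchar": "<u1",
    "int8": "<i1", "uint8": "<u1", "int16": "<i2", "uint16": "<u2",
}


def read_ply(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a PLY vertex cloud. Returns ``(points, labels_or_None)``."""
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"end_header")
    if end < 0:
        raise InvalidParameterError(f"{path}: not a PLY file (no end_header)")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end:]
    body = body[body.find(b"\n") + 1 :]

    fmt = None
    n = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append((tok[2], tok[1]))
    if fmt is None or n is None:
        raise InvalidParameterError(f"{path}: malformed PLY header")
    names = [p[0] for p in props]
    if not {"x", "y", "z"} <= set(names):
        raise InvalidParameterError(f"{path}: vertex element lacks x/y/z")

    if fmt == "ascii":
        data = np.loadtxt(
            [ln for ln in body.decode("ascii").splitlines() if ln.strip()][:n],
            dtype=float, ndmin=2,
        )
        cols = {name: data[:, i] for i, (name, _) in enumerate(props)}
    elif fmt == "binary_little_endian":
        dt = np.dtype([(name, _PLY_TYPES[typ]) for name, typ in props])
        rec = np.frombuffer(body, dtype=dt, count=n)
        cols = {name: rec[name] for name, _ in props}
    else:
        raise InvalidParameterError(f"{path}: unsupported PLY format {fmt!r}")

    points = np.column_stack([cols["x"], cols["y"], cols["z"]]).astype(float)
    labels = cols["label"].astype(int) if "label" in cols else None
    return points, labels


def write_xyz(path: str | Path, points: np.ndarray) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.9g")


def read_xyz(path: str | Path) -> np.ndarray:
    pts = np.loadtxt(path, dtype=float, ndmin=2)
    if pts.shape[1] != 3:
        raise InvalidParameterError(f"{path}: expected 3 columns, got {pts.shape[1]}")
    return pts


def write_transforms_json(path: str | Path, transforms: list[RigidTransform]) -> None:
    write_json(path, {"transforms": [t.to_dict() for t in transforms]})


def read_transforms_json(path: str | Path) -> list[RigidTransform]:
    with open(path) as fh:
        d = json.load(fh)
    return [RigidTransform.from_dict(t) for t in d["transforms"]]


def write_json(path: str | Path, obj: dict) -> None:
    """Deterministic JSON dump (sorted keys, newline-terminated)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


_HERD_COLUMNS = [
    "breed", "gender", "determination_date", "birth_date",
    "chest", "abdominal", "waist", "length", "height", "weight",
]


def _canon(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


def read_herd_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw herd table; header names may use spaces or underscores."""
    df = pd.read_csv(path)
    df.columns = [_canon(c) for c in df.columns]
    missing = [c for c in _HERD_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    return df[_HERD_COLUMNS]


def write_herd_csv(path: str | Path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)
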