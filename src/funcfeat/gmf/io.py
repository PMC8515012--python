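"""Mesh and model I/O.

PLY support covers vertex clouds only (no face elements): ASCII and
binary little-endian, float32 ``x``/``y``/``z`` properties. Fitted
models are serialized as a directory of ``.npy`` arrays plus a JSON
metadata file recording shapes, column names, the component scaling
convention and a format version.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np

from .design import DesignCoding
from .model import GMFModel

__all__ = ["write_ply", "read_ply", "save_gmf", "load_gmf"]

FORMAT_VERSION = 1


def write_ply(path, vertices: np.ndarray, binary: bool = False) -> None:
    """Write a (V, 3) or flat (3V,) vertex cloud as a PLY file."""
    v = np.asarray(vertices, dtype=np.float32)
    if v.ndim == 1:
        v = v.reshape(-1, 3)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("vertices must be (V, 3) or flat (3V,)")
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {v.shape[0]}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "end_header\n"
    )
    path = Path(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(v.astype("<f4").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for x, y, z in v:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


def read_ply(path) -> np.ndarray:
    """Read a vertex cloud written by :func:`write_ply`; returns (V, 3)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"end_header\n")
    if end < 0:
        raise ValueError(f"{path}: not a PLY file (missing end_header)")
    header = raw[:end].decode("ascii").splitlines()
    body = raw[end + len(b"end_header\n"):]
    if not header or header[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    fmt = None
    n_vertex = None
    props = []
    for line in header[1:]:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element" and parts[1] == "vertex":
            n_vertex = int(parts[2])
        elif parts[0] == "property":
            props.append(parts[2])
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
    if n_vertex is None or props[:3] != ["x", "y", "z"]:
        raise ValueError(f"{path}: expected a vertex element with x/y/z properties")
    if fmt == "ascii":
        vals = np.array(body.decode("ascii").split(), dtype=float)
        v = vals.reshape(n_vertex, len(props))[:, :3]
    else:
        itemsize = struct.calcsize("<" + "f" * len(props))
        v = np.frombuffer(body[: n_vertex * itemsize], dtype="<f4").reshape(n_vertex, len(props))[:, :3]
    return np.asarray(v, dtype=float)


def save_gmf(model: GMFModel, directory) -> None:
    """Serialize a fitted model to ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    arrays = {
        "A_shape": model.A_shape,
        "U_shape": model.U_shape,
        "s_shape": model.s_shape,
        "V_shape": model.V_shape,
    }
    if model.has_texture:
        arrays.update(A_tex=model.A_tex, U_tex=model.U_tex, s_tex=model.s_tex, V_tex=model.V_tex)
    for name, arr in arrays.items():
        np.save(d / f"{name}.npy", arr)
    meta = {
        "format_version": FORMAT_VERSION,
        "n_exemplars": model.n_exemplars,
        "component_scaling": "unit-variance (s / sqrt(N - 1))",
        "column_names": model.coding.column_names,
        "arrays": {name: list(arr.shape) for name, arr in arrays.items()},
        "coding": {
            "has_sex": model.coding.has_sex,
            "has_age": model.coding.has_age,
            "sex_levels": list(model.coding.sex_levels),
            "age_center": model.coding.age_center,
            "ethnicity_levels": list(model.coding.ethnicity_levels),
            "interactions": model.coding.interactions,
        },
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))


def load_gmf(directory) -> GMFModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    if meta["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta['format_version']}")
    c = meta["coding"]
    coding = DesignCoding(
        has_sex=c["has_sex"],
        has_age=c["has_age"],
        sex_levels=tuple(c["sex_levels"]),
        age_center=c["age_center"],
        ethnicity_levels=tuple(c["ethnicity_levels"]),
        interactions=c["interactions"],
    )
    arr = {name: np.load(d / f"{name}.npy") for name in meta["arrays"]}
    return GMFModel(
        coding=coding,
        A_shape=arr["A_shape"],
        U_shape=arr["U_shape"],
        s_shape=arr["s_shape"],
        V_shape=arr["V_shape"],
        n_exemplars=meta["n_exemplars"],
        A_tex=arr.get("A_tex"),
        U_tex=arr.get("U_tex"),
        s_tex=arr.get("s_tex"),
        V_tex=arr.get("V_tex"),
    )
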