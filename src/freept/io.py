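"""Point-set and landmark file I/O.

Formats are deliberately plain: whitespace-delimited XYZ text (``#``
comments allowed), ascii PLY with x/y/z vertex properties, and a landmark
CSV with columns ``pair_id, side, x, y, z`` (side in {source, target}).
Voxel masks are converted to volumetric point-sets by grid sampling: one
point per foreground voxel, at the voxel center.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import pandas as pd

from .pointset import LandmarkSet, PointSet, VoxelMask

__all__ = ["read_pointset", "write_pointset", "grid_sample_mask",
           "read_landmarks", "write_landmarks"]


class FormatError(ValueError):
    pass


def _read_xyz(path: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric field") from None
    if not rows:
        raise FormatError(f"{path}: no points found")
    return np.array(rows)


def _read_ply(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        header, lineno = [], 0
        while True:
            line = fh.readline().decode("ascii", errors="replace").strip()
            lineno += 1
            header.append(line)
            if line == "end_header":
                break
            if lineno > 200:
                raise FormatError(f"{path}: PLY header not terminated")
        if not header or header[0] != "ply":
            raise FormatError(f"{path}: not a PLY file")
        fmt = next((h.split()[1] for h in header if h.startswith("format ")), None)
        if fmt != "ascii":
            raise FormatError(f"{path}: only ascii PLY is supported, got {fmt!r}")
        n_vertex, props, in_vertex = None, [], False
        for h in header:
            if h.startswith("element "):
                _, name, cnt = h.split()[:3]
                in_vertex = name == "vertex"
                if in_vertex:
                    n_vertex = int(cnt)
            elif h.startswith("property ") and in_vertex:
                props.append(h.split()[-1])
        if n_vertex is None:
            raise FormatError(f"{path}: PLY has no vertex element")
        try:
            ix, iy, iz = props.index("x"), props.index("y"), props.index("z")
        except ValueError:
            raise FormatError(f"{path}: vertex element lacks x/y/z properties") from None
        rows = []
        for i in range(n_vertex):
            parts = fh.readline().decode("ascii").split()
            if len(parts) < len(props):
                raise FormatError(f"{path}: vertex line {i + 1}: too few fields")
            rows.append([float(parts[ix]), float(parts[iy]), float(parts[iz])])
    if not rows:
        raise FormatError(f"{path}: PLY contains no vertices")
    return np.array(rows)


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    return "ply" if ext == ".ply" else "xyz"


def read_pointset(path: str, format: str | None = None,
                  id: str | None = None, space_tag: str = "mm") -> PointSet:
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        coords = _read_xyz(path)
    elif fmt == "ply":
        coords = _read_ply(path)
    else:
        raise ValueError(f"unknown point-set format {fmt!r}")
    name = id if id is not None else os.path.splitext(os.path.basename(path))[0]
    return PointSet(coords, id=name, space_tag=space_tag)


def write_pointset(ps: PointSet, path: str, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        with open(path, "w") as fh:
            for x, y, z in ps.coords:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(ps)}\n")
            fh.write("property float64 x\nproperty float64 y\nproperty float64 z\n")
            fh.write("end_header\n")
            for x, y, z in ps.coords:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
    else:
        raise ValueError(f"unknown point-set format {fmt!r}")


def grid_sample_mask(mask: VoxelMask, id: str = "") -> PointSet:
    """One point per foreground voxel, at the voxel center (mm).

    This turns a volumetric segmentation into the grid-like point-set the
    registration pipeline consumes.
    """
    idx = np.argwhere(mask.grid)
    if idx.shape[0] == 0:
        raise ValueError("mask has no foreground voxels")
    coords = mask.origin[None, :] + idx.astype(np.float64) * mask.spacing
    return PointSet(coords, id=id, space_tag="mm")


def read_landmarks(path: str) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"pair_id", "side", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: landmark CSV needs columns {sorted(required)}")
    pairs = []
    for pair_id, grp in df.groupby("pair_id", sort=False):
        src = grp[grp["side"] == "source"][["x", "y", "z"]].to_numpy(float)
        tgt = grp[grp["side"] == "target"][["x", "y", "z"]].to_numpy(float)
        if src.size == 0 or tgt.size == 0:
            raise FormatError(f"{path}: pair {pair_id!r} is missing a side")
        bad = set(grp["side"]) - {"source", "target"}
        if bad:
            raise FormatError(f"{path}: pair {pair_id!r} has unknown side(s) {sorted(bad)}")
        pairs.append((src, tgt, str(pair_id)))
    if not pairs:
        raise FormatError(f"{path}: no landmark pairs")
    return LandmarkSet(pairs)


def write_landmarks(lm: LandmarkSet, path: str) -> None:
    rows = []
    for src, tgt, label in lm.pairs:
        for p in src:
            rows.append((label, "source", *p))
        for p in tgt:
            rows.append((label, "target", *p))
    pd.DataFrame(rows, columns=["pair_id", "side", "x", "y", "z"]).to_csv(path, index=False)
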