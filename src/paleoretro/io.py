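"""File formats: meshes (PLY/OBJ/STL via trimesh), landmark CSV, template JSON.

Landmark CSV columns are ``label,x,y,z`` (or ``label,x,y`` in 2D). The
bilateral map is JSON ``{"pairs": [["l","r"], ...], "midline": [...]}``. A
template file combines landmarks (inline or a CSV reference), the bilateral
map and the patch grids. Units are millimetres throughout.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from ._mesh import make_mesh
from .errors import DegenerateInputError
from .geometry import BilateralMap, DistanceMap, LandmarkConfiguration
from .retrodeform import RetrodeformTemplate, SemilandmarkPatch

__all__ = [
    "load_mesh",
    "save_mesh",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_bilateral_map",
    "write_bilateral_map",
    "read_template",
    "write_template",
    "write_distance_csv",
]

_MESH_SUFFIXES = {".ply", ".obj", ".stl", ".off"}


def load_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise DegenerateInputError(f"unsupported mesh format {path.suffix!r}")
    loaded = trimesh.load(path, force="mesh", process=False)
    return make_mesh(loaded.vertices, loaded.faces)


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise DegenerateInputError(f"unsupported mesh format {path.suffix!r}")
    mesh.export(path)


def read_landmarks_csv(path) -> LandmarkConfiguration:
    df = pd.read_csv(path)
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if "label" not in df.columns or len(cols) < 2:
        raise DegenerateInputError("landmark CSV needs columns label,x,y[,z]")
    return LandmarkConfiguration(
        points=df[cols].to_numpy(dtype=float), labels=tuple(df["label"].astype(str))
    )


def write_landmarks_csv(config: LandmarkConfiguration, path) -> None:
    cols = ["x", "y", "z"][: config.dim]
    df = pd.DataFrame(config.points, columns=cols)
    df.insert(0, "label", list(config.labels))
    df.to_csv(path, index=False)


def read_bilateral_map(path) -> BilateralMap:
    with open(path) as fh:
        data = json.load(fh)
    return BilateralMap(
        pairs=tuple((a, b) for a, b in data["pairs"]),
        midline=tuple(data.get("midline", [])),
    )


def write_bilateral_map(bmap: BilateralMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"pairs": [list(p) for p in bmap.pairs], "midline": list(bmap.midline)},
            fh,
            indent=2,
        )


def write_template(template: RetrodeformTemplate, path) -> None:
    data = {
        "landmarks": [
            [l, *map(float, p)] for l, p in zip(template.config.labels, template.config.points)
        ],
        "bilateral": {
            "pairs": [list(p) for p in template.bilateral.pairs],
            "midline": list(template.bilateral.midline),
        },
        "patches": [
            {"left": [list(r) for r in p.left_grid], "right": [list(r) for r in p.right_grid]}
            for p in template.patches
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def read_template(path) -> RetrodeformTemplate:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if "landmarks_csv" in data:
        config = read_landmarks_csv(path.parent / data["landmarks_csv"])
    else:
        rows = data["landmarks"]
        config = LandmarkConfiguration(
            points=np.array([r[1:] for r in rows], dtype=float),
            labels=tuple(str(r[0]) for r in rows),
        )
    bmap = BilateralMap(
        pairs=tuple((a, b) for a, b in data["bilateral"]["pairs"]),
        midline=tuple(data["bilateral"].get("midline", [])),
    )
    patches = tuple(
        SemilandmarkPatch(
            left_grid=tuple(tuple(r) for r in p["left"]),
            right_grid=tuple(tuple(r) for r in p["right"]),
        )
        for p in data.get("patches", [])
    )
    return RetrodeformTemplate(config=config, bilateral=bmap, patches=patches)


def write_distance_csv(dmap: DistanceMap, path) -> None:
    pd.DataFrame(
        {"vertex": np.arange(len(dmap.values)), "signed_distance_mm": dmap.values}
    ).to_csv(path, index=False)
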