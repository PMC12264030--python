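"""File formats: shape CSV + topology JSON, clinical CSV, PLY mesh export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError
from .geometry import Topology
from .metrics import LVMesh

__all__ = [
    "save_shapes_csv",
    "load_shapes_csv",
    "save_topology",
    "load_topology",
    "export_mesh_ply",
]


def _shape_header(n_points: int) -> list[str]:
    return [f"p{i}_{ax}" for i in range(n_points) for ax in "xyz"]


def save_shapes_csv(path, shapes: np.ndarray) -> None:
    """One row per case, columns p0_x, p0_y, p0_z, ..."""
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    if shapes.shape[1] % 3:
        raise DimensionError("shape vector length must be divisible by 3")
    df = pd.DataFrame(shapes, columns=_shape_header(shapes.shape[1] // 3))
    df.to_csv(path, index=False, float_format="%.6f")


def load_shapes_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float)


def save_topology(path, topology: Topology) -> None:
    Path(path).write_text(json.dumps(topology.to_dict(), indent=2, sort_keys=True))


def load_topology(path) -> Topology:
    return Topology.from_dict(json.loads(Path(path).read_text()))


def export_mesh_ply(path, mesh: LVMesh) -> None:
    """Write a closed LV surface as ASCII PLY (via trimesh)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
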