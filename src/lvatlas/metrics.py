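"""LV volumetry: enclosed volumes, mass, ejection fraction, BSA-indexed measures.

Volumes are computed from closed triangulated surfaces by the divergence
theorem (summed signed tetrahedra); the open basal rim of each surface is
capped with a planar fan to the rim centroid before integration. Mass is
myocardial shell volume times the standard myocardial density 1.05 g/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidParameterError
from .geometry import SURFACE_BLOCKS, Topology

__all__ = [
    "LVMesh",
    "LVMeasures",
    "enclosed_volume",
    "lv_mass",
    "body_surface_area",
    "measures",
    "meshes_from_shape",
    "measures_table",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class LVMesh:
    """A closed, consistently oriented triangulated LV surface (mm)."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int
    surface: str = ""  # "endo" | "epi"
    frame: str = ""  # "ED" | "ES"


def _check_closed(faces: np.ndarray) -> None:
    """Every undirected edge must be shared by exactly two opposed triangles."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise GeometryError("mesh is not closed: boundary or non-manifold edges found")
    # consistent orientation: each directed edge appears exactly once
    _, dcounts = np.unique(edges, axis=0, return_counts=True)
    if not np.all(dcounts == 1):
        raise GeometryError("mesh orientation is inconsistent")


def enclosed_volume(mesh: LVMesh) -> float:
    """Enclosed volume in mL (1 mL = 1000 mm^3), orientation-insensitive."""
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    if f.ndim != 2 or f.shape[1] != 3 or len(f) < 4:
        raise GeometryError("mesh must have at least 4 triangular faces")
    _check_closed(f)
    tri = v[f]  # (F, 3, 3)
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return abs(signed) / 1000.0


def lv_mass(epi: LVMesh, endo: LVMesh) -> float:
    """Myocardial mass in g = (V_epi - V_endo) x 1.05 g/mL."""
    v_epi = enclosed_volume(epi)
    v_endo = enclosed_volume(endo)
    if v_epi <= v_endo:
        raise GeometryError(
            f"epicardial volume ({v_epi:.2f} mL) must exceed endocardial ({v_endo:.2f} mL)"
        )
    return (v_epi - v_endo) * MYOCARDIAL_DENSITY_G_PER_ML


def body_surface_area(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """BSA in m^2 (Mosteller by default; Du Bois as alternative)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise InvalidParameterError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm**0.725 * weight_kg**0.425)
    raise InvalidParameterError(f"unknown BSA formula: {formula!r}")


@dataclass
class LVMeasures:
    """Standard LV measures; volumes in mL, mass in g, EF in %, indexed by BSA."""

    edv: float
    esv: float
    mass: float
    ef: float
    bsa: float
    lvedvi: float
    lvesvi: float
    lvmi: float


def measures(
    endo_ed: LVMesh,
    epi_ed: LVMesh,
    endo_es: LVMesh,
    height_cm: float,
    weight_kg: float,
    bsa_formula: str = "mosteller",
) -> LVMeasures:
    """Volumes from the endocardial surfaces, mass at ED, EF, and BSA indexing."""
    edv = enclosed_volume(endo_ed)
    esv = enclosed_volume(endo_es)
    if esv > edv:
        warnings.warn("ESV exceeds EDV; ejection fraction will be negative", stacklevel=2)
    mass = lv_mass(epi_ed, endo_ed)
    ef = 100.0 * (edv - esv) / edv
    bsa = body_surface_area(height_cm, weight_kg, bsa_formula)
    return LVMeasures(
        edv=edv, esv=esv, mass=mass, ef=ef, bsa=bsa,
        lvedvi=edv / bsa, lvesvi=esv / bsa, lvmi=mass / bsa,
    )


def _capped_mesh(points: np.ndarray, topology: Topology, surface: str, frame: str) -> LVMesh:
    """Close an open surface block with a planar basal fan to the rim centroid."""
    faces = topology.open_surface_faces()
    rim = topology.rim_indices()
    centroid = points[rim].mean(axis=0)
    vertices = np.vstack([points, centroid])
    ci = len(points)
    n_phi = topology.n_phi
    cap = [(rim[i], rim[(i + 1) % n_phi], ci) for i in range(n_phi)]
    all_faces = np.vstack([faces, np.asarray(cap, dtype=np.int64)])
    return LVMesh(vertices=vertices, faces=all_faces, surface=surface, frame=frame)


def meshes_from_shape(shape: np.ndarray, topology: Topology) -> dict[str, LVMesh]:
    """Build the four closed LV meshes from one flat shape vector."""
    flat = np.asarray(shape, dtype=float).ravel()
    if flat.size != topology.shape_dim:
        raise GeometryError(
            f"shape vector length {flat.size} != topology dimension {topology.shape_dim}"
        )
    out = {}
    for name in SURFACE_BLOCKS:
        surface, frame = name.split("_")
        pts = topology.block_points(flat, name)
        out[name] = _capped_mesh(pts, topology, surface, frame)
    return out


def shape_measures(
    shape: np.ndarray,
    topology: Topology,
    height_cm: float,
    weight_kg: float,
    bsa_formula: str = "mosteller",
) -> LVMeasures:
    m = meshes_from_shape(shape, topology)
    return measures(m["endo_ED"], m["epi_ED"], m["endo_ES"], height_cm, weight_kg, bsa_formula)


def measures_table(shapes: np.ndarray, topology: Topology, clinical) -> "pandas.DataFrame":
    """Per-case LV measures for a cohort; ``clinical`` needs height_cm/weight_kg."""
    import pandas as pd

    rows = []
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    for i, (_, rec) in enumerate(clinical.iterrows()):
        m = shape_measures(shapes[i], topology, rec["height_cm"], rec["weight_kg"])
        rows.append(
            {
                "case_id": rec.get("case_id", i),
                "edv_ml": m.edv, "esv_ml": m.esv, "mass_g": m.mass, "ef_pct": m.ef,
                "bsa_m2": m.bsa, "lvedvi": m.lvedvi, "lvesvi": m.lvesvi, "lvmi": m.lvmi,
            }
        )
    return pd.DataFrame(rows)
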