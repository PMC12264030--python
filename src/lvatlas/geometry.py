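"""Parametric left-ventricular surface geometry.

The synthetic LV is a truncated prolate spheroid sampled on a fixed
parametric grid, so that every generated case carries homologous surface
points: endocardium and epicardium at end-diastole (ED) and end-systole
(ES), concatenated into one flat coordinate vector
``[x1, y1, z1, ..., xN, yN, zN]`` (millimetres).

The default grid uses 785 points per surface (28 rings x 28 meridians plus
an apical pole), i.e. 4 surfaces x 785 points x 3 coordinates = 9420
numbers per case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError

__all__ = [
    "LVGeometryParams",
    "Topology",
    "generate_base_lv",
    "default_topology",
    "surface_normals",
]

SURFACE_BLOCKS = ("endo_ED", "epi_ED", "endo_ES", "epi_ES")


def _grid_dims(points_per_surface: int) -> tuple[int, int]:
    """Factor ``points_per_surface - 1`` into (n_rings, n_phi), closest to square."""
    m = points_per_surface - 1
    if m < 9:
        raise InvalidParameterError("points_per_surface must be at least 10")
    best = None
    for r in range(3, int(math.isqrt(m)) + 1):
        if m % r == 0 and m // r >= 3:
            best = (r, m // r)
    if best is None:
        raise InvalidParameterError(
            f"points_per_surface - 1 = {m} has no grid factorisation (rings x meridians)"
        )
    return best


@dataclass(frozen=True)
class LVGeometryParams:
    """Parameters of the truncated prolate-spheroid LV stand-in.

    ``endo_semi_axes_ed`` are the (a, b, c) semi-axes of the ED endocardial
    spheroid in mm, with c the long axis. The epicardium is a uniform
    outward offset by ``wall_thickness_ed``. ES is an anisotropic
    contraction: transverse semi-axes shrink by ``radial_thickening`` and
    the long axis by ``long_axis_shortening``; the ES wall offset is solved
    so that myocardial (shell) volume is conserved. The basal truncation
    plane sits at ``truncation_fraction`` x c above the centre.
    """

    endo_semi_axes_ed: tuple[float, float, float] = (22.0, 22.0, 63.0)
    wall_thickness_ed: float = 7.0
    radial_thickening: float = 0.25
    long_axis_shortening: float = 0.28
    points_per_surface: int = 785
    truncation_fraction: float = 0.92

    def __post_init__(self) -> None:
        a, b, c = self.endo_semi_axes_ed
        if min(a, b, c) <= 0:
            raise InvalidParameterError("endocardial semi-axes must be positive")
        if self.wall_thickness_ed <= 0:
            raise InvalidParameterError("wall thickness must be positive")
        if not 0 <= self.radial_thickening < 1 or not 0 <= self.long_axis_shortening < 1:
            raise InvalidParameterError("systolic fractions must lie in [0, 1)")
        if not 0 < self.truncation_fraction < 1:
            raise InvalidParameterError("truncation_fraction must lie in (0, 1)")
        _grid_dims(self.points_per_surface)  # validates factorisation

    @property
    def grid_dims(self) -> tuple[int, int]:
        return _grid_dims(self.points_per_surface)

    @property
    def n_points(self) -> int:
        """Total homologous points over the four surfaces."""
        return 4 * self.points_per_surface

    @property
    def shape_dim(self) -> int:
        """Length of the flat shape vector (default 9420)."""
        return 3 * self.n_points


@dataclass(frozen=True)
class Topology:
    """Surface/frame partition and triangulation of the flat shape vector."""

    points_per_surface: int
    n_rings: int
    n_phi: int
    blocks: dict = field(default_factory=dict)  # name -> (start_point, stop_point)

    @property
    def shape_dim(self) -> int:
        return 3 * 4 * self.points_per_surface

    def block_slice(self, name: str) -> slice:
        """Coordinate slice of one surface block in the flat vector."""
        start, stop = self.blocks[name]
        return slice(3 * start, 3 * stop)

    def block_points(self, shape: np.ndarray, name: str) -> np.ndarray:
        """(points_per_surface, 3) view of one surface block."""
        flat = np.asarray(shape, dtype=float).ravel()
        return flat[self.block_slice(name)].reshape(-1, 3)

    def open_surface_faces(self) -> np.ndarray:
        """Outward-oriented triangulation of one open (uncapped) surface."""
        return _open_surface_faces(self.n_rings, self.n_phi)

    def rim_indices(self) -> np.ndarray:
        """Indices (within a surface block) of the basal rim ring."""
        return np.arange(self.n_phi)

    def to_dict(self) -> dict:
        return {
            "points_per_surface": self.points_per_surface,
            "n_rings": self.n_rings,
            "n_phi": self.n_phi,
            "blocks": {k: list(v) for k, v in self.blocks.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Topology":
        return cls(
            points_per_surface=int(d["points_per_surface"]),
            n_rings=int(d["n_rings"]),
            n_phi=int(d["n_phi"]),
            blocks={k: tuple(v) for k, v in d["blocks"].items()},
        )


def default_topology(params: LVGeometryParams | None = None) -> Topology:
    params = params or LVGeometryParams()
    n_rings, n_phi = params.grid_dims
    pps = params.points_per_surface
    blocks = {name: (i * pps, (i + 1) * pps) for i, name in enumerate(SURFACE_BLOCKS)}
    return Topology(points_per_surface=pps, n_rings=n_rings, n_phi=n_phi, blocks=blocks)


def _spheroid_surface(a, b, c, truncation_fraction, n_rings, n_phi) -> np.ndarray:
    """Sample a truncated spheroid on the fixed (theta, phi) grid.

    theta runs from the basal truncation ring (z = t*c) to the apex
    (z = -c); the apical pole is appended as a single point.
    """
    theta0 = math.acos(truncation_fraction)
    thetas = theta0 + (np.arange(n_rings) / n_rings) * (math.pi - theta0)
    phis = 2.0 * math.pi * np.arange(n_phi) / n_phi
    th, ph = np.meshgrid(thetas, phis, indexing="ij")
    pts = np.empty((n_rings * n_phi + 1, 3))
    pts[:-1, 0] = (a * np.sin(th) * np.cos(ph)).ravel()
    pts[:-1, 1] = (b * np.sin(th) * np.sin(ph)).ravel()
    pts[:-1, 2] = (c * np.cos(th)).ravel()
    pts[-1] = (0.0, 0.0, -c)
    return pts


def _open_surface_faces(n_rings: int, n_phi: int) -> np.ndarray:
    faces = []
    for j in range(n_rings - 1):
        for i in range(n_phi):
            a = j * n_phi + i
            b = j * n_phi + (i + 1) % n_phi
            c = (j + 1) * n_phi + i
            d = (j + 1) * n_phi + (i + 1) % n_phi
            faces.append((a, d, b))
            faces.append((a, c, d))
    apex = n_rings * n_phi
    j = n_rings - 1
    for i in range(n_phi):
        a = j * n_phi + i
        b = j * n_phi + (i + 1) % n_phi
        faces.append((a, apex, b))
    return np.asarray(faces, dtype=np.int64)


def _block_semi_axes(params: LVGeometryParams) -> dict[str, tuple[float, float, float]]:
    """Semi-axes of all four surfaces, with ES wall solved for shell-volume conservation."""
    a, b, c = params.endo_semi_axes_ed
    w = params.wall_thickness_ed
    fr, fl = params.radial_thickening, params.long_axis_shortening
    a_s, b_s, c_s = a * (1 - fr), b * (1 - fr), c * (1 - fl)
    shell = (a + w) * (b + w) * (c + w) - a * b * c  # ~ myocardial volume / (4pi/3)

    def g(wp):
        return (a_s + wp) * (b_s + wp) * (c_s + wp) - (a_s * b_s * c_s + shell)

    w_es = brentq(g, 1e-9, 10.0 * (w + max(a, b, c)))
    return {
        "endo_ED": (a, b, c),
        "epi_ED": (a + w, b + w, c + w),
        "endo_ES": (a_s, b_s, c_s),
        "epi_ES": (a_s + w_es, b_s + w_es, c_s + w_es),
    }


def generate_base_lv(params: LVGeometryParams | None = None) -> np.ndarray:
    """Return the flat shape vector of the canonical (noise-free) LV.

    Block order is endo_ED, epi_ED, endo_ES, epi_ES; every case generated
    from the same ``points_per_surface`` shares grid indices (homology).
    """
    params = params or LVGeometryParams()
    n_rings, n_phi = params.grid_dims
    axes = _block_semi_axes(params)
    parts = [
        _spheroid_surface(*axes[name], params.truncation_fraction, n_rings, n_phi)
        for name in SURFACE_BLOCKS
    ]
    return np.concatenate([p.ravel() for p in parts])


def surface_normals(params: LVGeometryParams, block: str) -> np.ndarray:
    """Outward unit normals of one surface block of the canonical LV.

    Analytic spheroid normals n ~ (x/a^2, y/b^2, z/c^2); the apical pole
    gets (0, 0, -1).
    """
    n_rings, n_phi = params.grid_dims
    a, b, c = _block_semi_axes(params)[block]
    pts = _spheroid_surface(a, b, c, params.truncation_fraction, n_rings, n_phi)
    n = pts / np.array([a**2, b**2, c**2])
    n[-1] = (0.0, 0.0, -1.0)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return n / norms
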