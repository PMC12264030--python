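"""Shared fixtures: canonical geometry and a small reusable cohort."""

import warnings

import numpy as np
import pytest

import lvatlas as lv

# sklearn PLS warns when the y residual flattens at high component counts;
# harmless during component-grid sweeps
warnings.filterwarnings("ignore", message="y residual is constant")


@pytest.fixture(scope="session")
def params() -> lv.LVGeometryParams:
    return lv.LVGeometryParams()


@pytest.fixture(scope="session")
def topology(params):
    return lv.default_topology(params)


@pytest.fixture(scope="session")
def base_shape(params):
    return lv.generate_base_lv(params)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-case default cohort (shapes + clinical), session-cached."""
    cfg = lv.CohortConfig(n_cases=60, seed=42)
    shapes, clinical = lv.generate_cohort(cfg)
    return cfg, shapes, clinical


@pytest.fixture(scope="session")
def fitted_atlas(small_cohort):
    _, shapes, _ = small_cohort
    return lv.ShapeAtlas().fit(shapes)


def rigid_motion(shape: np.ndarray, seed: int = 0, angle_deg: float = 25.0,
                 shift: float = 12.0) -> np.ndarray:
    """Apply a reproducible rigid rotation + translation to a flat shape."""
    rng = np.random.default_rng(seed)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
    t = rng.normal(0.0, shift, 3)
    return (shape.reshape(-1, 3) @ rot.T + t).ravel()
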