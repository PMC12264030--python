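"""Statistical shape atlas: generalised Procrustes alignment + PCA.

An atlas is a point-distribution model of a cohort's homologous LV shape
vectors: the Procrustes mean shape plus orthonormal principal components of
the deviations from the mean, truncated at a cumulative explained-variance
cutoff (99.9% by default). Alignment removes rotation and translation only
— scale is deliberately retained, because heart size itself is
physiologically meaningful.

``ShapeAtlas`` follows the scikit-learn transformer contract: ``fit`` runs
GPA and PCA, ``transform`` projects arbitrary homologous shapes into the
atlas score space (one-shot rigid alignment to the fixed mean, then dot
products with the components), ``inverse_transform`` reconstructs shapes
from scores.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DimensionError, InvalidParameterError

__all__ = [
    "kabsch_rotation",
    "rigid_align",
    "generalised_procrustes",
    "ShapeAtlas",
    "dimensionality_reduction_percent",
]


def kabsch_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det +1) mapping centred ``source`` onto
    centred ``target`` in the least-squares sense."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def rigid_align(shape: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly align one flat shape vector to a reference (rotation +
    translation only; centroid size is preserved)."""
    a = np.asarray(shape, dtype=float).reshape(-1, 3)
    b = np.asarray(reference, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise DimensionError(f"shape has {a.shape[0]} points, reference {b.shape[0]}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot = kabsch_rotation(a - ca, b - cb)
    return ((a - ca) @ rot.T + cb).ravel()


def generalised_procrustes(
    shapes: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iteratively align a set of homologous shapes to their evolving mean.

    Returns (aligned shapes (n, 3N), mean shape (3N,), iterations used).
    The first pass aligns to shape 0 as provisional mean; convergence is
    declared when the relative mean-shape change drops below ``tol``. After
    convergence every shape is re-aligned once to the final mean, so each
    aligned shape is the optimal rigid fit to the returned mean.
    """
    x = np.atleast_2d(np.asarray(shapes, dtype=float))
    n, dim = x.shape
    if n < 2:
        raise InvalidParameterError("generalised Procrustes needs at least 2 shapes")
    if dim % 3:
        raise DimensionError("shape vector length must be divisible by 3")
    aligned = x.copy()
    mean = x[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = rigid_align(aligned[i], mean)
        new_mean = aligned.mean(axis=0)
        delta = np.linalg.norm(new_mean - mean) / max(np.linalg.norm(mean), 1e-30)
        mean = new_mean
        if delta < tol:
            break
    else:
        warnings.warn(
            f"generalised Procrustes did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    for i in range(n):
        aligned[i] = rigid_align(aligned[i], mean)
    return aligned, mean, n_iter


def dimensionality_reduction_percent(n_components: int, total_dim: int) -> float:
    """Percentage reduction from the original shape dimension to the
    retained component count, e.g. 176 of 9420 -> 98.1."""
    return 100.0 * (1.0 - n_components / total_dim)


class ShapeAtlas(BaseEstimator, TransformerMixin):
    """GPA + PCA shape atlas with a cumulative-variance component cutoff.

    Parameters
    ----------
    variance_cutoff : float in (0, 1], default 0.999
        Smallest component count whose cumulative explained variance
        reaches this fraction is retained.
    gpa_tol, gpa_max_iter : GPA convergence controls.

    Attributes (after ``fit``)
    --------------------------
    mean_shape_ : (3N,) Procrustes mean, mm.
    components_ : (K, 3N) orthonormal principal directions.
    explained_variance_ : (K,) descending variances (divisor n - 1).
    variance_fraction_retained_ : cumulative fraction at K components.
    training_scores_ : (n, K) scores of the training shapes.
    """

    def __init__(self, variance_cutoff: float = 0.999, gpa_tol: float = 1e-10,
                 gpa_max_iter: int = 100):
        self.variance_cutoff = variance_cutoff
        self.gpa_tol = gpa_tol
        self.gpa_max_iter = gpa_max_iter

    def fit(self, X, y=None):
        if not 0.0 < self.variance_cutoff <= 1.0:
            raise InvalidParameterError("variance_cutoff must lie in (0, 1]")
        x = np.atleast_2d(np.asarray(X, dtype=float))
        if x.shape[0] < 2:
            raise InvalidParameterError("an atlas needs at least 2 shapes")
        aligned, mean, self.n_gpa_iterations_ = generalised_procrustes(
            x, tol=self.gpa_tol, max_iter=self.gpa_max_iter
        )
        centred = aligned - mean
        # economy SVD of the centred data matrix
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        n = x.shape[0]
        variances = s**2 / (n - 1)
        total = variances.sum()
        cum = np.cumsum(variances) / total
        k = int(np.searchsorted(cum, self.variance_cutoff - 1e-12) + 1)
        k = min(k, len(variances))
        # deterministic sign: largest-magnitude loading positive
        comps = vt[:k]
        for j in range(k):
            i_max = np.argmax(np.abs(comps[j]))
            if comps[j, i_max] < 0:
                comps[j] = -comps[j]
        self.mean_shape_ = mean
        self.components_ = comps
        self.explained_variance_ = variances[:k]
        self.total_variance_ = float(total)
        self.variance_fraction_retained_ = float(cum[k - 1])
        self.n_components_ = k
        self.n_features_in_ = x.shape[1]
        self.n_samples_ = n
        self.training_scores_ = centred @ comps.T
        return self

    def _align(self, X) -> np.ndarray:
        x = np.atleast_2d(np.asarray(X, dtype=float))
        if x.shape[1] != self.n_features_in_:
            raise DimensionError(
                f"shape dimension {x.shape[1]} != atlas dimension {self.n_features_in_}"
            )
        return np.stack([rigid_align(row, self.mean_shape_) for row in x])

    def transform(self, X) -> np.ndarray:
        """Project shapes into the atlas score space.

        Each shape is rigidly aligned to the atlas mean (one-shot optimal
        fit), the mean is subtracted, and scores are the dot products with
        the components. The out-of-subspace residual is discarded; its norm
        is recorded in ``last_projection_residual_``.
        """
        check_is_fitted(self, "mean_shape_")
        centred = self._align(X) - self.mean_shape_
        scores = centred @ self.components_.T
        recon = scores @ self.components_
        self.last_projection_residual_ = np.linalg.norm(centred - recon, axis=1)
        return scores

    def inverse_transform(self, scores) -> np.ndarray:
        """Reconstruct shapes: mean + components x scores (zero-padded if
        fewer than K scores are given)."""
        check_is_fitted(self, "mean_shape_")
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        if s.shape[1] > self.n_components_:
            raise DimensionError(
                f"got {s.shape[1]} scores but atlas retains {self.n_components_}"
            )
        out = self.mean_shape_ + s @ self.components_[: s.shape[1]]
        return out[0] if np.asarray(scores).ndim == 1 else out

    # --- persistence -----------------------------------------------------

    def save(self, directory) -> None:
        """Persist as a directory of CSVs plus a metadata JSON."""
        check_is_fitted(self, "mean_shape_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "mean_shape.csv", self.mean_shape_[None], delimiter=",")
        np.savetxt(d / "components.csv", self.components_, delimiter=",")
        np.savetxt(d / "variances.csv", self.explained_variance_[None], delimiter=",")
        meta = {
            "n_components": self.n_components_,
            "variance_cutoff": self.variance_cutoff,
            "variance_fraction_retained": self.variance_fraction_retained_,
            "total_variance": self.total_variance_,
            "n_training_shapes": self.n_samples_,
            "shape_dim": self.n_features_in_,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "ShapeAtlas":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        atlas = cls(variance_cutoff=meta["variance_cutoff"])
        atlas.mean_shape_ = np.loadtxt(d / "mean_shape.csv", delimiter=",").ravel()
        atlas.components_ = np.atleast_2d(np.loadtxt(d / "components.csv", delimiter=","))
        atlas.explained_variance_ = np.atleast_1d(
            np.loadtxt(d / "variances.csv", delimiter=",")
        ).ravel()
        atlas.n_components_ = int(meta["n_components"])
        atlas.variance_fraction_retained_ = float(meta["variance_fraction_retained"])
        atlas.total_variance_ = float(meta["total_variance"])
        atlas.n_samples_ = int(meta["n_training_shapes"])
        atlas.n_features_in_ = int(meta["shape_dim"])
        return atlas
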