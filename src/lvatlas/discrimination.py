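"""PLSR discrimination of risk-factor membership from age, sex and shape scores.

For each risk factor a partial least squares regression is trained on the
binary group label (risk vs no-risk) over the predictor matrix
[age, sex, atlas shape scores]. Predictors are centred and scaled
block-wise: age and sex each to unit variance, and the whole shape-score
block by one common factor (the pooled score SD). Age/sex live on very
different scales from the scores, but the scores are mutually commensurate
(all mm along orthonormal modes); a per-column rescaling would instead
whiten low-variance components up and destroy the anatomical meaning of
the fitted coefficient direction. The component count is chosen by
stratified five-fold cross-validation
minimising the squared error of the 0/1 response, ties towards fewer
components. Internal performance uses leave-one-out scores; external
performance projects the other cohort's shapes through the internal atlas
and scores them with the frozen internal model.

Implementation notes: the latent decomposition is the standard univariate-
response PLS (NIPALS, identical to SIMPLS for a single response; the fit is
delegated to scikit-learn). Leave-one-out scores are *intercept-free* — the
per-fold linear score omits the fold's label-mean intercept, which is
rank-preserving for any fixed model but, if kept, varies with the held-out
label and deterministically depresses the null AUC (the classic
leave-one-out pessimism artifact).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .atlas import ShapeAtlas
from .errors import DimensionError, InvalidParameterError

__all__ = [
    "RiskFactorDiscriminator",
    "build_predictors",
    "select_ncomp",
    "loo_scores",
    "external_scores",
    "shape_effect_contours",
]


def build_predictors(clinical, shape_scores: np.ndarray, rows=None) -> np.ndarray:
    """Predictor matrix [age, sex, shape scores] for the given row subset."""
    scores = np.atleast_2d(np.asarray(shape_scores, dtype=float))
    age = clinical["age"].to_numpy(dtype=float)
    sex = clinical["sex"].to_numpy(dtype=float)
    if len(age) != len(scores):
        raise DimensionError("clinical table and shape scores disagree in length")
    x = np.column_stack([age, sex, scores])
    return x[rows] if rows is not None else x


N_COVARIATE_COLUMNS = 2  # age, sex precede the shape-score block


def _standardise_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Block-wise standardisation: age/sex per column, scores by pooled SD."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    k = min(N_COVARIATE_COLUMNS, x.shape[1])
    if x.shape[1] > k:
        pooled = np.sqrt(np.mean(sd[k:] ** 2))
        sd[k:] = pooled
    sd = np.where(sd > 0, sd, 1.0)  # zero-variance guard
    return mu, sd


def _fit_pls(xs: np.ndarray, y: np.ndarray, ncomp: int) -> tuple[np.ndarray, float]:
    """Fit univariate PLS on standardised predictors; return (coef, y_mean)."""
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(xs, y.astype(float))
    return pls.coef_.ravel().copy(), float(np.mean(y))


def _pls_coef_path(xs: np.ndarray, y: np.ndarray, ks: list[int]) -> dict[int, np.ndarray]:
    """Coefficient vectors for nested component counts from a single fit.

    For NIPALS, P'W is unit upper triangular, so the k-component rotation
    matrix is the first k columns of the full one and
    B_k = rotations[:, :k] @ y_loadings[:, :k]'.
    """
    kmax = max(ks)
    pls = PLSRegression(n_components=kmax, scale=False)
    pls.fit(xs, y.astype(float))
    rot = pls.x_rotations_  # (p, kmax)
    q = pls.y_loadings_.ravel()  # (kmax,)
    return {k: rot[:, :k] @ q[:k] for k in ks}


def select_ncomp(
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    grid=None,
    seed: int | None = 0,
) -> int:
    """Component count minimising CV mean squared error of the 0/1 response.

    Stratified, seeded fold assignment; ties break towards the smallest
    count. The grid is clipped to what the fold training sets can support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    n, p = x.shape
    if n < folds:
        raise InvalidParameterError(f"need at least {folds} cases for {folds}-fold CV")
    if grid is None:
        grid = range(1, 31)
    grid = sorted(set(int(k) for k in grid))
    if not grid:
        raise InvalidParameterError("component grid is empty")
    max_rank = min(p, n - (n // folds) - 1)
    grid = [k for k in grid if k <= max_rank] or [1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = dict.fromkeys(grid, 0.0)
    for tr, te in skf.split(x, y):
        mu, sd = _standardise_params(x[tr])
        xs_tr = (x[tr] - mu) / sd
        xs_te = (x[te] - mu) / sd
        coefs = _pls_coef_path(xs_tr, y[tr], grid)
        y_mean = float(np.mean(y[tr]))
        for k, b in coefs.items():
            pred = xs_te @ b + y_mean
            sse[k] += float(np.sum((y[te] - pred) ** 2))
    best = min(grid, key=lambda k: (sse[k], k))
    return int(best)


def loo_scores(x: np.ndarray, y: np.ndarray, ncomp: int) -> np.ndarray:
    """Leave-one-out linear scores (intercept-free), preserving case order.

    ``ncomp`` must be fixed beforehand; no per-fold re-selection happens
    here.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    out = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        mu, sd = _standardise_params(x[tr])
        k = min(ncomp, x.shape[1], n - 2)
        coef, _ = _fit_pls((x[tr] - mu) / sd, y[tr], k)
        out[i] = (x[i] - mu) / sd @ coef
    return out


class RiskFactorDiscriminator(BaseEstimator):
    """PLSR model of one risk factor over [age, sex, shape scores].

    Parameters
    ----------
    n_components : int or "cv"
        Latent component count; ``"cv"`` selects it by stratified k-fold CV.
    component_grid : iterable of int, default 1..30.
    cv_folds : int, default 5.
    random_state : seed for the CV fold shuffle.
    factor : optional factor name, carried for provenance.

    After ``fit``: ``coef_`` (standardised-space coefficients),
    ``intercept_``, ``mu_``/``sigma_`` (standardisation), ``n_components_``.
    """

    def __init__(self, n_components="cv", component_grid=None, cv_folds: int = 5,
                 random_state: int | None = 0, factor: str | None = None):
        self.n_components = n_components
        self.component_grid = component_grid
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.factor = factor

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise InvalidParameterError("both classes must be present to fit")
        if self.n_components == "cv":
            ncomp = select_ncomp(
                x, y, folds=self.cv_folds, grid=self.component_grid,
                seed=self.random_state,
            )
        else:
            ncomp = int(self.n_components)
            if not 1 <= ncomp <= x.shape[1]:
                raise InvalidParameterError(
                    f"n_components={ncomp} outside [1, {x.shape[1]}]"
                )
        self.mu_, self.sigma_ = _standardise_params(x)
        xs = (x - self.mu_) / self.sigma_
        self.coef_, self.intercept_ = _fit_pls(xs, y, ncomp)
        self.n_components_ = ncomp
        self.n_features_in_ = x.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous predicted score (higher = more risk-like)."""
        check_is_fitted(self, "coef_")
        x = np.atleast_2d(np.asarray(X, dtype=float))
        if x.shape[1] != self.n_features_in_:
            raise DimensionError(
                f"predictor dimension {x.shape[1]} != fitted {self.n_features_in_}"
            )
        return (x - self.mu_) / self.sigma_ @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)

    # --- persistence -----------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "coef_")
        payload = {
            "factor": self.factor,
            "n_components": self.n_components_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "mu": self.mu_.tolist(),
            "sigma": self.sigma_.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RiskFactorDiscriminator":
        d = json.loads(Path(path).read_text())
        model = cls(n_components=d["n_components"], factor=d.get("factor"))
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        model.mu_ = np.asarray(d["mu"], dtype=float)
        model.sigma_ = np.asarray(d["sigma"], dtype=float)
        model.n_components_ = int(d["n_components"])
        model.n_features_in_ = len(model.coef_)
        return model


def external_scores(
    model: RiskFactorDiscriminator,
    internal_atlas: ShapeAtlas,
    shapes: np.ndarray,
    clinical,
    rows=None,
) -> np.ndarray:
    """Score external cases with a frozen internal model.

    External shapes are projected through the internal atlas (one-shot
    rigid alignment to the internal mean), combined with external age/sex,
    standardised with the internal training parameters, and scored with the
    internal coefficients.
    """
    scores = internal_atlas.transform(np.atleast_2d(shapes))
    x = build_predictors(clinical, scores, rows=rows)
    return model.decision_function(x)


def shape_effect_contours(
    model: RiskFactorDiscriminator,
    atlas: ShapeAtlas,
    magnitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean shape +/- the model's shape-effect direction, scaled to
    ``magnitude`` mm of total displacement.

    The shape block of the standardised coefficients is mapped back to raw
    score units, pushed through the atlas components into the full shape
    space, and normalised, so the returned displacement norm equals
    ``magnitude`` exactly. Age/sex coefficients do not enter the contour.
    """
    check_is_fitted(model, "coef_")
    check_is_fitted(atlas, "mean_shape_")
    beta_scores = model.coef_[2:] / model.sigma_[2:]
    if len(beta_scores) != atlas.n_components_:
        raise DimensionError(
            f"model has {len(beta_scores)} shape coefficients, atlas retains "
            f"{atlas.n_components_} components"
        )
    direction = beta_scores @ atlas.components_
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise InvalidParameterError("shape coefficient vector is zero")
    direction /= nrm
    return (
        atlas.mean_shape_ + magnitude * direction,
        atlas.mean_shape_ - magnitude * direction,
    )
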