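"""Validation experiments for the analysis pipeline.

These runs check the statistical behaviour of the whole chain (generator ->
atlas -> PLSR -> ROC) under controlled conditions:

* null calibration — zero shape effects: leave-one-out AUCs should sit at
  chance, and the unpaired AUC comparison should reject at its nominal
  rate;
* parameter recovery — a single strong effect: the model's fitted
  shape-effect direction should align with the generative one, and internal
  AUC should rise monotonically with effect size;
* twin-cohort generalisability — paired cohorts with shared (or
  deliberately decoupled) effect directions: external performance should
  match (or drop below) internal performance accordingly.

Problem sizes follow the package's standard validation settings
(n = 500 for null runs, n = 800 for recovery and twin runs, n = 300 for the
effect-size sweep).
"""

from __future__ import annotations

import numpy as np

from .atlas import ShapeAtlas
from .discrimination import (
    RiskFactorDiscriminator,
    build_predictors,
    loo_scores,
    select_ncomp,
    shape_effect_contours,
)
from .pipeline import ExperimentConfig, GeneralisabilityReport, run_experiment
from .risk import add_risk_columns, assign_groups
from .stats import compare_auc_unpaired, roc_auc
from .synthetic import (
    FACTORS,
    CohortConfig,
    generate_cohort,
    biased_corelab_config,
    named_effect_direction,
    random_orthogonal_direction,
    reference_corelab_config,
)

__all__ = [
    "single_factor_config",
    "internal_loo_auc",
    "null_calibration_aucs",
    "comparison_type_i_rate",
    "direction_recovery_cosine",
    "effect_size_auc_curve",
    "twin_experiment",
]


def single_factor_config(
    factor: str, n_cases: int, seed: int, effect: float, noise_sd: float | None = None,
) -> CohortConfig:
    """Balanced one-factor cohort: prevalence 0.5 for ``factor``, 0 elsewhere."""
    kwargs = {}
    if noise_sd is not None:
        kwargs["noise_sd"] = noise_sd
    return CohortConfig(
        n_cases=n_cases,
        seed=seed,
        prevalence={f: (0.5 if f == factor else 0.0) for f in FACTORS},
        effect_size={f: (effect if f == factor else 0.0) for f in FACTORS},
        **kwargs,
    )


def internal_loo_auc(config: CohortConfig, factor: str, cv_seed: int = 0):
    """Full internal evaluation of one cohort for one factor.

    Returns (auc, n_plsr_components, fitted atlas, fitted model, generative
    direction cosine ingredients) packed as a dict.
    """
    shapes, clinical = generate_cohort(config)
    profiled = add_risk_columns(clinical)
    atlas = ShapeAtlas().fit(shapes)
    risk, norisk = assign_groups(profiled, factor)
    rows = np.concatenate([risk, norisk])
    y = np.concatenate([np.ones(len(risk), int), np.zeros(len(norisk), int)])
    x = build_predictors(profiled, atlas.training_scores_, rows=rows)
    ncomp = select_ncomp(x, y, seed=cv_seed)
    scores = loo_scores(x, y, ncomp)
    auc = roc_auc(scores, y).auc
    model = RiskFactorDiscriminator(n_components=ncomp, factor=factor).fit(x, y)
    return {"auc": auc, "ncomp": ncomp, "atlas": atlas, "model": model,
            "config": config, "n": len(y)}


def null_calibration_aucs(n_cases: int = 500, seed: int = 0) -> dict:
    """Zero-effect LOO AUCs for every factor in two independent cohorts.

    Each factor gets its own balanced cohort pair (prevalence 0.5), the
    maximum-precision design for checking that the evaluation is neither
    optimistic (leakage) nor pessimistic (fold-coupling artifacts).
    """
    out = {}
    for k, factor in enumerate(FACTORS):
        for cohort in (0, 1):
            cfg = single_factor_config(
                factor, n_cases=n_cases, seed=seed + 10 * k + cohort, effect=0.0
            )
            res = internal_loo_auc(cfg, factor, cv_seed=seed)
            out[(factor, cohort)] = res["auc"]
    return out


def comparison_type_i_rate(
    n_replicates: int = 200, n_per_class: int = 150, seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the unpaired AUC comparison on paired null samples."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    rejections = 0
    for _ in range(n_replicates):
        r1 = roc_auc(rng.standard_normal(2 * n_per_class), y)
        r2 = roc_auc(rng.standard_normal(2 * n_per_class), y)
        _, p = compare_auc_unpaired(r1, r2)
        rejections += p < alpha
    return rejections / n_replicates


def direction_recovery_cosine(
    n_cases: int = 800, effect: float = 2.0, noise_sd: float = 0.5, seed: int = 0,
    factor: str = "hypertension",
) -> float:
    """Cosine between the generative effect direction and the model's
    recovered shape-effect direction."""
    cfg = single_factor_config(
        factor, n_cases=n_cases, seed=seed, effect=effect, noise_sd=noise_sd
    )
    res = internal_loo_auc(cfg, factor, cv_seed=seed)
    plus, _ = shape_effect_contours(res["model"], res["atlas"], magnitude=1.0)
    recovered = plus - res["atlas"].mean_shape_
    generative = cfg.resolved_directions()[factor]
    return float(abs(recovered @ generative) / np.linalg.norm(recovered))


def effect_size_auc_curve(
    effects=(0.0, 0.5, 1.0, 2.0), n_cases: int = 300, n_seeds: int = 5,
    seed: int = 0, factor: str = "hypertension",
) -> list[float]:
    """Mean internal LOO AUC per effect size, averaged over replicate seeds."""
    means = []
    for eff in effects:
        aucs = []
        for rep in range(n_seeds):
            cfg = single_factor_config(
                factor, n_cases=n_cases, seed=seed + 1000 + rep, effect=eff
            )
            aucs.append(internal_loo_auc(cfg, factor, cv_seed=seed)["auc"])
        means.append(float(np.mean(aucs)))
    return means


def twin_experiment(
    n_cases: int = 800, effect: float = 1.5, seed: int = 0,
    obesity_orthogonal: bool = False, n_boot: int = 2000,
) -> GeneralisabilityReport:
    """Paired-cohort generalisability run with shared effect directions,
    optionally decoupling the obesity direction between cohorts."""
    eff = {f: effect for f in FACTORS}
    cohort_a = biased_corelab_config(seed=seed, n_cases=n_cases, effect_size=eff)
    cohort_b = reference_corelab_config(seed=seed + 1, n_cases=n_cases, effect_size=eff)
    if obesity_orthogonal:
        reference = named_effect_direction("cavity_dilation", cohort_a.geometry)
        cohort_b.effect_direction = dict(cohort_b.effect_direction)
        cohort_b.effect_direction["obesity"] = random_orthogonal_direction(
            reference, seed=seed + 12345
        )
    cfg = ExperimentConfig(
        cohort_a=cohort_a, cohort_b=cohort_b, seed=seed, n_boot=n_boot
    )
    return run_experiment(cfg)
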