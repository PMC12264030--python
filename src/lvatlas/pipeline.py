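"""End-to-end generalisability experiment.

Two cohorts in, a per-factor internal/external AUC comparison out: for each
cohort taken as "internal", a GPA+PCA atlas is built from all internal
shapes; per risk factor, the PLSR component count is chosen by stratified
five-fold CV, internal performance is leave-one-out AUC with a bootstrap
CI, the full-data model then scores the *other* cohort's shapes projected
through the internal atlas, and internal vs external AUCs are compared with
the unpaired DeLong z test. An atlas is flagged generalisable for a factor
when the comparison is non-significant (p > 0.05) and the 95% CIs overlap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import ShapeAtlas
from .discrimination import (
    RiskFactorDiscriminator,
    build_predictors,
    external_scores,
    loo_scores,
    select_ncomp,
    shape_effect_contours,
)
from .errors import InvalidParameterError
from .geometry import default_topology
from .io import export_mesh_ply
from .metrics import measures_table, meshes_from_shape
from .risk import add_risk_columns, assign_groups
from .stats import (
    bootstrap_auc_ci,
    cohort_table,
    compare_auc_unpaired,
    match_no_risk,
    roc_auc,
)
from .synthetic import FACTORS, CohortConfig, generate_cohort

__all__ = ["ExperimentConfig", "FactorResult", "GeneralisabilityReport", "run_experiment",
           "render_report"]


@dataclass
class ExperimentConfig:
    cohort_a: CohortConfig = field(default_factory=lambda: CohortConfig(seed=0))
    cohort_b: CohortConfig = field(default_factory=lambda: CohortConfig(seed=1))
    factors: tuple = FACTORS
    variance_cutoff: float = 0.999
    cv_folds: int = 5
    component_grid: tuple = tuple(range(1, 31))
    n_boot: int = 2000
    seed: int = 0
    names: tuple = ("cohortA", "cohortB")

    def __post_init__(self) -> None:
        unknown = set(self.factors) - set(FACTORS)
        if unknown:
            raise InvalidParameterError(f"unknown factors: {sorted(unknown)}")


@dataclass
class FactorResult:
    factor: str
    atlas: str  # name of the internal cohort
    n_components_retained: int
    n_plsr_components: int
    n_risk_internal: int
    n_norisk_internal: int
    n_risk_external: int
    n_norisk_external: int
    internal_auc: float
    internal_ci: tuple
    external_auc: float
    external_ci: tuple
    z_statistic: float
    p_value: float
    generalisable: bool


@dataclass
class GeneralisabilityReport:
    results: list
    factors: tuple
    seed: int
    version: str
    config_digest: str

    def to_json(self) -> str:
        payload = {
            "factors": list(self.factors),
            "seed": self.seed,
            "version": self.version,
            "config_digest": self.config_digest,
            "results": [asdict(r) for r in self.results],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneralisabilityReport":
        d = json.loads(text)
        results = []
        for r in d["results"]:
            r = dict(r)
            r["internal_ci"] = tuple(r["internal_ci"])
            r["external_ci"] = tuple(r["external_ci"])
            results.append(FactorResult(**r))
        return cls(
            results=results,
            factors=tuple(d["factors"]),
            seed=d["seed"],
            version=d["version"],
            config_digest=d["config_digest"],
        )

    def table(self) -> pd.DataFrame:
        import dataclasses

        columns = [f.name for f in dataclasses.fields(FactorResult)]
        return pd.DataFrame([asdict(r) for r in self.results], columns=columns)


def _config_digest(cfg: ExperimentConfig) -> str:
    import hashlib

    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ci_overlap(ci1, ci2) -> bool:
    return ci1[0] <= ci2[1] and ci2[0] <= ci1[1]


def evaluate_direction(
    internal_shapes, internal_clinical, external_shapes, external_clinical,
    cfg: ExperimentConfig, atlas_name: str, seed: int,
    external_is_internal: bool = False,
):
    """All-factor evaluation with one cohort as internal, the other external.

    Returns (results, context) where context carries the fitted atlas and
    per-factor models for rendering.
    """
    rng = np.random.SeedSequence(seed)
    atlas = ShapeAtlas(variance_cutoff=cfg.variance_cutoff).fit(internal_shapes)
    int_prof = add_risk_columns(internal_clinical)
    ext_prof = add_risk_columns(external_clinical)
    ext_scores_all = (
        atlas.training_scores_ if external_is_internal else atlas.transform(external_shapes)
    )
    results, models, roc_tables = [], {}, {}
    for factor, child in zip(cfg.factors, rng.spawn(len(cfg.factors))):
        cv_seed, boot_seed = (int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2))
        r_int, n_int = assign_groups(int_prof, factor)
        r_ext, n_ext = assign_groups(ext_prof, factor)
        rows_int = np.concatenate([r_int, n_int])
        y_int = np.concatenate([np.ones(len(r_int), int), np.zeros(len(n_int), int)])
        x_int = build_predictors(int_prof, atlas.training_scores_, rows=rows_int)

        ncomp = select_ncomp(
            x_int, y_int, folds=cfg.cv_folds, grid=cfg.component_grid, seed=cv_seed
        )
        s_loo = loo_scores(x_int, y_int, ncomp)
        roc_int = roc_auc(s_loo, y_int)
        roc_int.ci = bootstrap_auc_ci(s_loo, y_int, n_boot=cfg.n_boot, seed=boot_seed)

        model = RiskFactorDiscriminator(
            n_components=ncomp, factor=factor, random_state=cv_seed
        ).fit(x_int, y_int)

        rows_ext = np.concatenate([r_ext, n_ext])
        y_ext = np.concatenate([np.ones(len(r_ext), int), np.zeros(len(n_ext), int)])
        x_ext = build_predictors(ext_prof, ext_scores_all, rows=rows_ext)
        s_ext = model.decision_function(x_ext)
        roc_ext = roc_auc(s_ext, y_ext)
        roc_ext.ci = bootstrap_auc_ci(s_ext, y_ext, n_boot=cfg.n_boot, seed=boot_seed + 1)

        z, p = compare_auc_unpaired(roc_int, roc_ext)
        results.append(
            FactorResult(
                factor=factor,
                atlas=atlas_name,
                n_components_retained=atlas.n_components_,
                n_plsr_components=ncomp,
                n_risk_internal=len(r_int),
                n_norisk_internal=len(n_int),
                n_risk_external=len(r_ext),
                n_norisk_external=len(n_ext),
                internal_auc=roc_int.auc,
                internal_ci=tuple(round(v, 6) for v in roc_int.ci),
                external_auc=roc_ext.auc,
                external_ci=tuple(round(v, 6) for v in roc_ext.ci),
                z_statistic=round(float(z), 6),
                p_value=float(p),
                generalisable=bool(p > 0.05 and _ci_overlap(roc_int.ci, roc_ext.ci)),
            )
        )
        models[factor] = model
        roc_tables[factor] = {
            "internal": roc_int.thresholds,
            "external": roc_ext.thresholds,
        }
    context = {
        "atlas": atlas,
        "models": models,
        "internal_profiled": int_prof,
        "roc_tables": roc_tables,
    }
    return results, context


def run_experiment(cfg: ExperimentConfig) -> GeneralisabilityReport:
    """Run the full two-direction generalisability experiment."""
    shapes_a, clin_a = generate_cohort(cfg.cohort_a)
    shapes_b, clin_b = generate_cohort(cfg.cohort_b)
    ss = np.random.SeedSequence(cfg.seed)
    seed_ab, seed_ba = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    res_a, ctx_a = evaluate_direction(
        shapes_a, clin_a, shapes_b, clin_b, cfg, cfg.names[0], seed_ab
    )
    res_b, ctx_b = evaluate_direction(
        shapes_b, clin_b, shapes_a, clin_a, cfg, cfg.names[1], seed_ba
    )
    report = GeneralisabilityReport(
        results=res_a + res_b,
        factors=cfg.factors,
        seed=cfg.seed,
        version=__version__,
        config_digest=_config_digest(cfg),
    )
    report._context = {  # non-serialised artifacts for rendering
        cfg.names[0]: ctx_a | {"shapes": shapes_a, "clinical": clin_a},
        cfg.names[1]: ctx_b | {"shapes": shapes_b, "clinical": clin_b},
        "config": cfg,
    }
    return report


def render_report(report: GeneralisabilityReport, out_dir) -> None:
    """Persist the report: JSON, Table-1/2/3-style CSVs, ROC sweeps and
    +/- effect contour meshes (when the run context is attached)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.table().to_csv(out / "table3.csv", index=False)

    ctx = getattr(report, "_context", None)
    if ctx is None:
        return
    cfg: ExperimentConfig = ctx["config"]
    names = cfg.names
    prof = {n: ctx[n]["internal_profiled"] for n in names}

    # Table-1 analogue: cohort composition comparison
    variables = {
        "age": "continuous", "sex": "categorical", "bmi": "continuous",
        "sbp_mmhg": "continuous", "dbp_mmhg": "continuous",
        "hba1c_mmol_mol": "continuous", "ldl_mg_dl": "continuous",
        **{f: "categorical" for f in FACTORS}, "no_risk": "categorical",
    }
    cohort_table(prof[names[0]], prof[names[1]], variables, names=names).to_csv(
        out / "table1.csv", index=False
    )

    # Table-2 analogue: LV measures of exactly matched no-risk cases
    topo = default_topology(cfg.cohort_a.geometry)
    norisk = {n: prof[n][prof[n]["no_risk"]] for n in names}
    match = match_no_risk(norisk[names[0]], norisk[names[1]])
    if match.n_pairs:
        meas = {}
        for k, n in enumerate(names):
            ids = match.ids(k)
            meas[n] = measures_table(
                ctx[n]["shapes"][np.asarray(ids)], topo, prof[n].loc[ids]
            )
        mvars = {v: "continuous" for v in ("lvedvi", "lvesvi", "lvmi", "ef_pct")}
        cohort_table(meas[names[0]], meas[names[1]], mvars, names=names).to_csv(
            out / "table2.csv", index=False
        )

    # ROC sweeps and effect contours
    (out / "roc").mkdir(exist_ok=True)
    (out / "contours").mkdir(exist_ok=True)
    for name in names:
        atlas = ctx[name]["atlas"]
        for factor, tables in ctx[name]["roc_tables"].items():
            for side, table in tables.items():
                table.to_csv(out / "roc" / f"{name}_{factor}_{side}.csv", index=False)
        for factor, model in ctx[name]["models"].items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plus, minus = shape_effect_contours(model, atlas, magnitude=2.0)
            for tag, shp in (("plus", plus), ("minus", minus)):
                meshes = meshes_from_shape(shp, topo)
                export_mesh_ply(
                    out / "contours" / f"{name}_{factor}_{tag}_endo_ED.ply",
                    meshes["endo_ED"],
                )


def self_generalisability(cfg: ExperimentConfig, which: str = "a"):
    """Run one cohort against itself as its own 'external' cohort (the
    internal and external AUCs should then agree closely)."""
    cohort_cfg = cfg.cohort_a if which == "a" else cfg.cohort_b
    shapes, clin = generate_cohort(cohort_cfg)
    results, _ = evaluate_direction(
        shapes, clin, shapes, clin, cfg, "self", cfg.seed, external_is_internal=True
    )
    return results
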