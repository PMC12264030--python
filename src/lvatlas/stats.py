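"""ROC/AUC machinery, bootstrap CIs, unpaired AUC comparison, thresholds,
exact age/sex matching and cohort comparison tables.

The AUC is the Mann-Whitney rank statistic (ties count one half). The
unpaired internal-vs-external comparison uses a z statistic with per-curve
DeLong variances, z = (AUC1 - AUC2) / sqrt(V1 + V2); a Welch t test on
bootstrap replicates is available behind a flag as the alternative reading
of the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import InvalidParameterError

__all__ = [
    "RocSummary",
    "MatchResult",
    "roc_auc",
    "auc_rank",
    "delong_variance",
    "bootstrap_auc_ci",
    "compare_auc_unpaired",
    "optimal_threshold",
    "match_no_risk",
    "cohort_table",
]


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise InvalidParameterError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidParameterError("both classes must be present")
    return pos, neg


def auc_rank(scores, labels) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    return (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate (structural components)."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass
class RocSummary:
    """Scores, labels, AUC with bootstrap CI and the full threshold sweep."""

    scores: np.ndarray
    labels: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None
    n_risk: int = 0
    n_norisk: int = 0
    thresholds: pd.DataFrame = field(default_factory=pd.DataFrame)


def roc_auc(scores, labels) -> RocSummary:
    """AUC by rank statistic plus the full ROC threshold table."""
    pos, neg = _split(scores, labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = auc_rank(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    table = pd.DataFrame(
        {"threshold": thr, "sensitivity": tpr, "specificity": 1.0 - fpr}
    )
    return RocSummary(
        scores=scores, labels=labels, auc=float(auc),
        n_risk=len(pos), n_norisk=len(neg), thresholds=table,
    )


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int | None = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI with stratified case resampling.

    Resampling within each class keeps every replicate two-class by
    construction, so no degenerate redraws are needed.
    """
    pos, neg = _split(scores, labels)
    rng = np.random.default_rng(seed)
    m, n = len(pos), len(neg)
    reps = np.empty(n_boot)
    y = np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)])
    for b in range(n_boot):
        s = np.concatenate(
            [pos[rng.integers(0, m, m)], neg[rng.integers(0, n, n)]]
        )
        reps[b] = auc_rank(s, y)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_auc_unpaired(
    roc1: RocSummary, roc2: RocSummary, method: str = "delong",
    n_boot: int = 2000, seed: int | None = 0,
) -> tuple[float, float]:
    """Two-sided test of AUC1 = AUC2 for independent test sets.

    ``method="delong"`` (default): z with per-curve DeLong variances.
    ``method="welch-bootstrap"``: Welch t test on bootstrap AUC replicates.
    """
    if method == "delong":
        v1 = delong_variance(roc1.scores, roc1.labels)
        v2 = delong_variance(roc2.scores, roc2.labels)
        var = v1 + v2
        diff = roc1.auc - roc2.auc
        if var <= 0:
            if diff == 0:
                return 0.0, 1.0
            raise InvalidParameterError(
                "degenerate AUC variances; comparison p-value undefined"
            )
        z = diff / np.sqrt(var)
        return float(z), float(2.0 * sps.norm.sf(abs(z)))
    if method == "welch-bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for roc in (roc1, roc2):
            pos, neg = _split(roc.scores, roc.labels)
            m, n = len(pos), len(neg)
            y = np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)])
            r = np.empty(n_boot)
            for b in range(n_boot):
                s = np.concatenate(
                    [pos[rng.integers(0, m, m)], neg[rng.integers(0, n, n)]]
                )
                r[b] = auc_rank(s, y)
            reps.append(r)
        t, p = sps.ttest_ind(reps[0], reps[1], equal_var=False)
        return float(t), float(p)
    raise InvalidParameterError(f"unknown comparison method: {method!r}")


def optimal_threshold(roc: RocSummary) -> tuple[float, float, float]:
    """Operating point maximising Youden J = sensitivity + specificity - 1.

    Ties resolve to the lowest threshold. If every score is identical the
    single degenerate threshold is returned with a warning.
    """
    t = roc.thresholds
    finite = t[np.isfinite(t["threshold"])]
    if finite.empty or np.ptp(roc.scores) == 0:
        warnings.warn("degenerate ROC: all scores equal", stacklevel=2)
        thr = float(roc.scores[0])
        pos = roc.labels == 1
        return thr, 1.0, 0.0  # everything called positive at the single threshold
    j = finite["sensitivity"] + finite["specificity"] - 1.0
    best_j = j.max()
    candidates = finite[np.isclose(j, best_j)]
    row = candidates.loc[candidates["threshold"].idxmin()]
    return float(row["threshold"]), float(row["sensitivity"]), float(row["specificity"])


@dataclass
class MatchResult:
    """1:1 exactly matched case pairs between two cohorts."""

    pairs: list  # [(id_cohort1, id_cohort2), ...]
    variables: tuple = ("age", "sex")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def ids(self, which: int) -> list:
        return [p[which] for p in self.pairs]


def match_no_risk(table1: pd.DataFrame, table2: pd.DataFrame,
                  variables=("age", "sex")) -> MatchResult:
    """Exact 1:1 matching on the given variables (age and sex by default).

    Only age and sex enter the propensity score, so nearest matching
    reduces to exact-cell matching; within a cell, cases pair in input
    order and unmatched cases are dropped. Matched sub-cohorts therefore
    have identical age/sex multisets.
    """
    variables = tuple(variables)
    cells1: dict[tuple, list] = {}
    cells2: dict[tuple, list] = {}
    for cells, table in ((cells1, table1), (cells2, table2)):
        for idx, row in table.iterrows():
            key = tuple(row[v] for v in variables)
            cells.setdefault(key, []).append(idx)
    pairs = []
    for key in cells1:
        if key in cells2:
            for a, b in zip(cells1[key], cells2[key]):
                pairs.append((a, b))
    if not pairs:
        warnings.warn("no exactly matching cases between cohorts", stacklevel=2)
    return MatchResult(pairs=pairs, variables=variables)


def cohort_table(
    table1: pd.DataFrame, table2: pd.DataFrame, variables: dict[str, str],
    names=("cohort1", "cohort2"),
) -> pd.DataFrame:
    """Per-variable comparison between two cohorts.

    ``variables`` maps column name -> "continuous" (Wilcoxon rank-sum,
    mean +/- SD summary) or "categorical" (Pearson chi-squared, n (%)
    summary).
    """
    rows = []
    for var, kind in variables.items():
        a, b = table1[var], table2[var]
        if kind == "continuous":
            stat_p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
            s1 = f"{a.mean():.1f}±{a.std(ddof=1):.1f}"
            s2 = f"{b.mean():.1f}±{b.std(ddof=1):.1f}"
        elif kind == "categorical":
            levels = sorted(set(a.unique()) | set(b.unique()))
            counts = np.array(
                [[(a == lv).sum() for lv in levels], [(b == lv).sum() for lv in levels]]
            )
            if counts.shape[1] < 2:
                stat_p = 1.0
            else:
                stat_p = sps.chi2_contingency(counts).pvalue
            top = levels[-1] if set(levels) <= {0, 1, False, True} else levels[0]
            n1, n2 = (a == top).sum(), (b == top).sum()
            s1 = f"{n1} ({100.0 * n1 / len(a):.0f}%)"
            s2 = f"{n2} ({100.0 * n2 / len(b):.0f}%)"
        else:
            raise InvalidParameterError(f"unknown variable type: {kind!r}")
        rows.append({"variable": var, names[0]: s1, names[1]: s2, "p_value": float(stat_p)})
    return pd.DataFrame(rows)
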