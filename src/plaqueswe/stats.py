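"""Cohort-level statistical evaluation.

Acquisition-level velocities are first summarised per plaque (mean and
sample SD over passing acquisitions), then evaluated two ways:

* AHA-type group comparison - the complex, rupture-prone type VI
  plaques are tested against each of the other types with a two-sided
  Wilcoxon rank-sum test, separately per velocity metric and imaging
  view. A metric "differentiates type VI from all others" when every
  pairwise p-value is below 0.05 (0.01 for the strict flag).
* Correlation screen - each velocity metric is correlated (Pearson and
  Spearman) against every MRI-derived component and lipid covariate,
  using pairwise-complete observations; a correlation is flagged when
  |R| >= 0.5 and p < 0.05 for the respective coefficient.

Wilcoxon p-values are exact (full enumeration of rank assignments) when
the combined sample size is at most 12 and there are no ties - the
regime of the 4-8 plaque groups here - and otherwise use the normal
approximation with tie and continuity corrections. No multiple-testing
correction is applied anywhere; the report records the number of tests
performed instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import AHA_TYPES, CohortTable, METRICS, VIEWS

__all__ = [
    "aggregate_plaque",
    "wilcoxon_rank_sum",
    "GroupComparisonResult",
    "compare_aha_groups",
    "CorrelationResult",
    "correlate",
    "EvaluationReport",
    "run_full_evaluation",
]

EXACT_MAX_COMBINED_N = 12
REFERENCE_GROUP = "VI"


def aggregate_plaque(values: Sequence[float]) -> tuple[float, float, int]:
    """Per-plaque summary of passing acquisition values.

    Returns (mean, sample SD, n); the SD uses the n-1 denominator and is
    0 for a single acquisition. Raises on an empty input - the metric is
    then undefined for that plaque.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no passing acquisitions; metric undefined for this plaque")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd, int(v.size)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample size is <= 12 and the
    pooled values are tie-free; otherwise the normal approximation with
    tie correction and continuity correction. The returned p lies in
    (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MAX_COMBINED_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(1.0, max(res.pvalue, np.finfo(float).tiny)))


@dataclass(frozen=True)
class GroupComparisonResult:
    metric: str
    view: str
    p_values: dict[str, float]  # other AHA type -> p (nan when undefined)
    n_per_group: dict[str, int]
    significant_all: bool  # every pairwise p < 0.05
    significant_all_strict: bool  # every pairwise p < 0.01


def compare_aha_groups(
    cohort: CohortTable, metric: str, view: str, reference: str = REFERENCE_GROUP
) -> GroupComparisonResult:
    """Test the reference AHA type against every other type present.

    Uses per-plaque metric means in the given view; plaques without a
    defined value are dropped. A pair with an empty group is undefined
    (p = nan) and forces both significance flags to False.
    """
    col = f"{metric}_mean"
    if col not in cohort.data.columns:
        raise ValueError(f"cohort table has no column {col!r}")
    sub = cohort.data[cohort.data["view"] == view]
    groups = {
        a: sub.loc[sub["aha_type"] == a, col].dropna().to_numpy()
        for a in AHA_TYPES
    }
    others = [a for a in AHA_TYPES if a != reference]
    p_values: dict[str, float] = {}
    for a in others:
        if groups[reference].size == 0 or groups[a].size == 0:
            p_values[a] = float("nan")
        else:
            p_values[a] = wilcoxon_rank_sum(groups[reference], groups[a])
    defined = all(np.isfinite(p) for p in p_values.values())
    return GroupComparisonResult(
        metric=metric,
        view=view,
        p_values=p_values,
        n_per_group={a: int(g.size) for a, g in groups.items()},
        significant_all=bool(defined and all(p < 0.05 for p in p_values.values())),
        significant_all_strict=bool(defined and all(p < 0.01 for p in p_values.values())),
    )


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    view: str
    covariate: str
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    n_used: int
    defined: bool
    flagged_pearson: bool
    flagged_spearman: bool

    @property
    def flagged(self) -> bool:
        return self.flagged_pearson or self.flagged_spearman


def _flag(r: float, p: float) -> bool:
    return bool(np.isfinite(r) and np.isfinite(p) and abs(r) >= 0.5 and p < 0.05)


def correlate(cohort: CohortTable, metric: str, view: str, covariate: str) -> CorrelationResult:
    """Pearson and Spearman correlation of a velocity metric against one
    covariate, over pairwise-complete plaques in the given view.

    Plaques where the covariate (or the metric) is undefined are
    excluded from this particular analysis. Fewer than 3 complete pairs
    make the result undefined (and never flagged). Pearson p-values use
    the t-distribution with n-2 df; Spearman p-values the same
    t-approximation on the rank correlation (average ranks for ties).
    """
    col = f"{metric}_mean"
    for c in (col, covariate):
        if c not in cohort.data.columns:
            raise ValueError(f"cohort table has no column {c!r}")
    sub = cohort.data[cohort.data["view"] == view]
    xy = sub[[col, covariate]].dropna()
    n = len(xy)
    if n < 3 or xy[col].nunique() < 2 or xy[covariate].nunique() < 2:
        nan = float("nan")
        return CorrelationResult(metric, view, covariate, nan, nan, nan, nan, n, False, False, False)
    pr = sps.pearsonr(xy[col], xy[covariate])
    sr = sps.spearmanr(xy[col], xy[covariate])
    return CorrelationResult(
        metric=metric,
        view=view,
        covariate=covariate,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n_used=n,
        defined=True,
        flagged_pearson=_flag(pr.statistic, pr.pvalue),
        flagged_spearman=_flag(sr.statistic, sr.pvalue),
    )


@dataclass(frozen=True)
class EvaluationReport:
    group_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    n_tests: int

    def summary(self) -> dict:
        gc = self.group_comparisons
        corr = self.correlations
        return {
            "n_tests": self.n_tests,
            "multiple_testing_correction": "none",
            "significant_all": [
                {"metric": r.metric, "view": r.view, "strict": bool(r.significant_all_strict)}
                for r in gc.itertuples()
                if r.significant_all
            ],
            "flagged_correlations": [
                {
                    "metric": r.metric,
                    "view": r.view,
                    "covariate": r.covariate,
                    "pearson_r": None if not np.isfinite(r.pearson_r) else round(r.pearson_r, 3),
                    "spearman_r": None if not np.isfinite(r.spearman_r) else round(r.spearman_r, 3),
                }
                for r in corr.itertuples()
                if r.flagged
            ],
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.group_comparisons.to_csv(out / "group_comparisons.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_full_evaluation(
    cohort: CohortTable,
    metrics: Optional[Sequence[str]] = None,
    views: Sequence[str] = VIEWS,
) -> EvaluationReport:
    """Group comparisons and correlation screens for every metric x view.

    Covers each velocity metric present in the table against every
    component and lipid covariate column. Deterministic given the
    cohort table.
    """
    metrics = list(metrics) if metrics is not None else cohort.metric_columns()
    covariates = cohort.covariate_columns()

    gc_rows = []
    for metric in metrics:
        for view in views:
            res = compare_aha_groups(cohort, metric, view)
            row = {"metric": metric, "view": view}
            for a, p in res.p_values.items():
                row[f"p_vs_{a}"] = p
            row["significant_all"] = res.significant_all
            row["significant_all_strict"] = res.significant_all_strict
            gc_rows.append(row)

    corr_rows = []
    for metric in metrics:
        for view in views:
            for cov in covariates:
                r = correlate(cohort, metric, view, cov)
                corr_rows.append(
                    {
                        "metric": metric,
                        "view": view,
                        "covariate": cov,
                        "pearson_r": r.pearson_r,
                        "pearson_p": r.pearson_p,
                        "spearman_r": r.spearman_r,
                        "spearman_p": r.spearman_p,
                        "n_used": r.n_used,
                        "defined": r.defined,
                        "flagged": r.flagged,
                    }
                )

    n_tests = sum(
        int(np.isfinite(p))
        for row in gc_rows
        for key, p in row.items()
        if key.startswith("p_vs_")
    ) + 2 * sum(r["defined"] for r in corr_rows)
    return EvaluationReport(
        group_comparisons=pd.DataFrame(gc_rows),
        correlations=pd.DataFrame(corr_rows),
        n_tests=n_tests,
    )
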