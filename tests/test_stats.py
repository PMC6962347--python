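"""Cohort statistics: aggregation, rank tests, correlation screens."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plaqueswe import (
    CohortSimConfig,
    CohortTable,
    aggregate_plaque,
    compare_aha_groups,
    correlate,
    run_full_evaluation,
    simulate_cohort,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p over all rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestAggregatePlaque:
    def test_two_values(self):
        mean, sd, n = aggregate_plaque([4.0, 6.0])
        assert mean == 5.0 and n == 2
        assert sd == pytest.approx(np.sqrt(2))

    def test_single_value_degenerate(self):
        assert aggregate_plaque([5.1]) == (5.1, 0.0, 1)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no passing"):
            aggregate_plaque([])

    def test_sampling_distribution_of_mean(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            vals = 5.0 + rng.normal(0, 1.0, size=15)
            mean, _, _ = aggregate_plaque(vals)
            hits += abs(mean - 5.0) < 1.0
        assert hits / 200 >= 0.95


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.permutation(np.arange(12.0))[:5]
            y = rng.permutation(np.arange(100.0, 112.0))[: rng.integers(3, 7)]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(exact_rank_sum_p(x, y))

    def test_approximation_close_to_exact_at_6_plus_6(self):
        rng = np.random.default_rng(2)
        diffs = []
        for _ in range(100)  :
            pooled = rng.normal(size=12) + rng.uniform(0, 1)
            x, y = pooled[:6], pooled[6:] + rng.uniform(0, 1.5)
            p_exact = exact_rank_sum_p(x, y)
            # force the asymptotic branch by adding a tied duplicate pair
            x2 = np.concatenate([x, [y[0]]])
            y2 = np.concatenate([y, [y[0]]])
            p_full_exact = exact_rank_sum_p(x2, y2)
            p_approx = wilcoxon_rank_sum(x2, y2)
            diffs.append(abs(p_approx - p_full_exact))
        assert max(diffs) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=25, derandomize=True)
    @given(shift=st.floats(min_value=-5, max_value=5), scale=st.floats(min_value=0.1, max_value=10))
    def test_invariant_under_monotone_transform(self, shift, scale):
        x = np.array([0.3, 1.2, 2.9, 4.1])
        y = np.array([0.9, 2.2, 3.3, 5.6, 6.0])
        p0 = wilcoxon_rank_sum(x, y)
        assert wilcoxon_rank_sum(scale * x + shift, scale * y + shift) == pytest.approx(p0)
        assert wilcoxon_rank_sum(np.exp(x), np.exp(y)) == pytest.approx(p0)


def _toy_cohort(values_by_group, view="T", metric="group_velocity", covariates=None):
    rows = []
    i = 0
    for aha, vals in values_by_group.items():
        for v in vals:
            row = {
                "plaque_id": f"P{i:03d}",
                "subject_id": f"S{i:03d}",
                "view": view,
                "aha_type": aha,
                f"{metric}_mean": v,
                f"{metric}_sd": 0.0,
                f"{metric}_n": 1,
            }
            if covariates:
                for name, arr in covariates.items():
                    row[name] = arr[i]
            rows.append(row)
            i += 1
    return CohortTable(pd.DataFrame(rows))


class TestCompareAhaGroups:
    def test_separated_reference_group_flags(self):
        t = _toy_cohort(
            {
                "III": [3.0, 3.1, 3.2, 3.3],
                "V": [3.4, 3.5, 3.6, 3.7],
                "VI": [7.0, 7.1, 7.2, 7.3, 7.4],
                "VII": [3.0, 3.2, 3.4, 3.6],
            }
        )
        res = compare_aha_groups(t, "group_velocity", "T")
        assert res.significant_all
        assert all(p < 0.05 for p in res.p_values.values())

    def test_empty_group_makes_pair_undefined(self):
        t = _toy_cohort({"III": [3.0, 3.1, 3.5], "VI": [7.0, 7.2, 7.4, 7.6]})
        res = compare_aha_groups(t, "group_velocity", "T")
        assert np.isnan(res.p_values["V"]) and np.isnan(res.p_values["VII"])
        assert not res.significant_all


class TestCorrelate:
    def test_exact_linear_relation(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t = _toy_cohort({"III": vals}, covariates={"lrnc_pct": 2 * vals + 1})
        res = correlate(t, "group_velocity", "T", "lrnc_pct")
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_r == pytest.approx(1.0)
        assert res.flagged

    def test_spearman_hand_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # rank displacements d = (-1, 1, -1, 1, 0): 1 - 6*4/(5*24) = 0.8
        t = _toy_cohort({"III": x}, covariates={"lrnc_pct": y})
        res = correlate(t, "group_velocity", "T", "lrnc_pct")
        assert res.spearman_r == pytest.approx(0.8)

    def test_missing_values_excluded_pairwise(self):
        vals = np.arange(1.0, 9.0)
        cov = 3 * vals
        cov[2] = np.nan
        t = _toy_cohort({"III": vals}, covariates={"lrnc_pct": cov})
        res = correlate(t, "group_velocity", "T", "lrnc_pct")
        assert res.n_used == 7
        assert res.pearson_r == pytest.approx(1.0)

    def test_fewer_than_three_pairs_undefined(self):
        vals = np.arange(1.0, 6.0)
        cov = np.full(5, np.nan)
        cov[:2] = [1.0, 2.0]
        t = _toy_cohort({"III": vals}, covariates={"lrnc_pct": cov})
        res = correlate(t, "group_velocity", "T", "lrnc_pct")
        assert not res.defined and not res.flagged

    @settings(max_examples=20, derandomize=True)
    @given(a=st.floats(min_value=0.1, max_value=5), b=st.floats(min_value=-3, max_value=3))
    def test_pearson_affine_spearman_monotone_invariance(self, a, b):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        y = 0.7 * x + rng.normal(size=12)
        t1 = _toy_cohort({"III": x}, covariates={"lrnc_pct": y})
        t2 = _toy_cohort({"III": a * x + b}, covariates={"lrnc_pct": np.exp(y)})
        r1 = correlate(t1, "group_velocity", "T", "lrnc_pct")
        r2 = correlate(t2, "group_velocity", "T", "lrnc_pct")
        assert r2.spearman_r == pytest.approx(r1.spearman_r)
        t3 = _toy_cohort({"III": a * x + b}, covariates={"lrnc_pct": a * y + b})
        r3 = correlate(t3, "group_velocity", "T", "lrnc_pct")
        assert r3.pearson_r == pytest.approx(r1.pearson_r)


class TestRunFullEvaluation:
    def test_structure_and_determinism(self, tmp_path):
        t = simulate_cohort(CohortSimConfig(seed=6))
        rep1 = run_full_evaluation(t)
        assert len(rep1.group_comparisons) == 8  # 4 metrics x 2 views
        rep2 = run_full_evaluation(t)
        assert rep1.group_comparisons.equals(rep2.group_comparisons)
        assert rep1.correlations.equals(rep2.correlations)
        rep1.write(tmp_path / "report")
        assert (tmp_path / "report" / "summary.json").exists()

    def test_fully_missing_component_undefined(self):
        cfg = CohortSimConfig(seed=7, missing_fraction=1.0)
        t = simulate_cohort(cfg)
        rep = run_full_evaluation(t)
        rows = rep.correlations[rep.correlations["covariate"] == "lrnc_pct"]
        assert not rows["defined"].any()

    def test_malformed_table_names_column(self):
        with pytest.raises(ValueError, match="aha_type"):
            CohortTable(pd.DataFrame({"plaque_id": [], "subject_id": [], "view": []}))
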