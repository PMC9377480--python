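"""Study statistics: exact rank tests against brute-force enumeration,
Cronbach alpha against a hand-computed fixture, the noncentral-t power
search against simulation and statsmodels, and the summary-table layouts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hautil import (
    AssessmentMethod,
    KnowledgeScores,
    ValidationError,
    change_scores,
    cronbach_alpha,
    power_two_sample_t,
    ranking_proportions,
    rank_sum_test,
    sample_size_two_sample_t,
    signed_rank_test,
    stratified_summary,
    subgroup_decrement,
    vintage_correlation,
)
from hautil.analysis import APPROX, EXACT


def brute_force_rank_sum_p(a, b):
    """Independent oracle: enumerate label permutations via rank vectors."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    mu = n_a * (len(pooled) + 1) / 2
    obs = ranks[:n_a].sum()
    hits = total = 0
    for perm in itertools.permutations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(perm)].sum() - mu) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / total


def brute_force_signed_rank_p(d):
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    mu = len(d) * (len(d) + 1) / 4
    obs = ranks[d > 0].sum()
    hits = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        total += 1
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestChangeScores:
    def test_per_patient_and_summary(self):
        scores = [
            KnowledgeScores("a", 79, 89),
            KnowledgeScores("b", 50, 50),
            KnowledgeScores("c", 100, 90),
        ]
        out = change_scores(scores)
        assert out["per_patient"] == {"a": 10.0, "b": 0.0, "c": -10.0}
        assert out["mean"] == pytest.approx(0.0)
        assert out["median"] == pytest.approx(0.0)

    def test_item_vector_consistency_enforced(self):
        KnowledgeScores("a", 30, 40, items_pre=(1, 1, 1, 0, 0, 0, 0, 0, 0, 0))
        with pytest.raises(ValidationError):
            KnowledgeScores("a", 40, 40, items_pre=(1, 1, 1, 0, 0, 0, 0, 0, 0, 0))


class TestCronbachAlpha:
    def test_perfect_consistency(self):
        v = np.array([1, 0, 1, 0, 1])
        assert cronbach_alpha(np.column_stack([v, v, v])) == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        matrix = [(1, 1, 0), (1, 0, 0), (1, 1, 1), (0, 0, 0)]
        assert cronbach_alpha(matrix) == pytest.approx(0.75)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValidationError):
            cronbach_alpha(np.ones((4, 3)))

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = rng.integers(0, 2, size=(8, 5)).astype(float)
            if m.sum(axis=1).var(ddof=1) == 0:
                continue
            assert cronbach_alpha(m) <= 1.0 + 1e-12


class TestRankSum:
    def test_enumerated_example(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == EXACT
        assert res.p_value == pytest.approx(1 / 3)

    def test_no_separation(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=rng.integers(2, 5)).astype(float)
        b = rng.integers(0, 5, size=rng.integers(2, 5)).astype(float)
        res = rank_sum_test(a, b)
        assert res.method == EXACT
        assert res.p_value == pytest.approx(brute_force_rank_sum_p(a, b))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=5), rng.normal(size=6)
        res = rank_sum_test(a, b)
        expected = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(expected.pvalue)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(8)
        res = rank_sum_test(rng.normal(size=30), rng.normal(0.5, size=30))
        assert res.method == APPROX
        assert 0 < res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


class TestSignedRank:
    def test_enumerated_example(self):
        res = signed_rank_test([1, 2, 3])
        assert res.method == EXACT
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_degenerate(self):
        with pytest.raises(ValidationError):
            signed_rank_test([0, 0, 0])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-4, 5, size=rng.integers(3, 10)).astype(float)
        if (d != 0).sum() == 0:
            d[0] = 1.0
        res = signed_rank_test(d)
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d))

    def test_exact_matches_scipy_without_ties(self):
        d = np.array([1.3, -0.7, 2.1, 3.9, -1.8, 0.4, 2.6])
        res = signed_rank_test(d)
        expected = sps.wilcoxon(d, alternative="two-sided", mode="exact")
        assert res.p_value == pytest.approx(expected.pvalue)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        res = signed_rank_test(rng.normal(0.5, 1, size=40))
        assert res.method == APPROX
        assert 0 < res.p_value <= 1


class TestRankingProportions:
    @staticmethod
    def frame(n, k):
        """k of n patients rate the HCV-viremic transplant below hemodialysis."""
        hemo = np.full(n, 80.0)
        hcv = np.where(np.arange(n) < k, 70.0, 90.0)
        return pd.DataFrame(
            {
                "utility_sg_hemodialysis": hemo,
                "utility_sg_tx_hcv_viremic": hcv,
                "utility_tto_hemodialysis": hemo,
                "utility_tto_tx_hcv_viremic": hcv,
            }
        )

    def test_printed_counts_give_printed_percents(self):
        out = ranking_proportions(self.frame(63, 47), AssessmentMethod.SG)
        assert (out["count"], out["percent"]) == (47, 75)
        out = ranking_proportions(self.frame(63, 39), AssessmentMethod.TTO)
        assert (out["count"], out["percent"]) == (39, 62)

    def test_boundary_cases(self):
        assert ranking_proportions(self.frame(10, 10), AssessmentMethod.SG)["percent"] == 100
        assert ranking_proportions(self.frame(10, 0), AssessmentMethod.SG)["percent"] == 0

    def test_missing_values_excluded_and_counted(self):
        df = self.frame(10, 5)
        df.loc[0, "utility_sg_hemodialysis"] = np.nan
        out = ranking_proportions(df, AssessmentMethod.SG)
        assert out["excluded"] == 1 and out["n"] == 9

    def test_order_and_affine_invariance(self):
        df = self.frame(20, 13)
        base = ranking_proportions(df, AssessmentMethod.SG)["percent"]
        shuffled = df.sample(frac=1, random_state=0)
        assert ranking_proportions(shuffled, AssessmentMethod.SG)["percent"] == base
        scaled = df.copy()
        for c in scaled.columns:
            scaled[c] = scaled[c] * 0.5 + 3
        assert ranking_proportions(scaled, AssessmentMethod.SG)["percent"] == base


class TestVintageCorrelation:
    @staticmethod
    def frame(decrement, vintage):
        return pd.DataFrame(
            {
                "utility_sg_hemodialysis": np.zeros(len(decrement)),
                "utility_sg_tx_hcv_viremic": decrement,
                "vintage_years": vintage,
            }
        )

    def test_perfect_negative_linear(self):
        vintage = np.array([1.0, 2, 3, 4, 5])
        assert vintage_correlation(self.frame(-2 * vintage, vintage)) == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        with pytest.raises(ValidationError):
            vintage_correlation(self.frame(np.arange(5.0), np.full(5, 3.0)))

    def test_toy_table_matches_hand_computation(self):
        dec = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        vin = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # hand: covariance ratio
        r_hand = np.cov(dec, vin, ddof=1)[0, 1] / (dec.std(ddof=1) * vin.std(ddof=1))
        assert vintage_correlation(self.frame(dec, vin)) == pytest.approx(r_hand)


class TestSubgroupDecrement:
    @staticmethod
    def frame(with_prior, without_prior):
        dec = np.concatenate([with_prior, without_prior])
        return pd.DataFrame(
            {
                "utility_sg_hemodialysis": np.zeros(len(dec)),
                "utility_sg_tx_hcv_viremic": dec,
                "prior_transplant": [True] * len(with_prior) + [False] * len(without_prior),
            }
        )

    def test_constructed_level_means(self):
        out = subgroup_decrement(self.frame([-20.6, -10.6], [-5.5, -5.5]))
        assert out["mean_with_prior"] == pytest.approx(-15.6)
        assert out["mean_without_prior"] == pytest.approx(-5.5)

    def test_identical_groups(self):
        out = subgroup_decrement(self.frame([-5.0, -5.0], [-5.0, -5.0]))
        assert out["mean_with_prior"] == out["mean_without_prior"]
        assert out["comparison"].p_value == pytest.approx(1.0)

    def test_one_patient_per_level_uses_exact_route(self):
        out = subgroup_decrement(self.frame([-7.0], [-3.0]))
        assert out["comparison"].method == EXACT

    def test_empty_level_rejected(self):
        with pytest.raises(ValidationError):
            subgroup_decrement(self.frame([], [-1.0, 2.0]))


class TestPower:
    def test_standardized_difference_of_one(self):
        assert sample_size_two_sample_t(1.0, 1.0, 0.05, 0.80) == 17

    def test_study_design_n(self):
        assert sample_size_two_sample_t(12, 16.3, 0.05, 0.80) == 30

    def test_matches_statsmodels(self):
        import math

        from statsmodels.stats.power import TTestIndPower

        for d in (0.4, 0.7, 1.0):
            ours = sample_size_two_sample_t(d, 1.0, 0.05, 0.80)
            ref = math.ceil(
                TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.80)
            )
            assert ours == ref

    def test_monotonicity(self):
        assert sample_size_two_sample_t(6, 16.3) >= sample_size_two_sample_t(12, 16.3)
        assert sample_size_two_sample_t(12, 20.0) >= sample_size_two_sample_t(12, 16.3)
        assert sample_size_two_sample_t(12, 16.3, power=0.9) >= sample_size_two_sample_t(
            12, 16.3, power=0.8
        )

    def test_huge_effect_floors_at_two(self):
        assert sample_size_two_sample_t(1e6, 1.0) == 2

    def test_infeasible_power(self):
        with pytest.raises(ValidationError):
            sample_size_two_sample_t(1, 1, alpha=0.5, power=0.4)

    def test_returned_n_achieves_power_in_simulation(self):
        delta, sd = 12.0, 16.3
        n = sample_size_two_sample_t(delta, sd, 0.05, 0.80)
        rng = np.random.default_rng(2024)
        reps = 10_000
        a = rng.normal(0.0, sd, size=(reps, n))
        b = rng.normal(delta, sd, size=(reps, n))
        t, p = sps.ttest_ind(a, b, axis=1)
        hit = float(np.mean(p < 0.05))
        mc_se = np.sqrt(0.8 * 0.2 / reps)
        assert hit >= 0.80 - 2 * mc_se


class TestSummaryTables:
    def test_layout_and_order_invariance(self, sim_wide):
        table = stratified_summary(sim_wide, "arm")
        assert len(table) == 9  # 3 methods x 3 states
        assert {"overall_mean", "matched_mean", "mismatched_mean", "p_value"} <= set(
            table.columns
        )
        permuted = stratified_summary(sim_wide.sample(frac=1, random_state=1), "arm")
        pd.testing.assert_frame_equal(table, permuted)

    def test_single_level_stratifier_rejected(self, sim_wide):
        df = sim_wide.copy()
        df["arm"] = "matched"
        with pytest.raises(ValidationError):
            stratified_summary(df, "arm")

    def test_race_table(self, sim_wide):
        table = stratified_summary(sim_wide, "race")
        assert "african_american_mean" in table.columns
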