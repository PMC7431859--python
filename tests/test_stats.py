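from itertools import combinations as it_combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from immunoselect.stats import (
    GroupComparison,
    age_categories,
    bh_adjust,
    cliffs_d,
    compare_observed_scores,
    fisher_exact_2x2,
    mann_whitney_one_tailed,
    permutation_null,
)


def mw_exact_p_enumeration(x, y, alternative):
    """Oracle: exact one-tailed p by enumerating all rank splits (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    null_us = []
    for idx in it_combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        null_us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    null_us = np.array(null_us)
    if alternative == "greater":
        return (null_us >= u_obs).mean()
    return (null_us <= u_obs).mean()


def cliffs_d_brute(x, y):
    gt = sum(1 for xi in x for yj in y if xi > yj)
    lt = sum(1 for xi in x for yj in y if xi < yj)
    return (gt - lt) / (len(x) * len(y))


def bh_stepup_oracle(p):
    """Hand-applied BH: sort, multiply by m/i, enforce monotonicity, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        # {1,2,3} vs {4,5,6}: one split of C(6,3)=20 is as extreme -> p = 0.05
        u, p = mann_whitney_one_tailed([4, 5, 6], [1, 2, 3], "greater")
        assert p == pytest.approx(0.05)
        u2, p2 = mann_whitney_one_tailed([1, 2, 3], [4, 5, 6], "less")
        assert p2 == pytest.approx(0.05)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n, m = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            if n + m > 12:
                continue
            pool = rng.permutation(100)[: n + m].astype(float)  # distinct values
            x, y = pool[:n], pool[n:]
            for alt in ("greater", "less"):
                _, p = mann_whitney_one_tailed(x, y, alt)
                assert p == pytest.approx(mw_exact_p_enumeration(x, y, alt), abs=1e-12)

    def test_identical_samples_give_p_at_least_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = mann_whitney_one_tailed(x, x, "greater")
        assert p >= 0.5

    def test_u_plus_u_prime_is_nm(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=20)
        u_x, _ = mann_whitney_one_tailed(x, y, "greater")
        u_y, _ = mann_whitney_one_tailed(y, x, "greater")
        assert u_x + u_y == pytest.approx(len(x) * len(y))

    def test_exact_and_asymptotic_agree_at_boundary(self):
        """Normal approximation within 0.01 absolute p of enumeration at n+m=12."""
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(17)
        for _ in range(10):
            pool = rng.permutation(1000)[:12].astype(float)
            x, y = pool[:6], pool[6:]
            _, p_exact = mann_whitney_one_tailed(x, y, "greater")
            p_asym = mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0], "greater")


class TestCliffsD:
    def test_complete_separation_boundaries(self):
        assert cliffs_d([1, 2], [5, 6]) == -1.0
        assert cliffs_d([5, 6], [1, 2]) == 1.0

    def test_identical_samples_give_zero(self):
        x = [3.0, 1.0, 2.0]
        assert cliffs_d(x, x) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            x = rng.integers(0, 20, size=rng.integers(2, 60)).astype(float)
            y = rng.integers(0, 20, size=rng.integers(2, 60)).astype(float)
            assert cliffs_d(x, y) == pytest.approx(cliffs_d_brute(x, y), abs=1e-14)


class TestBHAdjust:
    def test_hand_applied_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_idempotent_on_adjusted_values(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=15)
        once = bh_adjust(p)
        np.testing.assert_allclose(bh_adjust(once), once, atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserved(self):
        p = [0.04, 0.001, 0.7]
        adj = bh_adjust(p)
        assert np.all(adj >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


class TestFisherExact:
    def test_balanced_table_or_one(self):
        odds, p = fisher_exact_2x2([[10, 10], [10, 10]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_sample_or_and_hypergeometric_p(self):
        # [[1,9],[11,3]]: sample OR = (1*3)/(9*11)
        odds, p = fisher_exact_2x2([[1, 9], [11, 3]])
        assert odds == pytest.approx(3 / 99)
        # two-sided exact p: sum of hypergeometric probabilities <= P(observed)
        rv = hypergeom(24, 10, 12)  # N, K (row1 total), n (col1 total)
        probs = np.array([rv.pmf(k) for k in range(0, 11)])
        expect = probs[probs <= rv.pmf(1) * (1 + 1e-9)].sum()
        assert p == pytest.approx(expect, rel=1e-8)

    def test_zero_cell_gives_flagged_infinite_or(self):
        odds, _ = fisher_exact_2x2([[5, 0], [2, 3]])
        assert np.isinf(odds)

    def test_zero_margin_flagged_degenerate(self):
        odds, p = fisher_exact_2x2([[0, 0], [2, 3]])
        assert np.isnan(odds) and p == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0.5, 1], [1, 1]])


class TestAgeCategories:
    def test_pan_cohort_percentile_split(self):
        ages = pd.Series(np.arange(100, dtype=float))
        cats = age_categories(ages)
        assert (cats == "younger").sum() == 30
        assert (cats == "older").sum() == 30
        assert cats.isna().sum() == 40


class TestCompareObservedScores:
    @staticmethod
    def _long(scores, occurred, patients, mutation="M0"):
        return pd.DataFrame({
            "patient_id": patients,
            "mutation_id": mutation,
            "class": "I",
            "phbr": scores,
            "occurred": occurred,
            "expressed": occurred,
        })

    def test_pairwise_count_for_four_groups(self, scored_study):
        cohort = scored_study["cohort"].set_index("patient_id")
        sexage = (cohort["sex"].str[0].str.upper()
                  + age_categories(cohort["age_years"]).map({"younger": "Y", "older": "O"}))
        comps = compare_observed_scores(scored_study["long"], sexage.dropna(), "I")
        assert len(comps) == 6  # 4 groups -> C(4,2) pairwise
        for c in comps:
            if np.isfinite(c.p_one_tailed):
                assert c.p_bh >= c.p_one_tailed - 1e-12

    def test_direction_convention_focal_greater(self):
        long = self._long([9.0, 8.0, 7.0, 1.0, 2.0, 3.0],
                          [1] * 6, ["A1", "A2", "A3", "B1", "B2", "B3"])
        grouping = pd.Series({"A1": "a", "A2": "a", "A3": "a",
                              "B1": "b", "B2": "b", "B3": "b"})
        comp = compare_observed_scores(long, grouping, "I")[0]
        assert comp.group_a == "a"
        assert comp.p_one_tailed == pytest.approx(0.05)  # a greater, separated
        assert comp.cliffs_d == 1.0

    def test_unoccurred_cells_never_pooled(self):
        long = self._long([9.0, 1.0], [1, 0], ["A1", "B1"])
        grouping = pd.Series({"A1": "a", "B1": "b"})
        comps = compare_observed_scores(long, grouping, "I")
        assert comps[0].n_b == 0 and np.isnan(comps[0].p_one_tailed)


class TestPermutationNull:
    def test_null_data_statistic_inside_ci(self, scored_study):
        """Occurrences independent of genotype stay inside the 99% null CI."""
        rng = np.random.default_rng(0)
        scores = scored_study["phbr_i"]
        occ = pd.DataFrame(rng.random(scores.shape) < 0.1,
                           index=scores.index, columns=scores.columns).astype(int)
        grouping = scored_study["cohort"].set_index("patient_id")["sex"]
        res = permutation_null(scores, occ, grouping, "female", "male",
                               n_perm=300, seed=1)
        assert res.ci_low <= res.observed <= res.ci_high
        assert not res.outside_ci

    def test_identity_permutation_reproduces_observed(self, scored_study):
        """The observed statistic is a member of the permutation orbit."""
        scores = scored_study["phbr_i"]
        occ = scored_study["occurrence"]
        grouping = scored_study["cohort"].set_index("patient_id")["sex"]
        res = permutation_null(scores, occ, grouping, "female", "male",
                               n_perm=100, seed=2)
        # under the identity reassignment the statistic equals the observed one
        from immunoselect.stats import _group_statistic
        common = scores.index.intersection(occ.index)
        lab = grouping.reindex(common).to_numpy(dtype=object).astype(str)
        same = _group_statistic(scores.loc[common].to_numpy(),
                                occ.loc[common, scores.columns].to_numpy(),
                                lab, "female", "male", "median")
        assert same == pytest.approx(res.observed)

    def test_permutation_preserves_occurrence_counts(self, scored_study):
        """Reassignment is a bijection: column sums of Y are invariant."""
        occ = scored_study["occurrence"].to_numpy()
        rng = np.random.default_rng(5)
        perm = rng.permutation(occ.shape[0])
        np.testing.assert_array_equal(occ[perm].sum(axis=0), occ.sum(axis=0))

    def test_too_few_permutations_rejected(self, scored_study):
        grouping = scored_study["cohort"].set_index("patient_id")["sex"]
        with pytest.raises(ValueError):
            permutation_null(scored_study["phbr_i"], scored_study["occurrence"],
                             grouping, "female", "male", n_perm=10, seed=0)

    def test_missing_group_level_rejected(self, scored_study):
        grouping = pd.Series("male", index=scored_study["phbr_i"].index)
        with pytest.raises(ValueError, match="degenerate"):
            permutation_null(scored_study["phbr_i"], scored_study["occurrence"],
                             grouping, "female", "male", n_perm=100, seed=0)
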