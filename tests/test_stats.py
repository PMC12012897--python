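"""Statistical kernel: BH, Pearson, Fisher, rank tests, NB test, c-means."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from allohybrid.stats import (
    FuzzyCMeans,
    bh_adjust,
    fisher_exact_2x2,
    fisher_exact_many,
    fuzzy_cmeans,
    median_of_ratios_size_factors,
    nb_test_matrix,
    nb_two_group_test,
    pearson,
    rank_tests,
)


def bh_oracle(p):
    """Textbook step-up: adj_i = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_forced_by_formula(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_singleton_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 60)))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_sorted_uniform_adjusted_non_decreasing(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.random(100))
        assert np.all(np.diff(bh_adjust(p)) >= -1e-15)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))


class TestPearson:
    def test_dosage_worked_example(self):
        """(1/2, 2/3, 1) against (1.72, 1.96, 2.54): r and r^2 print as 0.99."""
        res = pearson([0.5, 2 / 3, 1.0], [1.72, 1.96, 2.54])
        assert math.floor(res.r * 100) / 100 == 0.99
        assert math.floor(res.r_squared * 100) / 100 == 0.99
        assert res.p_value < 0.05  # 1-df t (Cauchy) two-sided

    def test_exact_linear_relation(self):
        res = pearson([1.0, 2.0, 3.0, 4.0], [3.0, 5.0, 7.0, 9.0])
        assert res.r == pytest.approx(1.0)

    def test_constant_input_undefined(self):
        res = pearson([1, 2, 3], [5, 5, 5])
        assert res.undefined and math.isnan(res.r)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(20), rng.random(20)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)
        assert pearson(3 * x + 2, y).r == pytest.approx(pearson(x, y).r)
        assert pearson(-2 * x + 1, y).r == pytest.approx(-pearson(x, y).r)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of the hypergeometric support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = table_prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_2x2(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        res = fisher_exact_2x2(10, 0, 0, 10)
        assert res.p_value == pytest.approx(fisher_enumeration_oracle(10, 0, 0, 10), abs=1e-12)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            expected = fisher_enumeration_oracle(a, b, c, d)
            assert fisher_exact_2x2(a, b, c, d).p_value == pytest.approx(expected, abs=1e-12)
            assert fisher_exact_many(
                np.array([a]), np.array([b]), np.array([c]), np.array([d])
            )[0] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_under_row_and_column_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            assert fisher_exact_2x2(a, b, c, d).p_value == pytest.approx(
                fisher_exact_2x2(d, c, b, a).p_value, abs=1e-12
            )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestRankTests:
    def test_exact_symmetry_gives_p_one(self):
        assert rank_tests([[1, 2, 3], [1, 2, 3]]).p_value == 1.0

    def test_full_separation_smallest_exact_p(self):
        # 20 arrangements of 3+3; the two extreme ones give two-sided p = 0.1
        assert rank_tests([[1, 2, 3], [10, 11, 12]]).p_value == pytest.approx(2 / 20)

    def test_exact_matches_permutation_oracle(self):
        x, y = [1.0, 4.0, 6.0], [2.0, 7.0, 9.0]
        u_obs = sum(xi > yj for xi in x for yj in y)
        pooled = x + y
        us = [
            sum(a > b for a in combo for b in pooled if b not in combo)
            for combo in itertools.combinations(pooled, 3)
        ]
        mu = len(x) * len(y) / 2
        p_exact = sum(abs(u - mu) >= abs(u_obs - mu) for u in us) / len(us)
        assert rank_tests([x, y]).p_value == pytest.approx(p_exact)

    def test_three_groups_kruskal(self):
        res = rank_tests([[1, 2, 3], [1.5, 2.5, 3.5], [100, 101, 102]])
        assert res.p_value == pytest.approx(
            sps.kruskal([1, 2, 3], [1.5, 2.5, 3.5], [100, 101, 102]).pvalue
        )

    def test_kruskal_null_calibration(self):
        rng = np.random.default_rng(17)
        hits = sum(
            rank_tests([rng.normal(size=30) for _ in range(3)]).p_value < 0.05
            for _ in range(400)
        )
        assert 0.03 <= hits / 400 <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([[1, 2], []])


class TestNBTest:
    def test_null_case_small_effect(self):
        res = nb_two_group_test([10, 12, 11], [10, 11, 12])
        assert abs(res.log2_fold_change) < 0.2 and res.p_value > 0.5

    def test_all_zero_contract(self):
        res = nb_two_group_test([0, 0, 0], [0, 0, 0])
        assert res.log2_fold_change == 0.0 and res.p_value == 1.0

    def test_fold_change_direction_and_antisymmetry(self):
        rng = np.random.default_rng(0)
        A = rng.poisson(100, size=(200, 3)).astype(float)
        B = rng.poisson(400, size=(200, 3)).astype(float)
        lfc_ab, _ = nb_test_matrix(A, B)
        lfc_ba, _ = nb_test_matrix(B, A)
        assert np.median(lfc_ab) == pytest.approx(2.0, abs=0.2)
        assert lfc_ab == pytest.approx(-lfc_ba)

    def test_size_factors_remove_depth_difference(self):
        rng = np.random.default_rng(1)
        A = rng.poisson(100, size=(300, 3)).astype(float)
        B = rng.poisson(300, size=(300, 3)).astype(float)  # 3x deeper library
        lfc, _ = nb_test_matrix(A, B, np.ones(3), np.full(3, 3.0))
        assert abs(np.median(lfc)) < 0.1

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(5)
        A = rng.negative_binomial(10, 10 / 110, size=(800, 3))
        B = rng.negative_binomial(10, 10 / 110, size=(800, 3))
        _, p = nb_test_matrix(A, B)
        assert 0.02 <= (p < 0.05).mean() <= 0.08


class TestSizeFactors:
    def test_identical_samples_unity(self):
        counts = np.tile(np.arange(1, 50)[:, None], (1, 4))
        assert median_of_ratios_size_factors(counts) == pytest.approx(np.ones(4))

    def test_doubled_sample_ratio_two(self):
        rng = np.random.default_rng(9)
        a = rng.poisson(50, size=200) + 1
        counts = np.column_stack([a, 2 * a])
        f = median_of_ratios_size_factors(counts)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(21)
        counts = rng.poisson(80, size=(100, 5)) + 1
        log_ref = np.log(counts).mean(axis=1)
        expected = [
            np.exp(np.median(np.log(counts[:, j]) - log_ref)) for j in range(5)
        ]
        assert median_of_ratios_size_factors(counts) == pytest.approx(expected)


class TestFuzzyCMeans:
    def make_blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.3, size=(40, 4))
        b = rng.normal(5, 0.3, size=(40, 4))
        return np.vstack([a, b])

    def test_separated_blobs_confident_memberships(self):
        X = self.make_blobs()
        est = FuzzyCMeans(n_clusters=2, random_state=0).fit(X)
        top = est.memberships_.max(axis=1)
        assert (top > 0.9).all()
        # blob membership is consistent within each half
        assert len(set(est.labels_[:40])) == 1 and len(set(est.labels_[40:])) == 1

    def test_memberships_sum_to_one(self):
        est = FuzzyCMeans(n_clusters=3, random_state=1).fit(self.make_blobs(2))
        assert est.memberships_.sum(axis=1) == pytest.approx(np.ones(80))

    def test_objective_non_increasing(self):
        est = FuzzyCMeans(n_clusters=3, random_state=3, tol=0).fit(self.make_blobs(4))
        assert np.all(np.diff(est.objective_history_) <= 1e-9)

    def test_deterministic_for_fixed_seed(self):
        X = self.make_blobs(5)
        m1 = FuzzyCMeans(n_clusters=2, random_state=7).fit(X).memberships_
        m2 = FuzzyCMeans(n_clusters=2, random_state=7).fit(X).memberships_
        assert np.array_equal(m1, m2)

    def test_k9_profile_clustering_labels(self):
        rng = np.random.default_rng(6)
        profiles = rng.normal(size=(120, 5))
        clustering = fuzzy_cmeans(profiles, k=9, seed=0)
        assert set(clustering.labels) <= {f"C{i}" for i in range(1, 10)}
        assert clustering.memberships.shape == (120, 9)

    def test_constant_rows_dropped(self):
        X = np.vstack([np.ones((3, 4)), np.random.default_rng(0).normal(size=(20, 4))])
        clustering = fuzzy_cmeans(X, k=2, seed=0)
        assert list(clustering.kept_rows) == list(range(3, 23))

    def test_get_set_params_round_trip(self):
        est = FuzzyCMeans()
        est.set_params(n_clusters=5, m=1.5)
        assert est.get_params()["n_clusters"] == 5 and est.get_params()["m"] == 1.5
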