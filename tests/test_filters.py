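"""Filter-stage unit and property tests: Kendall tau, chi-square, MKMC, ReliefF."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from chainfs import (FeatureTable, ReliefFParams, chi2_2x2, chi2_statistic,
                     feature_redundancy, kendall_tau, label_relevance,
                     mkmc_rank, relieff_rank, relieff_weights, worked_fixtures)
from oracles import chi2_2x2_textbook, kendall_tau_bruteforce, relieff_textbook


class TestKendallTau:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 1, 1], [1, 2, 3], 0.0),   # constant vector convention
        ([5, 2, 9], [5, 5, 5], 0.0),
    ])
    def test_known_values(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected)

    def test_matches_pair_count_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 21))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            assert kendall_tau(x, y) == pytest.approx(
                kendall_tau_bruteforce(x, y), abs=1e-12)

    def test_exhaustive_small_ternary_vectors(self):
        """Exact agreement with the oracle over every (x, y) pair of short
        vectors on the alphabet {0, 1, 2}."""
        for n in (2, 3, 4):
            for x in itertools.product((0, 1, 2), repeat=n):
                for y in itertools.product((0, 1, 2), repeat=n):
                    assert kendall_tau(x, y) == pytest.approx(
                        kendall_tau_bruteforce(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=5, max_size=12),
           st.data())
    def test_long_ternary_vectors_and_symmetry(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 2), min_size=len(xs),
                                max_size=len(xs)))
        t = kendall_tau(xs, ys)
        assert -1.0 <= t <= 1.0
        assert t == pytest.approx(kendall_tau_bruteforce(xs, ys), abs=1e-12)
        assert t == pytest.approx(kendall_tau(ys, xs), abs=1e-12)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            kendall_tau([1], [2])


class TestLabelRelevance:
    def test_feature_equal_to_label_scores_one(self):
        fx = worked_fixtures()
        rel = label_relevance(fx["identity_table"], fx["identity_labels"])
        assert rel[0] == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        table = FeatureTable(np.column_stack([np.ones(6), np.arange(6)]))
        rel = label_relevance(table, np.array([0, 0, 0, 1, 1, 1]))
        assert rel[0] == 0.0

    def test_matches_per_column_oracle(self, rng):
        X = rng.integers(0, 10, (30, 6)).astype(float)
        y = rng.integers(0, 3, 30)
        rel = label_relevance(FeatureTable(X), y)
        for j in range(6):
            assert rel[j] == pytest.approx(
                abs(kendall_tau_bruteforce(X[:, j], y)), abs=1e-12)

    def test_single_class_rejected(self, tiny_table):
        table, _ = tiny_table
        with pytest.raises(ValueError):
            label_relevance(table, np.zeros(6))


class TestChiSquare:
    def test_equal_observed_expected_is_zero(self):
        assert chi2_statistic([3, 4, 5], [3, 4, 5]) == 0.0

    def test_worked_count_sets(self):
        fx = worked_fixtures()
        expected = 25 / 15 + 25 / 25 + 25 / 35 + 25 / 45
        assert chi2_statistic(fx["features1"], fx["features2"]) == pytest.approx(expected)

    def test_doubled_counts_identity(self, rng):
        e = rng.uniform(1, 50, 8)
        assert chi2_statistic(2 * e, e) == pytest.approx(e.sum())

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            chi2_statistic([1.0], [0.0])

    def test_2x2_balanced_table_is_zero(self):
        assert chi2_2x2(10, 10, 10, 10) == 0.0

    def test_2x2_diagonal_table_modes(self):
        assert chi2_2x2(10, 0, 0, 10) == pytest.approx(1.0)
        assert chi2_2x2(10, 0, 0, 10, mode="standard") == pytest.approx(20.0)

    def test_2x2_standard_equals_textbook_and_n_times_literal(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 30, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            std = chi2_2x2(a, b, c, d, mode="standard")
            assert std == pytest.approx(chi2_2x2_textbook(a, b, c, d), abs=1e-9)
            assert std == pytest.approx(
                (a + b + c + d) * chi2_2x2(a, b, c, d), abs=1e-9)

    def test_2x2_standard_matches_scipy_uncorrected(self, rng):
        for _ in range(50):
            tbl = rng.integers(1, 30, (2, 2))
            expected = chi2_contingency(tbl, correction=False).statistic
            assert chi2_2x2(*tbl.ravel(), mode="standard") == pytest.approx(expected)

    def test_2x2_zero_margin_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert chi2_2x2(0, 0, 5, 5) == 0.0


class TestFeatureRedundancy:
    def test_identical_columns_saturate(self, rng):
        f = rng.normal(size=100)
        _, norm = feature_redundancy(f, f.copy())
        assert norm == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            _, norm = feature_redundancy(r.normal(size=1000), r.normal(size=1000))
            hits += norm <= 0.1
        assert hits == 10

    def test_constant_column_is_zero(self, rng):
        assert feature_redundancy(np.ones(50), rng.normal(size=50)) == (0.0, 0.0)

    def test_normalized_form_bounded(self, rng):
        for _ in range(20):
            chi2, norm = feature_redundancy(rng.normal(size=40), rng.normal(size=40))
            assert chi2 >= 0
            assert 0.0 <= norm <= 1.0


class TestMKMCRank:
    def test_k1_is_argmax_relevance(self, planted):
        table, labels, _ = planted
        ranking = mkmc_rank(table, labels, 1)
        assert ranking.order == [int(np.argmax(label_relevance(table, labels)))]

    def test_full_k_is_permutation(self, tiny_table):
        table, labels = tiny_table
        ranking = mkmc_rank(table, labels, table.n_features)
        assert sorted(ranking.order) == list(range(table.n_features))

    def test_exact_copy_penalized_below_weaker_feature(self):
        """With informative feature A, its exact copy A', and a weaker but
        independent feature B, the greedy ranking demotes the copy."""
        r = np.random.default_rng(3)
        n = 300
        y = np.repeat([0, 1], n // 2)
        a = y * 3.0 + r.normal(size=n)
        b = y * 1.0 + r.normal(size=n)
        table = FeatureTable(np.column_stack([a, a.copy(), b]), ["A", "Acopy", "B"])
        ranking = mkmc_rank(table, y, 3)
        assert ranking.order[0] == 0            # A wins on relevance
        assert ranking.order.index(2) < ranking.order.index(1)  # B above copy
        # the copy's greedy objective is relevance minus the smallest
        # redundancy against the already-selected set {A, B}
        rel = label_relevance(table, y)
        red = min(feature_redundancy(a, a)[1], feature_redundancy(a, b)[1])
        assert ranking.scores[2] == pytest.approx(rel[1] - red)

    def test_scores_are_greedy_objectives_and_reproducible(self, planted):
        table, labels, _ = planted
        r1 = mkmc_rank(table, labels, 12)
        r2 = mkmc_rank(table, labels, 12)
        assert r1.order == r2.order
        assert r1.scores == r2.scores
        # first pick maximizes relevance alone, so it bounds every later
        # relevance-minus-redundancy objective (min-aggregated redundancy
        # itself can shrink as the set grows, so full monotonicity of the
        # score sequence is not guaranteed)
        assert all(s <= r1.scores[0] + 1e-12 for s in r1.scores)

    def test_k_out_of_range(self, tiny_table):
        table, labels = tiny_table
        with pytest.raises(ValueError):
            mkmc_rank(table, labels, 0)
        with pytest.raises(ValueError):
            mkmc_rank(table, labels, 4)

    def test_mean_aggregator_supported(self, planted):
        table, labels, _ = planted
        ranking = mkmc_rank(table, labels, 8, aggregator="mean")
        assert len(ranking) == 8


class TestReliefF:
    def test_constant_feature_weight_zero(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = np.repeat([0, 1], 20)
        w = relieff_weights(FeatureTable(X), y, ReliefFParams(k=3), rng)
        assert w[0] == 0.0

    def test_separating_feature_gets_highest_weight(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 100
            y = np.repeat([0, 1], n // 2)
            X = r.normal(size=(n, 5))
            X[:, 2] = y * 10.0 + r.normal(scale=0.1, size=n)  # perfect separator
            w = relieff_weights(FeatureTable(X), y, ReliefFParams(k=5),
                                np.random.default_rng(seed))
            hits += int(np.argmax(w)) == 2
        assert hits == 10

    def test_matches_textbook_oracle(self):
        r = np.random.default_rng(11)
        X = r.normal(size=(20, 5))
        y = r.integers(0, 2, 20)
        while len(np.unique(y)) < 2 or min(np.bincount(y)) < 4:
            y = r.integers(0, 2, 20)
        params = ReliefFParams(m=20, k=3)
        w = relieff_weights(FeatureTable(X), y, params, np.random.default_rng(5))
        sampled = np.random.default_rng(5).permutation(20)[:20]
        expected = relieff_textbook(X, y, 20, 3, sampled)
        np.testing.assert_allclose(w, expected, atol=1e-9)

    def test_duplicated_columns_equal_weights(self, rng):
        X = rng.normal(size=(60, 3))
        X = np.column_stack([X, X[:, 0]])
        y = rng.integers(0, 2, 60)
        y[:10] = 0
        y[10:20] = 1
        w = relieff_weights(FeatureTable(X), y, ReliefFParams(k=4),
                            np.random.default_rng(0))
        assert w[0] == pytest.approx(w[3], abs=1e-12)

    def test_class_too_small_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError):
            relieff_weights(FeatureTable(X), y, ReliefFParams(k=3), rng)

    def test_rank_keep_all_is_permutation(self, tiny_table, rng):
        table, labels = tiny_table
        ranking = relieff_rank(table, labels, 3, ReliefFParams(k=2), rng)
        assert sorted(ranking.order) == [0, 1, 2]
        assert ranking.scores == sorted(ranking.scores, reverse=True)

    def test_rank_keep_one_is_argmax(self, planted):
        table, labels, _ = planted
        w = relieff_weights(table, labels, rng=np.random.default_rng(1))
        ranking = relieff_rank(table, labels, 1, rng=np.random.default_rng(1))
        assert ranking.order == [int(np.argmax(w))]

    def test_informative_rank_above_noise(self):
        """Planted informative features beat pure-noise features in ranking."""
        from chainfs import SyntheticSpec, make_synthetic
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(n_samples=200, n_informative=3, n_redundant=0,
                                 n_noise=17, class_separation=3.0, seed=seed)
            table, labels, roles = make_synthetic(spec)
            ranking = relieff_rank(table, labels, 3,
                                   rng=np.random.default_rng(seed))
            hits += set(ranking.order) == {0, 1, 2}
        assert hits >= 9
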