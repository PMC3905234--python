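"""Mu-score partial-order statistics: definitions, oracles, invariants."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from mugwas import mucore
from conftest import brute_force_mu_scores


class TestPolarize:
    def test_all_plus_is_identity(self):
        win = np.array([[0, 1], [2, -1], [1, 0]], dtype=np.int8)
        out = mucore.polarize(win, np.array([1, 1]))
        assert np.array_equal(out, win)

    def test_hand_mapped_mixed_polarity(self):
        win = np.array([[0, 1, 2], [2, 0, 1], [1, 2, 0], [-1, 1, 1]], dtype=np.int8)
        out = mucore.polarize(win, np.array([1, -1, 1]))
        expect = win.copy()
        expect[:, 1] = [1, 2, 0, 1]
        assert np.array_equal(out, expect)

    def test_missing_preserved_in_flipped_component(self):
        win = np.array([[-1, 2], [1, -1]], dtype=np.int8)
        out = mucore.polarize(win, np.array([-1, -1]))
        assert out[0, 0] == -1 and out[1, 1] == -1
        assert out[0, 1] == 0 and out[1, 0] == 1

    def test_global_flip_negates_scores(self):
        rng = np.random.default_rng(5)
        win = rng.integers(0, 3, (30, 4)).astype(np.int8)
        plus = mucore.mu_scores(win)
        minus = mucore.mu_scores(mucore.polarize(win, -np.ones(4, dtype=int)))
        assert np.array_equal(plus.scores, -minus.scores)
        assert plus.mu_ic == minus.mu_ic


class TestMuScores:
    def test_total_order_chain(self):
        mu = mucore.mu_scores(np.array([[0, 0], [1, 1], [2, 1]]))
        assert mu.scores.tolist() == [-2, 0, 2]
        assert mu.mu_ic == 1.0

    def test_conflicting_components_incomparable(self):
        mu = mucore.mu_scores(np.array([[0, 1], [1, 0]]))
        assert mu.scores.tolist() == [0, 0]
        assert mu.mu_ic == 0.0

    def test_single_snp_equals_midrank_identity(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 57)
        mu = mucore.mu_scores(x[:, None])
        expect = 2 * rankdata(x) - (x.size + 1)
        assert np.allclose(mu.scores, expect)

    @pytest.mark.parametrize("n,w,miss", [(2, 1, 0.0), (7, 3, 0.3), (40, 6, 0.1),
                                          (120, 2, 0.0), (200, 4, 0.05)])
    def test_matches_brute_force_oracle(self, n, w, miss):
        rng = np.random.default_rng(n * 7 + w)
        win = rng.integers(0, 3, (n, w)).astype(np.int8)
        win[rng.random((n, w)) < miss] = -1
        mu = mucore.mu_scores(win)
        scores, mu_ic, ordered, total = brute_force_mu_scores(win)
        assert np.array_equal(mu.scores, scores)
        assert mu.n_pairs_ordered == ordered
        assert mu.n_pairs_total == total
        assert mu.mu_ic == pytest.approx(mu_ic)

    def test_brute_force_equivalence_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(st.integers(2, 25), st.integers(1, 6), st.randoms(use_true_random=False))
        def check(n, w, rnd):
            win = np.array([[rnd.choice([-1, 0, 0, 1, 1, 2]) for _ in range(w)]
                            for _ in range(n)], dtype=np.int8)
            mu = mucore.mu_scores(win)
            scores, _, ordered, _ = brute_force_mu_scores(win)
            assert np.array_equal(mu.scores, scores)
            assert mu.n_pairs_ordered == ordered

        check()

    def test_scores_sum_to_zero_property(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 60))
            w = int(rng.integers(1, 7))
            win = rng.integers(0, 3, (n, w)).astype(np.int8)
            win[rng.random((n, w)) < 0.15] = -1
            mu = mucore.mu_scores(win)
            assert mu.scores.sum() == 0
            assert np.all(np.abs(mu.scores) <= n - 1)

    def test_incomparable_subject_leaves_others_unchanged(self):
        rng = np.random.default_rng(4)
        win = rng.integers(0, 3, (25, 3)).astype(np.int8)
        base = mucore.mu_scores(win)
        extended = np.vstack([win, -np.ones((1, 3), dtype=np.int8)])
        ext = mucore.mu_scores(extended)
        assert np.array_equal(ext.scores[:-1], base.scores)
        assert ext.scores[-1] == 0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            mucore.mu_scores(np.array([[1, 2]]))


class TestUTest:
    def test_symmetric_scores_give_zero(self):
        # scores +1/-1 split evenly across groups
        win = np.array([[0], [1], [0], [1]])
        groups = np.array([True, True, False, False])
        res = mucore.u_test(mucore.mu_scores(win), groups)
        assert res.s == 0.0 and res.z == 0.0

    def test_degenerate_when_all_scores_zero(self):
        win = np.ones((6, 2), dtype=np.int8)
        res = mucore.u_test(mucore.mu_scores(win), np.arange(6) < 3)
        assert res.degenerate and res.s == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_single_snp_equals_tie_corrected_wilcoxon(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 150))
        x = rng.integers(0, 3, n)
        g = rng.random(n) < 0.5
        if g.all() or not g.any() or np.ptp(x) == 0:
            pytest.skip("degenerate draw")
        res = mucore.u_test(mucore.mu_scores(x[:, None]), g)
        mw = mannwhitneyu(x[g], x[~g], use_continuity=False, method="asymptotic")
        assert res.s == pytest.approx(-np.log10(mw.pvalue), rel=1e-10)

    def test_exhaustive_permutation_rank_agreement(self):
        # n=6, all 20 balanced label assignments: the normal-approximation p
        # orders the assignments exactly as the exact permutation p does
        from itertools import combinations

        win = np.array([[0, 1], [1, 1], [2, 0], [0, 0], [2, 2], [1, 2]])
        mu = mucore.mu_scores(win)
        stats, exact = [], []
        Ts = []
        for cases in combinations(range(6), 3):
            g = np.zeros(6, dtype=bool)
            g[list(cases)] = True
            Ts.append(mu.scores[g].sum())
        Ts = np.array(Ts)
        for cases in combinations(range(6), 3):
            g = np.zeros(6, dtype=bool)
            g[list(cases)] = True
            res = mucore.u_test(mu, g)
            stats.append(res.s)
            T = mu.scores[g].sum()
            exact.append((np.abs(Ts) >= abs(T)).mean())
        order_normal = np.argsort(np.argsort(-np.array(stats)))
        order_exact = np.argsort(np.argsort(np.array(exact)))
        # identical ranking up to ties in the exact p
        for i in range(len(stats)):
            for j in range(len(stats)):
                if exact[i] < exact[j]:
                    assert stats[i] >= stats[j]


class TestStratified:
    def test_single_stratum_reduces_to_u_test(self):
        rng = np.random.default_rng(2)
        win = rng.integers(0, 3, (40, 3)).astype(np.int8)
        g = rng.random(40) < 0.4
        plain = mucore.u_test(mucore.mu_scores(win), g)
        strat = mucore.stratified_u_test(win, g, np.zeros(40))
        assert strat.z == pytest.approx(plain.z)
        assert strat.s == pytest.approx(plain.s)

    def test_equal_and_opposite_strata_cancel(self):
        win = np.array([[0], [1], [2], [0], [1], [2], [0], [1], [2], [0], [1], [2]])
        g = np.array([0, 0, 1, 0, 1, 1, 1, 1, 0, 1, 0, 0], dtype=bool)
        strata = np.repeat([0, 1], 6)
        res = mucore.stratified_u_test(win, g, strata)
        assert abs(res.z) < 1e-12

    def test_two_strata_sums_match_direct_arithmetic(self):
        rng = np.random.default_rng(8)
        win = rng.integers(0, 3, (30, 2)).astype(np.int8)
        g = rng.random(30) < 0.5
        strata = (np.arange(30) >= 18).astype(int)
        T_tot, var_tot = 0.0, 0.0
        for k in (0, 1):
            idx = strata == k
            mu = mucore.mu_scores(win[idx])
            n1 = g[idx].sum()
            n2 = idx.sum() - n1
            T_tot += mu.scores[g[idx]].sum()
            var_tot += n1 * n2 * (mu.scores**2).sum() / (idx.sum() * (idx.sum() - 1))
        res = mucore.stratified_u_test(win, g, strata)
        assert res.z == pytest.approx(T_tot / np.sqrt(var_tot))

    def test_no_informative_stratum_degenerate(self):
        win = np.array([[0], [1], [2], [0]])
        g = np.array([True, True, False, False])
        strata = np.array([0, 0, 1, 1])  # each stratum single-group
        res = mucore.stratified_u_test(win, g, strata)
        assert res.degenerate


class TestSexSelection:
    def test_equal_values_keep_stratified(self):
        s, label = mucore.select_sex_specific(3.0, 3.0, 3.0)
        assert (s, label) == (3.0, "stratified")

    def test_strong_single_sex_wins_with_penalty(self):
        s, label = mucore.select_sex_specific(5.0, 6.0, 1.0)
        assert label == "male"
        assert s == pytest.approx(6.0 - np.log10(2))

    def test_exact_tie_resolves_to_stratified(self):
        s_strat = 2.5
        s_f = s_strat + np.log10(2)
        s, label = mucore.select_sex_specific(s_strat, 0.0, s_f)
        assert (s, label) == (s_strat, "stratified")
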