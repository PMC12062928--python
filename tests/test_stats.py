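"""Statistical toolbox: exact/enumeration oracles and invariances."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from playface.stats import (binomial_exact, cohens_kappa, dunn_bonferroni,
                            duration_ioa, kruskal_wallis_mc, paired_t,
                            wilcoxon_exact, yates_chi2)


# --------------------------- Yates chi-square ------------------------------

class TestYatesChi2:
    @pytest.mark.parametrize("table, expected", [
        ((33, 44, 8, 32), 5.080),
        ((171, 96, 15, 61), 45.024),
    ])
    def test_reported_contingency_values(self, table, expected):
        res = yates_chi2(table)
        assert res.statistic == pytest.approx(expected, abs=1e-3)
        assert res.df_or_n == 1

    def test_agrees_with_scipy_continuity_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tab = rng.integers(1, 60, size=4)
            ours = yates_chi2(tuple(tab))
            ref, p, _, _ = sps.chi2_contingency(tab.reshape(2, 2),
                                                correction=True)
            assert ours.statistic == pytest.approx(ref, rel=1e-10)
            assert ours.p_value == pytest.approx(p, rel=1e-10)

    def test_no_association_clamps_to_zero(self):
        res = yates_chi2((10, 10, 10, 10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_symmetry_under_transpose_and_swaps(self):
        a, b, c, d = 7, 21, 13, 2
        base = yates_chi2((a, b, c, d)).statistic
        assert yates_chi2((a, c, b, d)).statistic == pytest.approx(base)  # transpose
        assert yates_chi2((d, c, b, a)).statistic == pytest.approx(base)  # row+col swap

    def test_zero_marginal_not_available(self):
        assert not yates_chi2((0, 0, 5, 5)).available


# --------------------------- exact Wilcoxon --------------------------------

def brute_force_wilcoxon_p(diffs):
    """Two-sided exact p by explicit enumeration of every sign vector."""
    d = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    t_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    m = len(d)
    for signs in itertools.product([1, -1], repeat=m):
        w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
        if min(w_plus, ranks.sum() - w_plus) <= t_obs + 1e-9:
            count += 1
    return count / 2 ** m


class TestWilcoxonExact:
    def test_all_same_sign_n8(self):
        res = wilcoxon_exact(np.arange(1.0, 9.0), np.zeros(8))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 256)
        assert res.ties == 0

    def test_identical_samples_not_available(self):
        res = wilcoxon_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.available and res.ties == 3

    def test_zero_differences_counted_as_ties(self):
        res = wilcoxon_exact([1.0, 2.0, 5.0, 7.0], [1.0, 3.0, 4.0, 6.0])
        assert res.ties == 1

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # integers force tied absolute differences, exercising mid-ranks
        x = rng.integers(0, 6, size=5).astype(float)
        y = rng.integers(0, 6, size=5).astype(float)
        d = x - y
        d = d[d != 0]
        if len(d) == 0:
            pytest.skip("degenerate draw")
        res = wilcoxon_exact(x, y)
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d))

    def test_normal_approximation_close_to_exact_at_cutover(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.3, 1, size=30)
        y = rng.normal(0.0, 1, size=30)
        approx = wilcoxon_exact(x, y)
        assert approx.correction == "normal-approx"
        ref = sps.wilcoxon(x, y, correction=True, method="approx")
        assert approx.p_value == pytest.approx(ref.pvalue, abs=0.02)


# ------------------- Kruskal-Wallis Monte Carlo ----------------------------

def exact_kw_p(groups):
    """Exact randomization p for small samples by enumerating all
    assignments of the pooled values to the group sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    tie_sizes = np.unique(pooled, return_counts=True)[1]
    tie_factor = 1 - np.sum(tie_sizes ** 3 - tie_sizes) / (n ** 3 - n)

    def h_of(assign):
        h = 0.0
        for g in range(len(sizes)):
            r = ranks[np.asarray(assign) == g]
            h += r.sum() ** 2 / len(r)
        return (12.0 / (n * (n + 1)) * h - 3 * (n + 1)) / tie_factor

    labels = np.repeat(np.arange(len(sizes)), sizes)
    h_obs = h_of(labels)
    perms = set(itertools.permutations(labels))
    count = sum(h_of(p) >= h_obs - 1e-9 for p in perms)
    return count / len(perms)


class TestKruskalWallisMC:
    def test_identical_groups(self):
        res = kruskal_wallis_mc([[1, 2, 3], [1, 2, 3]], n_perm=200, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_all_values_identical(self):
        res = kruskal_wallis_mc([[2, 2], [2, 2, 2]], n_perm=100, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_h_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        groups = [rng.integers(0, 8, size=n).astype(float) for n in (6, 9, 7)]
        ours = kruskal_wallis_mc(groups, n_perm=100, seed=0)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_monte_carlo_p_matches_enumeration_oracle(self):
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        p_exact = exact_kw_p(groups)
        res = kruskal_wallis_mc(groups, n_perm=10000, seed=42)
        mc_se = math.sqrt(p_exact * (1 - p_exact) / 10000)
        assert abs(res.p_value - p_exact) <= 3 * mc_se + 2e-4

    def test_fixed_seed_is_reproducible(self):
        groups = [[1.0, 4.0, 2.0], [3.0, 8.0], [0.5, 9.0, 7.0]]
        p1 = kruskal_wallis_mc(groups, n_perm=2000, seed=9).p_value
        p2 = kruskal_wallis_mc(groups, n_perm=2000, seed=9).p_value
        assert p1 == p2

    def test_permutation_p_never_zero(self):
        groups = [[1, 2, 3], [100, 101, 102]]
        res = kruskal_wallis_mc(groups, n_perm=500, seed=1)
        assert res.p_value >= 1 / 501


class TestDunnBonferroni:
    def test_identical_groups_all_corrected_to_one(self):
        res = dunn_bonferroni([[1, 2, 3, 4]] * 3)
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_separated_groups_detected_and_capped(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                  rng.normal(5, 1, 30)]
        res = dunn_bonferroni(groups, labels=["a", "b", "c"])
        by_pair = {r.extra["pair"]: r for r in res}
        assert by_pair[("a", "c")].p_value < 0.001
        assert by_pair[("a", "b")].p_value == 1.0  # capped
        assert all(0 <= r.p_value <= 1 for r in res)

    def test_reports_raw_difference_and_z(self):
        res = dunn_bonferroni([[1, 2], [10, 11]])
        (r,) = res
        assert r.statistic == pytest.approx(-2.0)  # mean ranks 1.5 vs 3.5
        assert r.extra["z"] < 0


class TestPairedT:
    def test_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = paired_t(x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_ref)
        assert res.df_or_n == 11

    def test_zero_variance_not_available(self):
        assert not paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]).available


class TestBinomialExact:
    @pytest.mark.parametrize("k, n, expected", [
        (5, 5, 2 / 32),
        (5, 10, 1.0),
        (0, 10, 2 * 0.5 ** 10),
    ])
    def test_two_sided_p(self, k, n, expected):
        assert binomial_exact(k, n).p_value == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_exact(1, 0)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(list("aabb"), list("aabb")).statistic == 1.0

    def test_single_category_not_available(self):
        assert not cohens_kappa(["a"] * 5, ["a"] * 5).available

    def test_hand_computed_confusion_matrix(self):
        # confusion matrix (20, 5; 10, 15)
        c1 = ["x"] * 25 + ["y"] * 25
        c2 = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        p_o = 35 / 50
        p_e = (25 / 50) * (30 / 50) + (25 / 50) * (20 / 50)
        expected = (p_o - p_e) / (1 - p_e)
        assert cohens_kappa(c1, c2).statistic == pytest.approx(expected)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(4)
        c1 = rng.choice(list("abc"), size=200)
        c2 = rng.choice(list("abc"), size=200)
        ours = cohens_kappa(c1, c2).statistic
        assert ours == pytest.approx(cohen_kappa_score(c1, c2))
        assert abs(ours) < 0.15  # independent codings hover near zero


class TestDurationIOA:
    def test_single_trial_ratio(self):
        assert duration_ioa([15], [20]) == pytest.approx(0.75)

    def test_identical_durations_full_agreement(self):
        assert duration_ioa([3, 7], [3, 7], percent=True) == 100.0

    def test_mean_over_trials_in_percent(self):
        assert duration_ioa([15, 10], [20, 10], percent=True) == pytest.approx(87.5)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            duration_ioa([0.0], [1.0])
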