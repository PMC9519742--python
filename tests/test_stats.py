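"""Ordination and test statistics vs enumeration oracles and scipy/skbio."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency, mannwhitneyu

from cervidyn.stats import (
    chi_square_rxc,
    fisher_exact_2x2,
    mann_whitney_u,
    nmds,
    permanova,
)


def permanova_f_oracle(D, labels):
    """Direct loop-based pseudo-F computation."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    d2 = D**2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total


def exhaustive_p_oracle(D, labels):
    f_obs, _ = permanova_f_oracle(D, labels)
    perms = sorted(set(itertools.permutations(labels)))
    hits = sum(1 for p in perms if permanova_f_oracle(D, list(p))[0] >= f_obs - 1e-12)
    return hits / len(perms)


def fisher_oracle(table):
    """Exact-rational two-sided Fisher by enumerating all tables."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return Fraction(math.comb(c1, k) * math.comb(n - c1, r1 - k), math.comb(n, r1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


class TestPermanova:
    def test_two_tight_clusters_exhaustive(self):
        pts = np.array([0.0, 0, 0, 10, 10, 10])[:, None]
        D = squareform(pdist(pts))
        res = permanova(D, ["a"] * 3 + ["b"] * 3, exhaustive=True)
        assert res.p_value == pytest.approx(2 / 20)
        assert res.n_permutations == 20

    def test_equal_distances_r2_is_closed_form(self):
        """With all pairwise distances equal, R^2 = (a-1)/(N-1) for every labelling."""
        D = np.ones((6, 6)) - np.eye(6)
        labels = ["a", "a", "a", "b", "b", "b"]
        for perm in sorted(set(itertools.permutations(labels))):
            res = permanova(D, list(perm), exhaustive=True)
            assert res.r_squared == pytest.approx(1 / 5, abs=1e-12)

    def test_sampled_p_matches_exhaustive_within_mc_error(self, rng):
        for _ in range(8):
            n = int(rng.integers(6, 9))
            X = rng.standard_normal((n, 2))
            D = squareform(pdist(X))
            n_a = int(rng.integers(2, n - 1))
            labels = ["a"] * n_a + ["b"] * (n - n_a)
            p_exact = exhaustive_p_oracle(D, labels)
            res = permanova(D, labels, n_permutations=999, seed=int(rng.integers(2**31)))
            se = np.sqrt(p_exact * (1 - p_exact) / 999) + 1e-9
            assert abs(res.p_value - p_exact) <= 3 * se + 2 / 999

    def test_statistic_matches_loop_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            X = rng.standard_normal((n, 3))
            D = squareform(pdist(X))
            labels = list(rng.choice(["a", "b", "c"], size=n))
            if len(set(labels)) < 2 or min(labels.count(g) for g in set(labels)) < 1:
                continue
            f, r2 = permanova_f_oracle(D, labels)
            res = permanova(D, labels, n_permutations=9, seed=0)
            assert res.pseudo_f == pytest.approx(f, rel=1e-10)
            assert res.r_squared == pytest.approx(r2, rel=1e-10)

    def test_statistic_matches_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from skbio import DistanceMatrix

        X = rng.standard_normal((12, 2))
        D = squareform(pdist(X))
        labels = ["a"] * 6 + ["b"] * 6
        theirs = skbio_stats.permanova(DistanceMatrix(D), labels, permutations=99)
        ours = permanova(D, labels, n_permutations=99, seed=1)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_relabelling_invariance(self, rng):
        X = rng.standard_normal((10, 2))
        D = squareform(pdist(X))
        labels = ["a"] * 5 + ["b"] * 5
        res1 = permanova(D, labels, n_permutations=99, seed=7)
        res2 = permanova(D, ["x" if l == "a" else "y" for l in labels], n_permutations=99, seed=7)
        assert res1.pseudo_f == res2.pseudo_f
        assert res1.r_squared == res2.r_squared

    def test_p_never_below_inverse_permutations(self, rng):
        pts = np.concatenate([np.zeros(5), np.full(5, 100.0)])[:, None]
        D = squareform(pdist(pts))
        res = permanova(D, ["a"] * 5 + ["b"] * 5, n_permutations=199, seed=0)
        assert res.p_value >= 1 / 200

    def test_empty_group_rejected(self):
        D = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            permanova(D, ["a"] * 4, n_permutations=9)


class TestFisher:
    def test_table1_married_value(self):
        assert fisher_exact_2x2([[12, 52], [0, 36]]) == pytest.approx(0.0037, abs=1e-4)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_matches_rational_enumeration(self, rng):
        for _ in range(200):
            while True:
                t = rng.integers(0, 11, size=(2, 2))
                if 0 < t.sum() <= 40 and t.sum(axis=0).min() >= 0:
                    break
            p = fisher_exact_2x2(t)
            assert p == pytest.approx(fisher_oracle(t.tolist()), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestChiSquare:
    def test_independence_gives_zero(self):
        stat, df = chi_square_rxc([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and df == 1

    def test_hand_evaluated(self):
        stat, df = chi_square_rxc([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-9)
        assert df == 1

    def test_matches_scipy_and_permutation_invariant(self, rng):
        for _ in range(100):
            t = rng.integers(1, 30, size=(rng.integers(2, 5), rng.integers(2, 5)))
            stat, df = chi_square_rxc(t)
            ref = chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-10)
            assert df == ref.dof
            perm = t[rng.permutation(t.shape[0])][:, rng.permutation(t.shape[1])]
            assert chi_square_rxc(perm)[0] == pytest.approx(stat, rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_rxc([[0, 0], [1, 2]])


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0] * 10, [1.0] * 10)
        assert p == pytest.approx(1.0)

    def test_exact_branch_matches_scipy(self, rng):
        for _ in range(100):
            m, n = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.standard_normal(m)
            y = rng.standard_normal(n)
            u, p = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, method="exact", alternative="two-sided")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_approx_branch_matches_scipy(self, rng):
        for _ in range(100):
            x = rng.integers(0, 8, size=15).astype(float)  # ties likely
            y = rng.integers(0, 8, size=12).astype(float)
            u, p = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=True, alternative="two-sided")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_branches_agree_at_moderate_n(self, rng):
        for _ in range(30):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            _, p_exact = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=True, alternative="two-sided")
            assert abs(p_exact - ref.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestNMDS:
    def test_euclidean_embeddable_low_stress(self, rng):
        X = rng.standard_normal((14, 2))
        res = nmds(squareform(pdist(X)), k=2, n_restarts=4, seed=0)
        assert res.stress < 0.01

    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        assert nmds(D, k=2, n_restarts=3, seed=0).stress < 0.01

    def test_stress_trace_monotone_non_increasing(self, rng):
        X = rng.standard_normal((10, 4))
        res = nmds(squareform(pdist(X)), k=2, n_restarts=2, seed=3)
        trace = res.stress_trace
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_seed_determinism(self, rng):
        D = squareform(pdist(rng.standard_normal((9, 3))))
        r1 = nmds(D, n_restarts=3, seed=42)
        r2 = nmds(D, n_restarts=3, seed=42)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_all_zero_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            nmds(np.zeros((4, 4)))
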