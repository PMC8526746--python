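"""Bootstrap nulls vs exact oracles; classical tests vs enumeration/scipy."""

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pytest
from scipy import stats as sps

from synspot.repeatability_stats import (
    ResamplingResult,
    analytic_tail,
    chisq_independence,
    dunn_posthoc,
    kruskal_wallis,
    p_focal_at_least,
    p_focal_at_most,
    p_max_at_least,
    report_p,
    resample_counts,
    wilcoxon_rank_sum,
)


def binomial_tail_ge(k, n, p):
    """Independent closed-form oracle: sum of upper binomial terms."""
    return sum(
        Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


class TestResampleCounts:
    def test_shape_and_conservation(self):
        counts = resample_counts(24, 3, 500, seed=1)
        assert counts.shape == (500, 3)
        assert (counts.sum(axis=1) == 24).all()

    def test_single_route_degenerate(self):
        counts = resample_counts(10, 1, 50, seed=2)
        assert (counts == 10).all()

    def test_seed_determinism(self):
        a = resample_counts(15, 3, 1000, seed=42)
        b = resample_counts(15, 3, 1000, seed=42)
        assert (a == b).all()

    def test_mean_focal_count_matches_binomial(self):
        counts = resample_counts(24, 3, 100_000, seed=3)
        focal = counts[:, 0]
        se = sqrt(24 * (1 / 3) * (2 / 3) / len(focal))
        assert abs(focal.mean() - 8.0) < 3 * se


class TestAnalyticTail:
    def test_headline_23_of_24_closed_form(self):
        # hand derivation: C(24,23)(1/3)^23(2/3) + (1/3)^24 = 49/3^24
        assert analytic_tail("focal_at_least", 23, 24, 3) == Fraction(49, 3**24)

    def test_max_8_of_15_disjoint_tails(self):
        # two routes cannot both reach 8 of 15, so the union is 3 disjoint
        # binomial tails: 3 * sum_{j>=8} C(15,j)(1/3)^j(2/3)^(15-j)
        expected = 3 * binomial_tail_ge(8, 15, Fraction(1, 3))
        got = analytic_tail("max_at_least", 8, 15, 3)
        assert got == expected == Fraction(3_798_081, 14_348_907)
        assert abs(float(got) - 0.26469) < 5e-5

    def test_focal_none_of_16(self):
        assert analytic_tail("focal_at_most", 0, 16, 3) == Fraction(2, 3) ** 16

    @pytest.mark.parametrize(
        "stat,k,expected",
        [
            ("focal_at_least", 0, 1),
            ("focal_at_least", 25, 0),
            ("focal_at_most", 24, 1),
            ("max_at_least", 25, 0),
        ],
    )
    def test_boundary_values(self, stat, k, expected):
        assert analytic_tail(stat, k, 24, 3) == expected

    def test_inclusion_exclusion_against_enumeration(self):
        """Exact max-statistic tail vs full multinomial enumeration (n=8)."""
        n, r, k = 8, 3, 3
        total = Fraction(0)
        from math import factorial

        for a in range(n + 1):
            for b in range(n - a + 1):
                c = n - a - b
                if max(a, b, c) >= k:
                    total += Fraction(
                        factorial(n), factorial(a) * factorial(b) * factorial(c)
                    ) * Fraction(1, r) ** n
        assert analytic_tail("max_at_least", k, n, r) == total

    def test_limits_enforced(self):
        with pytest.raises(ValueError):
            analytic_tail("focal_at_least", 1, 300, 3)
        with pytest.raises(ValueError):
            analytic_tail("nonsense", 1, 10, 3)


class TestBootstrapEstimates:
    @pytest.mark.parametrize(
        "fn,stat,k,n_draws,n_routes",
        [
            (p_focal_at_least, "focal_at_least", 8, 15, 3),
            (p_focal_at_least, "focal_at_least", 5, 24, 6),
            (p_max_at_least, "max_at_least", 8, 15, 3),
            (p_max_at_least, "max_at_least", 10, 24, 3),
            (p_focal_at_most, "focal_at_most", 0, 16, 3),
            (p_focal_at_most, "focal_at_most", 3, 30, 4),
        ],
    )
    def test_monte_carlo_agrees_with_oracle(self, fn, stat, k, n_draws, n_routes):
        iterations = 100_000
        res = fn(k, n_draws, n_routes, iterations=iterations, seed=9)
        exact = float(analytic_tail(stat, k, n_draws, n_routes))
        se = sqrt(max(exact * (1 - exact), 1e-12) / iterations)
        assert abs(res.p_estimate - exact) <= 4 * se

    def test_zero_hit_bound_convention(self):
        res = p_focal_at_least(23, 24, 3, iterations=10_000, seed=1)
        assert res.hits == 0
        assert res.p_bound == "< 1/10000"

    def test_trivial_k_zero_and_full(self):
        assert p_focal_at_least(0, 10, 3, iterations=100, seed=0).p_estimate == 1.0
        assert p_focal_at_most(10, 10, 3, iterations=100, seed=0).p_estimate == 1.0
        assert p_max_at_least(11, 10, 3, iterations=100, seed=0).p_estimate == 0.0

    def test_focal_tail_monotone_in_k(self):
        ps = [
            p_focal_at_least(k, 15, 3, iterations=20_000, seed=4).p_estimate
            for k in (2, 5, 8, 11)
        ]
        assert ps == sorted(ps, reverse=True)

    def test_max_tail_dominates_focal_tail(self):
        kwargs = dict(iterations=50_000, seed=6)
        for k in (5, 7, 9):
            assert (
                p_max_at_least(k, 15, 3, **kwargs).p_estimate
                >= p_focal_at_least(k, 15, 3, **kwargs).p_estimate
            )

    def test_extra_routes_shrink_focal_tail(self):
        # the 3-route pool makes the headline statistic an underestimate:
        # any added route lowers the chance of many focal draws
        for k in (1, 5, 10):
            assert analytic_tail("focal_at_least", k, 24, 4) < analytic_tail(
                "focal_at_least", k, 24, 3
            )


class TestReportP:
    def test_zero_hits_million_iterations(self):
        res = ResamplingResult(
            "focal_at_least", 23, 24, 3, 10**6, 0, 0.0, "< 1/1000000", 1
        )
        assert report_p(res) == "P < 1 × 10⁻⁶"

    def test_point_estimate_formatting(self):
        res = ResamplingResult(
            "max_at_least", 8, 15, 3, 10**6, 264_700, 0.2647, None, 1
        )
        assert report_p(res).startswith("P = 0.2647")

    def test_all_hits(self):
        res = ResamplingResult("focal_at_least", 0, 24, 3, 100, 100, 1.0, None, 1)
        assert report_p(res) == "P = 1"


class TestChisqIndependence:
    def test_df_for_2x4_table(self):
        table = [[20, 18, 22, 19], [4, 6, 2, 5]]
        res = chisq_independence(table)
        assert res.df == 3

    def test_identical_proportions_give_zero(self):
        res = chisq_independence([[10, 20, 30], [1, 2, 3]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # margins 20/20, expected 10 everywhere: chi2 = 4 * 25/10 = 10
        assert chisq_independence([[15, 5], [5, 15]]).chi2 == pytest.approx(10.0)
        assert chisq_independence([[10, 10], [10, 10]]).chi2 == pytest.approx(0.0)

    def test_matches_scipy_without_correction(self, rng):
        table = rng.integers(1, 40, size=(3, 4))
        res = chisq_independence(table)
        chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
        assert res.chi2 == pytest.approx(chi2)
        assert res.p == pytest.approx(p)
        assert res.df == df

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_independence([[0, 0], [5, 3]])


def exact_permutation_p(x, y, sidedness="one"):
    """Enumeration oracle: all C(n1+n2, n1) assignments of pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    ws = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n1)]
    )
    p_low = (ws <= w_obs + 1e-9).mean()
    p_high = (ws >= w_obs - 1e-9).mean()
    if sidedness == "one":
        return min(p_low, p_high)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxonRankSum:
    def test_identical_samples(self):
        res = wilcoxon_rank_sum([1, 1, 2], [1, 2, 1])
        assert res.p == pytest.approx(1.0, abs=0.05)

    def test_all_values_identical_warns_p_one(self):
        res = wilcoxon_rank_sum([3, 3], [3, 3, 3])
        assert res.p == 1.0
        assert "warning" in res.extra

    def test_minimal_rank_sum_exact(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], sidedness="one")
        assert res.statistic == 6.0  # ranks 1+2+3
        assert res.extra["U"] == 0.0
        assert res.p == pytest.approx(1 / 20)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        res = wilcoxon_rank_sum(x, y, sidedness="one")
        assert res.extra["exact"]
        assert res.p == pytest.approx(exact_permutation_p(x, y, "one"), abs=1e-9)

    def test_normal_approximation_close_to_permutation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 8)
        res = wilcoxon_rank_sum(x, y, sidedness="one", exact=False)
        assert res.p == pytest.approx(exact_permutation_p(x, y, "one"), abs=0.01)

    def test_matches_scipy_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0]
        y = [2.0, 4.0, 5.0, 5.0, 6.0, 8.0, 9.0]
        res = wilcoxon_rank_sum(x, y, continuity=True, sidedness="two")
        ref = sps.mannwhitneyu(x, y, use_continuity=True, alternative="two-sided",
                               method="asymptotic")
        assert res.extra["U"] == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestKruskalWallisAndDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula_three_pairs(self):
        # groups {1,2},{3,4},{5,6}: mean ranks 1.5, 3.5, 5.5;
        # H = 12/(6*7) * 2*(1.5^2+3.5^2+5.5^2) - 3*7 = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)
        assert res.extra["df"] == 2

    def test_matches_scipy_with_ties(self, rng):
        groups = [list(rng.integers(0, 6, size=n)) for n in (7, 9, 8)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_h_grows_with_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 40)
        hs = []
        for shift in (0.0, 1.0, 2.0, 4.0):
            groups = [base, base + 0.1, base + shift]
            hs.append(kruskal_wallis(groups).statistic)
        assert hs[-1] > hs[0]
        assert hs == sorted(hs)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_dunn_two_group_z_matches_hand_value(self):
        # groups {1,2},{5,6}: mean ranks 1.5 and 3.5, N=4, no ties;
        # SE = sqrt(N(N+1)/12 * (1/2+1/2)) = sqrt(20/12)
        res = dunn_posthoc([[1, 2], [5, 6]], sidedness="two")[(0, 1)]
        assert res.statistic == pytest.approx((1.5 - 3.5) / sqrt(20 / 12))

    def test_dunn_pairwise_count_and_bonferroni(self):
        groups = [[1, 2, 3], [2, 3, 4], [8, 9, 10]]
        plain = dunn_posthoc(groups)
        adj = dunn_posthoc(groups, bonferroni=True)
        assert len(plain) == 3
        for key in plain:
            assert adj[key].p == pytest.approx(min(1.0, plain[key].p * 3))

    def test_dunn_detects_shifted_group_one_sided(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        c = rng.normal(3, 1, 15)
        res = dunn_posthoc([list(a), list(b), list(c)], sidedness="one")
        assert res[(0, 2)].p < 0.01
        assert res[(0, 1)].p > 0.05
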