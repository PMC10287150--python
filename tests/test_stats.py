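"""Unit tests for the rank-test battery, each checked against an
independent oracle (brute-force enumeration, closed forms, or a reference
library implementation)."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as scipy_stats
from hypothesis import given, settings, strategies as st

from grindex import (
    chi_square_upper_tail,
    dunn_posthoc,
    fisher_exact_rxc,
    kendall_tau_b,
    kruskal_wallis,
    mann_whitney,
    midranks,
    normal_two_sided_p,
)
from grindex.errors import DegenerateDataError, ValidationError

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_ranks(values):
    """Rank by pairwise counting: 1 + #smaller + half the other ties."""
    return [
        1.0
        + sum(1 for w in values if w < v)
        + 0.5 * sum(1 for j, w in enumerate(values) if w == v and j != i)
        for i, v in enumerate(values)
    ]


def oracle_kruskal_h(samples):
    """H from explicit rank construction, independent of the package path."""
    pooled = [v for s in samples for v in s]
    ranks = oracle_ranks(pooled)
    n = len(pooled)
    pos = 0
    stat = 0.0
    for s in samples:
        r = sum(ranks[pos:pos + len(s)])
        stat += r * r / len(s)
        pos += len(s)
    h = 12.0 / (n * (n + 1)) * stat - 3.0 * (n + 1)
    tie = sum(
        c ** 3 - c for c in (pooled.count(v) for v in set(pooled))
    )
    return h / (1.0 - tie / (n ** 3 - n))


def oracle_u(x, y):
    return sum(
        1.0 if xi > yi else 0.5 if xi == yi else 0.0
        for xi in x for yi in y
    )


def oracle_mw_exact_p(x, y):
    """Two-sided exact p by enumerating every labeling of the pooled
    sample: double the smaller tail of the U distribution, capped at 1."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = oracle_u(x, y)
    us = [
        oracle_u([pooled[i] for i in combo],
                 [pooled[i] for i in range(len(pooled)) if i not in combo])
        for combo in itertools.combinations(range(len(pooled)), n1)
    ]
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs) / total
    upper = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(lower, upper))


def oracle_tau_b(x, y):
    """tau-b from brute-force pair counting."""
    n = len(x)
    concordant = discordant = 0
    for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
        s = (xi > xj) - (xi < xj)
        t = (yi > yj) - (yi < yj)
        if s * t > 0:
            concordant += 1
        elif s * t < 0:
            discordant += 1
    n0 = n * (n - 1) // 2
    n1 = sum(
        c * (c - 1) // 2 for c in (x.count(v) for v in set(x))
    )
    n2 = sum(
        c * (c - 1) // 2 for c in (y.count(v) for v in set(y))
    )
    return (concordant - discordant) / math.sqrt((n0 - n1) * (n0 - n2))


def oracle_fisher_p(table):
    """Exact r x c p by full enumeration with rational arithmetic."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)

    def prob(cells):
        num = Fraction(1)
        for r in rows:
            num *= math.factorial(r)
        for c in cols:
            num *= math.factorial(c)
        den = Fraction(math.factorial(total))
        for v in cells:
            den *= math.factorial(v)
        return num / den

    observed = prob([v for row in table for v in row])
    n_rows, n_cols = len(rows), len(cols)

    def tables(row_idx, cols_left):
        if row_idx == n_rows - 1:
            if all(v >= 0 for v in cols_left):
                yield list(cols_left)
            return
        r = rows[row_idx]
        for combo in itertools.product(
            *(range(min(r, c) + 1) for c in cols_left)
        ):
            if sum(combo) == r:
                rest = [c - v for c, v in zip(cols_left, combo)]
                for tail in tables(row_idx + 1, rest):
                    yield list(combo) + tail

    p = sum(
        prob(cells) for cells in tables(0, cols)
        if prob(cells) <= observed
    )
    return float(p)


# ---------------------------------------------------------------------------
# midranks
# ---------------------------------------------------------------------------

class TestMidranks:
    @pytest.mark.parametrize(
        "values,ranks,ties",
        [
            ([10, 20, 30], [1, 2, 3], ()),
            ([5, 5, 7], [1.5, 1.5, 3], (2,)),
            ([4, 4, 4, 4], [2.5, 2.5, 2.5, 2.5], (4,)),
        ],
    )
    def test_examples(self, values, ranks, ties):
        ranked = midranks(values)
        assert list(ranked.midranks) == ranks
        assert ranked.tie_groups == ties

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            midranks([])

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=30))
    def test_rank_sum_invariant(self, values):
        ranked = midranks(values)
        n = len(values)
        assert math.isclose(sum(ranked.midranks), n * (n + 1) / 2)
        assert sum(ranked.tie_groups) <= n
        assert all(t >= 2 for t in ranked.tie_groups)

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=20))
    def test_matches_pairwise_counting_oracle(self, values):
        ranked = midranks(values)
        assert list(ranked.midranks) == pytest.approx(oracle_ranks(values))


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_two_untied_groups(self):
        result = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert result.statistic == pytest.approx(27 / 7, abs=1e-12)  # 3.857
        assert result.df == 1
        assert not result.tie_correction_applied

    def test_symmetric_rank_sums_give_zero(self):
        result = kruskal_wallis([[1, 2], [1, 2]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_equal_rank_sums_three_groups(self):
        # pooled 1..9 split so every group rank-sum is 15
        result = kruskal_wallis([[1, 5, 9], [2, 6, 7], [3, 4, 8]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[2, 2], [2, 2]])

    @given(
        st.lists(
            st.lists(st.integers(1, 4), min_size=1, max_size=6),
            min_size=2, max_size=4,
        )
    )
    def test_matches_brute_force_and_scipy(self, samples):
        pooled = [v for s in samples for v in s]
        if len(set(pooled)) < 2:
            return
        result = kruskal_wallis(samples)
        assert result.statistic == pytest.approx(
            oracle_kruskal_h(samples), abs=1e-10
        )
        ref = scipy_stats.kruskal(*[np.asarray(s, float) for s in samples])
        assert result.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert result.p_value == pytest.approx(ref.pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# Dunn
# ---------------------------------------------------------------------------

class TestDunn:
    def test_two_untied_groups(self):
        (cmp,) = dunn_posthoc([[1, 2, 3], [4, 5, 6]])
        assert cmp.z == pytest.approx(-3 / math.sqrt(3.5 * 2 / 3), abs=1e-12)
        assert cmp.z == pytest.approx(-1.964, abs=5e-4)
        assert cmp.m == 1

    def test_identical_groups(self):
        (cmp,) = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert cmp.z == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_adjusted == 1.0

    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
    )
    def test_antisymmetry_and_bonferroni_bound(self, a, b, c):
        if len(set(a + b + c)) < 2:
            return
        fwd = dunn_posthoc([a, b, c], ["a", "b", "c"])
        rev = dunn_posthoc([c, b, a], ["c", "b", "a"])
        fwd_map = {(x.group_a, x.group_b): x for x in fwd}
        rev_map = {(x.group_a, x.group_b): x for x in rev}
        for (ga, gb), cmp_fwd in fwd_map.items():
            cmp_rev = rev_map[(gb, ga)]
            assert cmp_fwd.z == pytest.approx(-cmp_rev.z, abs=1e-12)
            assert cmp_fwd.p_unadjusted == pytest.approx(
                cmp_rev.p_unadjusted, abs=1e-12
            )
        for cmp_ in fwd:
            assert 0.0 <= cmp_.p_adjusted <= 1.0
            assert cmp_.p_adjusted == pytest.approx(
                min(1.0, cmp_.m * cmp_.p_unadjusted)
            )
            assert cmp_.m == 3

    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=8, unique=True),
        st.lists(st.integers(101, 200), min_size=2, max_size=8, unique=True),
    )
    def test_h_equals_z_squared_for_two_untied_groups(self, a, b):
        h = kruskal_wallis([a, b]).statistic
        (cmp_,) = dunn_posthoc([a, b])
        assert h == pytest.approx(cmp_.z ** 2, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_no_winning_pairs(self):
        result = mann_whitney([1, 2, 3], [4, 5, 6])
        assert result.statistic == 0.0
        assert result.extra["W"] == 0.0
        assert result.extra["W_other_orientation"] == 9.0

    def test_single_pair(self):
        result = mann_whitney([5], [1])
        assert result.statistic == 1.0

    def test_exact_small_sample(self):
        result = mann_whitney([1, 3], [2, 4])
        assert result.statistic == 1.0
        assert result.method == "exact"
        # oracle: enumeration of all C(4,2)=6 labelings
        assert result.p_value == pytest.approx(
            oracle_mw_exact_p([1, 3], [2, 4])
        )
        assert result.p_value == pytest.approx(2 / 3)

    def test_ties_use_normal_approximation(self):
        result = mann_whitney([1, 2, 2], [2, 3, 4])
        assert result.method == "normal_approx"
        assert result.tie_correction_applied

    def test_large_sample_uses_normal_approximation(self):
        x = list(range(21))
        y = [v + 0.5 for v in range(21)]
        assert mann_whitney(x, y).method == "normal_approx"

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1])

    @given(
        st.lists(st.integers(0, 10), min_size=1, max_size=12),
        st.lists(st.integers(0, 10), min_size=1, max_size=12),
    )
    def test_matches_scipy(self, x, y):
        if len(set(x + y)) < 2:
            return
        result = mann_whitney(x, y)
        ref = scipy_stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if result.method == "exact" else "asymptotic",
        )
        assert result.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert result.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    @given(st.data())
    def test_exact_path_matches_enumeration(self, data):
        n1 = data.draw(st.integers(1, 5))
        n2 = data.draw(st.integers(1, 5))
        pooled = data.draw(
            st.lists(
                st.integers(0, 100), min_size=n1 + n2, max_size=n1 + n2,
                unique=True,
            )
        )
        x, y = pooled[:n1], pooled[n1:]
        result = mann_whitney(x, y)
        assert result.method == "exact"
        assert result.p_value == pytest.approx(oracle_mw_exact_p(x, y))


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------

class TestKendallTauB:
    def test_perfect_concordance(self):
        assert kendall_tau_b([1, 2, 3], [1, 2, 3]).statistic == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert kendall_tau_b([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_tied_example_matches_pair_counting(self):
        x, y = [1, 1, 2, 3], [1, 2, 2, 3]
        result = kendall_tau_b(x, y)
        assert result.statistic == pytest.approx(oracle_tau_b(x, y), abs=1e-12)

    def test_constant_variable_is_error(self):
        with pytest.raises(DegenerateDataError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError):
            kendall_tau_b([1, 2], [1, 2, 3])

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)),
            min_size=3, max_size=25,
        )
    )
    def test_range_and_oracle_and_scipy(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        result = kendall_tau_b(x, y)
        assert -1.0 <= result.statistic <= 1.0
        assert result.statistic == pytest.approx(oracle_tau_b(x, y), abs=1e-12)
        ref = scipy_stats.kendalltau(x, y)
        assert result.statistic == pytest.approx(ref.statistic, abs=1e-12)

    @given(
        st.lists(st.integers(0, 1000), min_size=3, max_size=15, unique=True),
        st.lists(st.integers(0, 1000), min_size=15, max_size=15, unique=True),
    )
    def test_equals_tau_a_without_ties(self, x, y):
        x = x[: min(len(x), len(y))]
        y = y[: len(x)]
        if len(x) < 3:
            return
        result = kendall_tau_b(x, y)
        n0 = len(x) * (len(x) - 1) / 2
        tau_a = (
            result.extra["concordant"] - result.extra["discordant"]
        ) / n0
        assert result.statistic == pytest.approx(tau_a, abs=1e-12)


# ---------------------------------------------------------------------------
# Fisher r x c
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_2x2_example(self):
        result = fisher_exact_rxc([[3, 1], [1, 3]])
        assert result.p_value == pytest.approx(34 / 70, abs=1e-10)
        assert result.method == "exact"

    def test_diagonal_2x2(self):
        result = fisher_exact_rxc([[2, 0], [0, 2]])
        assert result.p_value == pytest.approx(1 / 3, abs=1e-10)

    def test_zero_row_dropped(self):
        full = fisher_exact_rxc([[3, 1], [0, 0], [1, 3]])
        reduced = fisher_exact_rxc([[3, 1], [1, 3]])
        assert full.p_value == pytest.approx(reduced.p_value, abs=1e-12)
        assert full.extra["dropped_margins"] == 1

    def test_negative_counts_error(self):
        with pytest.raises(ValidationError):
            fisher_exact_rxc([[1, -1], [2, 3]])

    def test_too_small_after_dropping(self):
        with pytest.raises(ValidationError):
            fisher_exact_rxc([[1, 0], [3, 0]])

    @given(
        st.lists(
            st.lists(st.integers(0, 6), min_size=2, max_size=3),
            min_size=2, max_size=3,
        ).filter(
            lambda t: len({len(r) for r in t}) == 1
            and all(sum(r) > 0 for r in t)
            and all(sum(c) > 0 for c in zip(*t))
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_enumeration_matches_rational_oracle(self, table):
        result = fisher_exact_rxc(table, method="exact")
        assert result.p_value == pytest.approx(
            oracle_fisher_p(table), abs=1e-9
        )

    def test_2x2_matches_scipy(self):
        table = [[7, 2], [3, 9]]
        result = fisher_exact_rxc(table)
        ref = scipy_stats.fisher_exact(table)
        assert result.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("table", [[[3, 1], [1, 3]], [[8, 2, 5], [1, 7, 3], [4, 4, 9]]])
    def test_monte_carlo_converges_to_enumeration(self, table):
        exact = fisher_exact_rxc(table, method="exact").p_value
        n_reps = 100_000
        mc = fisher_exact_rxc(
            table, method="monte_carlo", n_reps=n_reps, seed=17
        )
        assert mc.method == "monte_carlo"
        assert mc.n_reps == n_reps and mc.seed == 17
        se = math.sqrt(exact * (1 - exact) / n_reps)
        assert abs(mc.p_value - exact) <= 3 * se

    def test_monte_carlo_reproducible(self):
        table = [[5, 1, 2], [2, 6, 1]]
        a = fisher_exact_rxc(table, method="monte_carlo", n_reps=5000, seed=3)
        b = fisher_exact_rxc(table, method="monte_carlo", n_reps=5000, seed=3)
        assert a.p_value == b.p_value

    def test_auto_switches_to_monte_carlo_for_large_totals(self):
        table = [[120, 30], [40, 90]]
        result = fisher_exact_rxc(table, n_reps=2000, seed=1)
        assert result.method == "monte_carlo"


# ---------------------------------------------------------------------------
# Tail functions
# ---------------------------------------------------------------------------

class TestTails:
    def test_chi2_at_zero(self):
        for df in (1, 2, 7):
            assert chi_square_upper_tail(0.0, df) == 1.0

    def test_chi2_df2_closed_form(self):
        assert chi_square_upper_tail(2 * math.log(20), 2) == pytest.approx(
            0.05, abs=1e-12
        )

    def test_chi2_df1_normal_identity(self):
        assert chi_square_upper_tail(3.841459, 1) == pytest.approx(
            0.05, abs=1e-6
        )

    @pytest.mark.parametrize("df", [1, 2, 3, 4, 5, 10, 25, 60])
    @pytest.mark.parametrize("x", [0.01, 0.5, 1.0, 3.84, 10.0, 42.0, 150.0])
    def test_chi2_matches_scipy(self, df, x):
        mine = chi_square_upper_tail(x, df)
        ref = scipy_stats.chi2.sf(x, df)
        assert mine == pytest.approx(ref, rel=1e-10, abs=1e-300)

    def test_chi2_monotone_decreasing(self):
        values = [chi_square_upper_tail(x, 3) for x in (0.0, 0.5, 1, 2, 5, 10)]
        assert values == sorted(values, reverse=True)

    def test_chi2_invalid(self):
        with pytest.raises(ValidationError):
            chi_square_upper_tail(1.0, 0)
        with pytest.raises(ValidationError):
            chi_square_upper_tail(-1.0, 2)

    def test_normal_two_sided(self):
        assert normal_two_sided_p(0.0) == 1.0
        assert normal_two_sided_p(1.959964) == pytest.approx(0.05, abs=1e-6)

    @given(st.floats(-8, 8))
    def test_normal_symmetry_and_range(self, z):
        p = normal_two_sided_p(z)
        assert 0.0 <= p <= 1.0
        assert p == normal_two_sided_p(-z)
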