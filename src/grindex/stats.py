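"""Tie-corrected nonparametric test battery, implemented from the formulas.

Everything here is written from first principles on top of mid-ranks with
explicit tie bookkeeping: the tie-corrected Kruskal-Wallis H, Dunn's
pairwise z with Bonferroni adjustment, the Mann-Whitney U / rank-sum W test
(exact null enumeration for small untied samples, tie-corrected normal
approximation with continuity correction otherwise), Kendall's tau-b with
the tie-adjusted normal approximation, and Fisher's exact test for r x c
tables (full enumeration of the margin-conditioned support when feasible,
seeded Monte-Carlo otherwise).  The chi-square and normal tail functions
these need are provided here as well, so the module has no dependency on an
external statistics library; library implementations are used only as
independent cross-check oracles in the test suite.

Conventions: all p-values are two-sided; the first sample/group passed in
defines the orientation of signed statistics (W, Dunn's z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "RankedSample",
    "TestResult",
    "PairwiseComparison",
    "midranks",
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney",
    "kendall_tau_b",
    "fisher_exact_rxc",
    "chi_square_upper_tail",
    "normal_two_sided_p",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedSample:
    """Values with their mid-ranks and tie bookkeeping.

    ``tie_groups`` lists the size t of every run of equal values with
    t >= 2; these sizes feed the Sum(t^3 - t) tie corrections.
    """

    values: tuple[float, ...]
    midranks: tuple[float, ...]
    tie_groups: tuple[int, ...]
    n: int

    @property
    def tie_term(self) -> float:
        """Sum of t^3 - t over tie groups."""
        return float(sum(t ** 3 - t for t in self.tie_groups))


@dataclass
class TestResult:
    """A test outcome with full method metadata, JSON-serializable."""

    test_name: str
    statistic_name: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    method: str = "exact"  # exact | normal_approx | chi2_approx | monte_carlo
    n_reps: Optional[int] = None
    seed: Optional[int] = None
    group_labels: Optional[tuple[str, ...]] = None
    sample_sizes: Optional[tuple[int, ...]] = None
    tie_correction_applied: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "method": self.method,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "group_labels": list(self.group_labels) if self.group_labels else None,
            "sample_sizes": list(self.sample_sizes) if self.sample_sizes else None,
            "tie_correction_applied": self.tie_correction_applied,
            "extra": self.extra,
        }


@dataclass(frozen=True)
class PairwiseComparison:
    """One Dunn post-hoc contrast; ``z`` is mean-rank(a) minus mean-rank(b)
    standardized, so swapping the groups flips its sign."""

    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float
    m: int

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "z": self.z,
            "p_unadjusted": self.p_unadjusted,
            "p_adjusted": self.p_adjusted,
            "m": self.m,
        }


# ---------------------------------------------------------------------------
# Distribution tails
# ---------------------------------------------------------------------------

def normal_two_sided_p(z: float) -> float:
    """Two-sided standard-normal tail probability, 2*(1 - Phi(|z|))."""
    if not math.isfinite(z):
        raise ValidationError("z must be finite")
    return math.erfc(abs(z) / math.sqrt(2.0))


def chi_square_upper_tail(x: float, df: int) -> float:
    """Upper-tail chi-square probability Q(df/2, x/2) for integer df >= 1.

    Uses the closed forms Q(x; 1) = erfc(sqrt(x/2)) and Q(x; 2) = exp(-x/2)
    plus the stable upward recurrence
    Q(x; v+2) = Q(x; v) + (x/2)^(v/2) exp(-x/2) / Gamma(v/2 + 1),
    which sums only positive terms.
    """
    if not isinstance(df, (int, np.integer)) or df < 1:
        raise ValidationError(f"df must be a positive integer, got {df!r}")
    if x < 0 or not math.isfinite(x):
        raise ValidationError(f"x must be finite and >= 0, got {x!r}")
    if x == 0.0:
        return 1.0

    half_x = x / 2.0
    if df % 2 == 1:
        q = math.erfc(math.sqrt(half_x))
        nu = 1
    else:
        q = math.exp(-half_x)
        nu = 2
    log_half_x = math.log(half_x)
    while nu < df:
        # add (x/2)^(nu/2) * exp(-x/2) / Gamma(nu/2 + 1)
        log_term = (nu / 2.0) * log_half_x - half_x - math.lgamma(nu / 2.0 + 1.0)
        q += math.exp(log_term)
        nu += 2
    return min(q, 1.0)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def midranks(values: Sequence[float]) -> RankedSample:
    """Mid-ranks of ``values``: tied observations share the mean of the
    ranks they jointly occupy."""
    n = len(values)
    if n == 0:
        raise ValidationError("cannot rank an empty sample")
    vals = [float(v) for v in values]
    if not all(math.isfinite(v) for v in vals):
        raise ValidationError("values must be finite")

    order = sorted(range(n), key=lambda i: vals[i])
    ranks = [0.0] * n
    tie_groups: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        mean_rank = (i + j + 2) / 2.0  # ranks are 1-based: (i+1 .. j+1)
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        if j > i:
            tie_groups.append(j - i + 1)
        i = j + 1
    return RankedSample(
        values=tuple(vals),
        midranks=tuple(ranks),
        tie_groups=tuple(tie_groups),
        n=n,
    )


def _pooled_ranks(samples: Sequence[Sequence[float]]) -> tuple[RankedSample, list[list[float]]]:
    pooled: list[float] = [float(v) for group in samples for v in group]
    ranked = midranks(pooled)
    per_group: list[list[float]] = []
    pos = 0
    for group in samples:
        per_group.append(list(ranked.midranks[pos:pos + len(group)]))
        pos += len(group)
    return ranked, per_group


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn
# ---------------------------------------------------------------------------

def _check_groups(samples: Sequence[Sequence[float]]) -> None:
    if len(samples) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(g) == 0 for g in samples):
        raise ValidationError("every group must be non-empty")


def kruskal_wallis(
    samples: Sequence[Sequence[float]],
    group_labels: Optional[Sequence[str]] = None,
) -> TestResult:
    """Tie-corrected Kruskal-Wallis rank test over k >= 2 groups.

    H = [12 / (N(N+1)) * Sum_j R_j^2 / n_j - 3(N+1)] / C with the tie
    correction C = 1 - Sum(t^3 - t) / (N^3 - N); the p-value is the
    chi-square upper tail at k-1 degrees of freedom.
    """
    _check_groups(samples)
    ranked, group_ranks = _pooled_ranks(samples)
    n_total = ranked.n
    correction = 1.0 - ranked.tie_term / (n_total ** 3 - n_total)
    if correction == 0.0:
        raise DegenerateDataError(
            "all pooled values are identical; H is undefined"
        )
    h_uncorrected = (
        12.0 / (n_total * (n_total + 1))
        * sum(sum(r) ** 2 / len(r) for r in group_ranks)
        - 3.0 * (n_total + 1)
    )
    h = h_uncorrected / correction
    k = len(samples)
    df = k - 1
    labels = tuple(group_labels) if group_labels else tuple(
        f"group{i + 1}" for i in range(k)
    )
    return TestResult(
        test_name="kruskal_wallis",
        statistic_name="H",
        statistic=h,
        p_value=chi_square_upper_tail(max(h, 0.0), df),
        df=df,
        method="chi2_approx",
        group_labels=labels,
        sample_sizes=tuple(len(g) for g in samples),
        tie_correction_applied=bool(ranked.tie_groups),
        extra={"tie_term": ranked.tie_term, "n_total": n_total},
    )


def dunn_posthoc(
    samples: Sequence[Sequence[float]],
    group_labels: Optional[Sequence[str]] = None,
    adjustment: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Dunn's tie-corrected pairwise z tests on the pooled mid-ranking.

    For groups i, j:
    z = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - Sum(t^3-t)/(12(N-1))] *
    (1/n_i + 1/n_j)); two-sided normal p, Bonferroni-adjusted over all
    m = k(k-1)/2 comparisons (p_adj = min(1, m*p)).
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValidationError(f"unknown adjustment {adjustment!r}")
    _check_groups(samples)
    ranked, group_ranks = _pooled_ranks(samples)
    n_total = ranked.n
    variance_scale = (
        n_total * (n_total + 1) / 12.0
        - ranked.tie_term / (12.0 * (n_total - 1))
    )
    if variance_scale <= 0.0:
        raise DegenerateDataError(
            "all pooled values are identical; Dunn's z is undefined"
        )
    k = len(samples)
    labels = tuple(group_labels) if group_labels else tuple(
        f"group{i + 1}" for i in range(k)
    )
    mean_ranks = [sum(r) / len(r) for r in group_ranks]
    m = k * (k - 1) // 2
    comparisons: list[PairwiseComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(
                variance_scale * (1.0 / len(samples[i]) + 1.0 / len(samples[j]))
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = normal_two_sided_p(z)
            p_adj = min(1.0, m * p) if adjustment == "bonferroni" else p
            comparisons.append(
                PairwiseComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    z=z,
                    p_unadjusted=p,
                    p_adjusted=p_adj,
                    m=m,
                )
            )
    return comparisons


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of labelings per U value (0..n1*n2) under the untied null.

    Classic recursion c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1):
    the largest pooled observation belongs to x (contributing n to U)
    or to y (contributing nothing).
    """
    memo: dict[tuple[int, int], list[int]] = {}

    def counts(m: int, n: int) -> list[int]:
        if m == 0 or n == 0:
            return [1]
        key = (m, n)
        if key in memo:
            return memo[key]
        out = [0] * (m * n + 1)
        for u, c in enumerate(counts(m - 1, n)):  # support 0..(m-1)n, shift n
            out[u + n] += c
        for u, c in enumerate(counts(m, n - 1)):  # support 0..m(n-1)
            out[u] += c
        memo[key] = out
        return out

    full = counts(n1, n2)
    full += [0] * (n1 * n2 + 1 - len(full))
    return tuple(full)


def _mann_whitney_exact_p(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p for integer U under the untied null: double the
    smaller tail, capped at 1 (the convention of standard exact routines)."""
    counts = _u_counts(n1, n2)
    total = sum(counts)
    ui = int(round(u))
    lower = sum(counts[: ui + 1]) / total
    upper = sum(counts[ui:]) / total
    return min(1.0, 2.0 * min(lower, upper))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    group_labels: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Mann-Whitney U / Wilcoxon rank-sum test of two samples.

    U counts pairs (x_i, y_j) with x_i > y_j, ties counting 1/2; it equals
    W = rank-sum(x) - n1(n1+1)/2, and both names are reported.  ``auto``
    uses exact null enumeration when both n <= 20 and there are no ties,
    otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal_approx"):
        raise ValidationError(f"unknown method {method!r}")
    n1, n2 = len(x), len(y)
    ranked, (rx, _ry) = _pooled_ranks([list(x), list(y)])
    has_ties = bool(ranked.tie_groups)
    w = sum(rx) - n1 * (n1 + 1) / 2.0  # equals U with half-counted ties
    u = w

    use_exact = (
        method == "exact"
        or (method == "auto" and not has_ties and n1 <= 20 and n2 <= 20)
    )
    if use_exact and has_ties:
        raise ValidationError("exact method is only defined without ties")

    if use_exact:
        p = _mann_whitney_exact_p(u, n1, n2)
        used = "exact"
    else:
        n_total = n1 + n2
        mu = n1 * n2 / 2.0
        sigma2 = (
            n1 * n2 / 12.0
            * ((n_total + 1) - ranked.tie_term / (n_total * (n_total - 1)))
        )
        if sigma2 <= 0.0:
            raise DegenerateDataError("all pooled values identical")
        diff = u - mu
        correction = 0.5 * (1 if diff > 0 else -1 if diff < 0 else 0)
        z = (diff - correction) / math.sqrt(sigma2)
        p = normal_two_sided_p(z)
        used = "normal_approx"

    return TestResult(
        test_name="mann_whitney",
        statistic_name="U",
        statistic=u,
        p_value=p,
        method=used,
        group_labels=group_labels,
        sample_sizes=(n1, n2),
        tie_correction_applied=has_ties and used == "normal_approx",
        extra={"W": w, "W_other_orientation": n1 * n2 - w},
    )


# ---------------------------------------------------------------------------
# Kendall's tau-b
# ---------------------------------------------------------------------------

def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall's tau-b rank correlation with tie-adjusted normal p-value.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and
    n1, n2 = Sum t(t-1)/2 over tie groups of x and y; the two-sided p comes
    from the normal approximation of C - D with the tie-adjusted variance.
    """
    if len(x) != len(y):
        raise ValidationError("x and y must be paired (equal length)")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 pairs")
    xv = [float(v) for v in x]
    yv = [float(v) for v in y]
    if len(set(xv)) < 2 or len(set(yv)) < 2:
        raise DegenerateDataError(
            "correlation undefined for a constant variable"
        )

    concordant = discordant = 0
    for i in range(n):
        xi, yi = xv[i], yv[i]
        for j in range(i + 1, n):
            sx = (xi > xv[j]) - (xi < xv[j])
            sy = (yi > yv[j]) - (yi < yv[j])
            s = sx * sy
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1

    def tie_sizes(values: list[float]) -> list[int]:
        counts: dict[float, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        return [c for c in counts.values() if c >= 2]

    tx = tie_sizes(xv)
    ty = tie_sizes(yv)
    n0 = n * (n - 1) // 2
    n1_ties = sum(t * (t - 1) // 2 for t in tx)
    n2_ties = sum(t * (t - 1) // 2 for t in ty)
    s = concordant - discordant
    tau_b = s / math.sqrt((n0 - n1_ties) * (n0 - n2_ties))

    # tie-adjusted variance of S (Kendall 1970; as used by standard
    # correlation-test implementations in the presence of ties)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(t * (t - 1) * (2 * t + 5) for t in ty)
    v1 = (
        sum(t * (t - 1) for t in tx) * sum(t * (t - 1) for t in ty)
        / (2.0 * n * (n - 1))
    )
    v2 = 0.0
    if n > 2:
        v2 = (
            sum(t * (t - 1) * (t - 2) for t in tx)
            * sum(t * (t - 1) * (t - 2) for t in ty)
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0.0:
        raise DegenerateDataError("variance of S is non-positive")
    z = s / math.sqrt(var_s)
    return TestResult(
        test_name="kendall_tau_b",
        statistic_name="tau_b",
        statistic=tau_b,
        p_value=normal_two_sided_p(z),
        method="normal_approx",
        sample_sizes=(n,),
        tie_correction_applied=bool(tx or ty),
        extra={
            "S": s,
            "z": z,
            "concordant": concordant,
            "discordant": discordant,
        },
    )


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables
# ---------------------------------------------------------------------------

def _table_log_prob(cells: Sequence[int], log_fixed: float) -> float:
    return log_fixed - sum(math.lgamma(c + 1) for c in cells)


def _enumeration_bound(row_sums: Sequence[int], n_cols: int) -> float:
    """Upper bound on the number of tables with the given margins: the
    product over all but the last row of the compositions count."""
    bound = 1.0
    for r in row_sums[:-1]:
        bound *= math.comb(r + n_cols - 1, n_cols - 1)
        if bound > 1e15:
            break
    return bound


def _enumerate_p(
    row_sums: list[int], col_sums: list[int], log_p_obs: float, log_fixed: float
) -> float:
    """Sum the probabilities of all margin-matching tables at least as
    extreme (probability <= observed, within relative tolerance 1e-7)."""
    n_rows, n_cols = len(row_sums), len(col_sums)
    threshold = log_p_obs + 1e-7
    total = 0.0

    cols_left = list(col_sums)
    cells: list[int] = []

    def fill_row(row: int, col: int, remaining: int) -> None:
        nonlocal total
        if row == n_rows - 1:
            # last row forced by column margins
            last = cols_left.copy()
            if sum(last) != row_sums[-1]:
                return
            lp = _table_log_prob(cells + last, log_fixed)
            if lp <= threshold:
                total += math.exp(lp)
            return
        if col == n_cols - 1:
            if remaining > cols_left[col]:
                return
            cells.append(remaining)
            cols_left[col] -= remaining
            fill_row(row + 1, 0, row_sums[row + 1])
            cols_left[col] += remaining
            cells.pop()
            return
        upper = min(remaining, cols_left[col])
        for v in range(upper + 1):
            cells.append(v)
            cols_left[col] -= v
            fill_row(row, col + 1, remaining - v)
            cols_left[col] += v
            cells.pop()

    fill_row(0, 0, row_sums[0])
    return min(total, 1.0)


def _monte_carlo_p(
    table: np.ndarray,
    log_p_obs: float,
    log_fixed: float,
    n_reps: int,
    seed: Optional[int],
) -> float:
    """Monte-Carlo p: sample tables from the margin-conditioned null by
    shuffling column labels against fixed row labels."""
    rng = np.random.default_rng(seed)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n_rows, n_cols = table.shape
    row_labels = np.repeat(np.arange(n_rows), row_sums)
    col_labels = np.repeat(np.arange(n_cols), col_sums)
    threshold = log_p_obs + 1e-7
    lgamma_cache = np.array(
        [math.lgamma(c + 1) for c in range(int(table.sum()) + 1)]
    )
    hits = 0
    flat_index_base = row_labels * n_cols
    for _ in range(n_reps):
        rng.shuffle(col_labels)
        counts = np.bincount(
            flat_index_base + col_labels, minlength=n_rows * n_cols
        )
        lp = log_fixed - lgamma_cache[counts].sum()
        if lp <= threshold:
            hits += 1
    return (hits + 1) / (n_reps + 1)


def fisher_exact_rxc(
    table: Sequence[Sequence[int]],
    method: str = "auto",
    n_reps: int = 100_000,
    seed: Optional[int] = None,
    max_total: int = 200,
    max_tables: float = 1e6,
) -> TestResult:
    """Fisher's exact test of independence for an r x c count table.

    The p-value sums the multivariate-hypergeometric probabilities (margins
    fixed) of every table whose probability is at most that of the observed
    table (relative tolerance 1e-7).  ``auto`` enumerates the support fully
    when the grand total is <= ``max_total`` and a cheap bound on the number
    of margin-matching tables is <= ``max_tables``; otherwise it samples
    ``n_reps`` tables from the conditioned null (p estimated as
    (hits+1)/(n_reps+1), seed recorded).  All-zero rows/columns are dropped
    before testing and flagged in ``extra``.
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValidationError(f"unknown method {method!r}")
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2:
        raise ValidationError("table must be 2-dimensional")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")

    row_keep = arr.sum(axis=1) > 0
    col_keep = arr.sum(axis=0) > 0
    dropped = (~row_keep).sum() + (~col_keep).sum()
    arr = arr[row_keep][:, col_keep]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(
            "need at least 2 non-empty rows and 2 non-empty columns"
        )

    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    total = int(arr.sum())
    log_fixed = (
        sum(math.lgamma(r + 1) for r in row_sums)
        + sum(math.lgamma(c + 1) for c in col_sums)
        - math.lgamma(total + 1)
    )
    log_p_obs = _table_log_prob([int(c) for c in arr.ravel()], log_fixed)

    if method == "exact":
        enumerable = True
    elif method == "monte_carlo":
        enumerable = False
    else:
        enumerable = (
            total <= max_total
            and _enumeration_bound(list(row_sums), arr.shape[1]) <= max_tables
        )

    if enumerable:
        p = _enumerate_p(
            [int(r) for r in row_sums], [int(c) for c in col_sums],
            log_p_obs, log_fixed,
        )
        return TestResult(
            test_name="fisher_exact",
            statistic_name="p",
            statistic=p,
            p_value=p,
            method="exact",
            sample_sizes=tuple(int(r) for r in row_sums),
            extra={"dropped_margins": int(dropped), "table_shape": list(arr.shape)},
        )
    p = _monte_carlo_p(arr, log_p_obs, log_fixed, n_reps, seed)
    return TestResult(
        test_name="fisher_exact",
        statistic_name="p",
        statistic=p,
        p_value=p,
        method="monte_carlo",
        n_reps=n_reps,
        seed=seed,
        sample_sizes=tuple(int(r) for r in row_sums),
        extra={"dropped_margins": int(dropped), "table_shape": list(arr.shape)},
    )
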