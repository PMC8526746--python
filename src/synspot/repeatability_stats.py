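"""Equal-weight bootstrap nulls for mutational repeatability, with exact
analytic oracles, plus the classical rank and contingency tests used around
them.

The central question: if every observed one-step mutational route were
equally likely to appear and to fix, how surprising is the observed spectrum
— e.g. one route taken in 23 of 24 independent lines? The null is simulated
by drawing, for each of ``n_draws`` lines, one of ``n_routes`` equally
weighted routes, over many iterations (default 10^6), and counting
iterations at least as extreme as the observation. Three tail statistics
are provided:

``focal_at_least``
    the a-priori named focal route is drawn >= k times;
``max_at_least``
    *any* route is drawn >= k times (no route named in advance);
``focal_at_most``
    the focal route is drawn <= k times (e.g. 0 of 16 invasion replicates).

When an empirical tail registers zero hits the p-value is reported as the
strict bound ``< 1/iterations``, never as zero. Exact tail probabilities
for all three statistics are available through :func:`analytic_tail`
(rational arithmetic, inclusion–exclusion for the maximum statistic).

Because the route pool is restricted to the observed routes, the
focal-route tails are conservative: adding any further route at any weight
only shrinks them.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as _sps

DEFAULT_ITERATIONS = 1_000_000

_STATISTICS = ("focal_at_least", "max_at_least", "focal_at_most")


@dataclass(frozen=True)
class ResamplingResult:
    """Outcome of an equal-weight bootstrap tail estimate."""

    statistic: str
    k: int
    n_draws: int
    n_routes: int
    iterations: int
    hits: int
    p_estimate: float
    p_bound: str | None
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.hits <= self.iterations:
            raise ValueError("hits outside 0..iterations")


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class RankTestResult:
    test: str
    statistic: float
    p: float
    sidedness: str = "two"
    continuity: bool = False
    extra: dict | None = None


# ---------------------------------------------------------------------------
# bootstrap machinery


def resample_counts(
    n_draws: int, n_routes: int, iterations: int, seed: int
) -> np.ndarray:
    """Per-iteration route-count vectors under the equal-weight null.

    Returns an ``(iterations, n_routes)`` integer array; each row sums to
    ``n_draws``. Deterministic under ``seed``.
    """
    if n_draws < 1 or n_routes < 1 or iterations < 1:
        raise ValueError("n_draws, n_routes and iterations must all be >= 1")
    rng = np.random.default_rng(seed)
    p = np.full(n_routes, 1.0 / n_routes)
    return rng.multinomial(n_draws, p, size=iterations)


def _result(
    statistic: str,
    k: int,
    n_draws: int,
    n_routes: int,
    iterations: int,
    hits: int,
    seed: int,
) -> ResamplingResult:
    bound = f"< 1/{iterations}" if hits == 0 else None
    return ResamplingResult(
        statistic=statistic,
        k=k,
        n_draws=n_draws,
        n_routes=n_routes,
        iterations=iterations,
        hits=hits,
        p_estimate=hits / iterations,
        p_bound=bound,
        seed=seed,
    )


def p_focal_at_least(
    k: int,
    n_draws: int,
    n_routes: int,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> ResamplingResult:
    """P(focal route drawn >= k times) under the equal-weight null."""
    if not 0 <= k <= n_draws:
        raise ValueError(f"k={k} outside 0..{n_draws}")
    counts = resample_counts(n_draws, n_routes, iterations, seed)
    hits = int((counts[:, 0] >= k).sum())
    return _result("focal_at_least", k, n_draws, n_routes, iterations, hits, seed)


def p_max_at_least(
    k: int,
    n_draws: int,
    n_routes: int,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> ResamplingResult:
    """P(the most-drawn route reaches >= k) under the equal-weight null."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > n_draws:
        # unreachable threshold: report exactly, skipping simulation
        return _result("max_at_least", k, n_draws, n_routes, iterations, 0, seed)
    counts = resample_counts(n_draws, n_routes, iterations, seed)
    hits = int((counts.max(axis=1) >= k).sum())
    return _result("max_at_least", k, n_draws, n_routes, iterations, hits, seed)


def p_focal_at_most(
    k: int,
    n_draws: int,
    n_routes: int,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> ResamplingResult:
    """P(focal route drawn <= k times) under the equal-weight null."""
    if not 0 <= k <= n_draws:
        raise ValueError(f"k={k} outside 0..{n_draws}")
    counts = resample_counts(n_draws, n_routes, iterations, seed)
    hits = int((counts[:, 0] <= k).sum())
    return _result("focal_at_most", k, n_draws, n_routes, iterations, hits, seed)


def _binomial_tail_ge(k: int, n: int, p: Fraction) -> Fraction:
    return sum(
        (Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)),
        Fraction(0),
    )


def _all_ge_k(m: int, k: int, n: int, r: int) -> Fraction:
    """P(each of m specified routes drawn >= k) with r equal routes, n draws.

    Exponential-generating-function convolution in exact rationals:
    P = n!/r^n * [x^n] (sum_{c>=k} x^c/c!)^m * (e_x truncated)^(r-m).
    """
    if m * k > n:
        return Fraction(0)

    def poly_mul(a: list[Fraction], b: list[Fraction]) -> list[Fraction]:
        out = [Fraction(0)] * (n + 1)
        for i, ai in enumerate(a):
            if not ai:
                continue
            for j, bj in enumerate(b):
                if i + j > n:
                    break
                if bj:
                    out[i + j] += ai * bj
        return out

    from math import factorial

    full = [Fraction(1, factorial(c)) for c in range(n + 1)]
    tail = [Fraction(0)] * k + full[k:]

    poly = [Fraction(1)] + [Fraction(0)] * n
    for _ in range(m):
        poly = poly_mul(poly, tail)
    for _ in range(r - m):
        poly = poly_mul(poly, full)
    return poly[n] * factorial(n) / Fraction(r) ** n


def analytic_tail(statistic: str, k: int, n_draws: int, n_routes: int) -> Fraction:
    """Exact tail probability for a bootstrap statistic (rational result).

    ``max_at_least`` uses inclusion–exclusion over which routes exceed the
    threshold; the other two are binomial tails of Bin(n_draws, 1/n_routes).
    Limited to ``n_draws <= 200`` to keep the exact arithmetic bounded.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_draws > 200:
        raise ValueError("analytic_tail supports n_draws <= 200")
    if n_draws < 1 or n_routes < 1:
        raise ValueError("n_draws and n_routes must be >= 1")
    p = Fraction(1, n_routes)
    if statistic == "focal_at_least":
        if k <= 0:
            return Fraction(1)
        if k > n_draws:
            return Fraction(0)
        return _binomial_tail_ge(k, n_draws, p)
    if statistic == "focal_at_most":
        if k < 0:
            return Fraction(0)
        if k >= n_draws:
            return Fraction(1)
        return 1 - _binomial_tail_ge(k + 1, n_draws, p)
    # max_at_least
    if k <= 0:
        return Fraction(1)
    if k > n_draws:
        return Fraction(0)
    total = Fraction(0)
    for m in range(1, n_routes + 1):
        if m * k > n_draws:
            break
        term = _all_ge_k(m, k, n_draws, n_routes)
        total += (-1) ** (m + 1) * comb(n_routes, m) * term
    return total


def report_p(result: ResamplingResult) -> str:
    """Human-readable p string following the zero-hit bound convention."""
    if result.hits == 0:
        exp = int(np.log10(result.iterations))
        if 10**exp == result.iterations:
            return f"P < 1 × 10⁻{_superscript(exp)}"
        return f"P < {1 / result.iterations:g}"
    if result.hits == result.iterations:
        return "P = 1"
    return f"P = {result.p_estimate:.4g} ({result.iterations} iterations)"


def _superscript(n: int) -> str:
    return "".join("⁰¹²³⁴⁵⁶⁷⁸⁹"[int(d)] for d in str(n))


# ---------------------------------------------------------------------------
# classical tests (first-principles implementations)


def chisq_independence(table) -> ContingencyResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ContingencyResult(chi2=chi2, df=df, p=float(_sps.chi2.sf(chi2, df)))


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks for ties (1-based midranks)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _tie_sizes(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def _rank_sum_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of rank-sum values for sample 1 over all C(n1+n2, n1) splits.

    Index i holds the number of assignments with rank sum
    ``n1(n1+1)/2 + i``. Classic dynamic program over distinct ranks.
    """
    max_u = n1 * n2
    # recurrence over ranks: each added rank either joins sample 1 or not
    w = np.zeros((n1 + 1, max_u + 1))
    w[0, 0] = 1.0
    for rank in range(1, n1 + n2 + 1):
        for m in range(min(n1, rank), 0, -1):
            shift = rank - m  # contribution to U when this rank joins sample 1
            if shift <= max_u:
                w[m, shift:] += w[m - 1, : max_u + 1 - shift]
    return w[n1]


def wilcoxon_rank_sum(
    x,
    y,
    continuity: bool = True,
    sidedness: str = "two",
    exact: bool | None = None,
) -> RankTestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test.

    The reported statistic W is the rank sum of `x` in the pooled midranks;
    the equivalent Mann–Whitney U is exposed in ``extra``. Small tie-free
    samples (both n <= 25) use the exact null distribution of W; otherwise
    the normal approximation with tie correction and, when requested, a 0.5
    continuity correction toward the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be nonempty")
    if sidedness not in ("one", "two"):
        raise ValueError("sidedness must be 'one' or 'two'")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1, n2 = len(x), len(y)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2
    ties = _tie_sizes(pooled)
    has_ties = (ties > 1).any()

    if len(np.unique(pooled)) == 1:
        return RankTestResult(
            test="wilcoxon_rank_sum", statistic=w, p=1.0,
            sidedness=sidedness, continuity=continuity,
            extra={"U": u, "warning": "all values identical"},
        )

    if exact is None:
        exact = not has_ties and n1 <= 25 and n2 <= 25
    if exact and has_ties:
        raise ValueError("exact distribution undefined with ties")

    if exact:
        dist = _rank_sum_distribution(n1, n2)
        total = dist.sum()
        ui = int(round(u))
        p_low = dist[: ui + 1].sum() / total
        p_high = dist[ui:].sum() / total
        if sidedness == "one":
            p = min(p_low, p_high)
        else:
            p = min(1.0, 2 * min(p_low, p_high))
        return RankTestResult(
            test="wilcoxon_rank_sum", statistic=w, p=float(p),
            sidedness=sidedness, continuity=False,
            extra={"U": u, "exact": True},
        )

    n = n1 + n2
    mean_w = n1 * (n + 1) / 2
    tie_term = (ties**3 - ties).sum() / (n * (n - 1)) if n > 1 else 0.0
    var_w = n1 * n2 / 12 * ((n + 1) - tie_term)
    diff = w - mean_w
    cc = 0.5 if continuity else 0.0
    if diff > 0:
        z = (diff - cc) / sqrt(var_w)
    elif diff < 0:
        z = (diff + cc) / sqrt(var_w)
    else:
        z = 0.0
    if sidedness == "one":
        p = float(_sps.norm.sf(abs(z)))
    else:
        p = float(2 * _sps.norm.sf(abs(z)))
    return RankTestResult(
        test="wilcoxon_rank_sum", statistic=w, p=min(1.0, p),
        sidedness=sidedness, continuity=continuity,
        extra={"U": u, "z": z, "exact": False},
    )


def kruskal_wallis(groups: list) -> RankTestResult:
    """Kruskal–Wallis H test with tie correction, df = groups − 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + len(a)]
        h += r.sum() ** 2 / len(a)
        start += len(a)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = _tie_sizes(pooled)
    correction = 1 - (ties**3 - ties).sum() / (n**3 - n)
    if correction == 0:  # all values identical
        h_corr = 0.0
    else:
        h_corr = h / correction
    df = len(groups) - 1
    return RankTestResult(
        test="kruskal_wallis",
        statistic=float(h_corr),
        p=float(_sps.chi2.sf(h_corr, df)),
        extra={"df": df},
    )


def dunn_posthoc(
    groups: list, sidedness: str = "two", bonferroni: bool = False
) -> dict[tuple[int, int], RankTestResult]:
    """Dunn's post-hoc pairwise Z tests on the pooled midranks.

    Returns a mapping from group-index pairs (i, j) to results. No multiple
    testing adjustment unless ``bonferroni`` is set.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _midranks(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + len(a)].mean())
        start += len(a)
    ties = _tie_sizes(pooled)
    tie_corr = (ties**3 - ties).sum() / (12 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12 - tie_corr
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out: dict[tuple[int, int], RankTestResult] = {}
    for i, j in combinations(range(len(groups)), 2):
        se = sqrt(base_var * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        if sidedness == "one":
            p = float(_sps.norm.sf(abs(z)))
        else:
            p = float(2 * _sps.norm.sf(abs(z)))
        if bonferroni:
            p = min(1.0, p * n_pairs)
        out[(i, j)] = RankTestResult(
            test="dunn", statistic=float(z), p=p, sidedness=sidedness
        )
    return out
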