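"""Shared statistical primitives.

The pipeline's inferential machinery — the conditional Fisher 2x2 test,
Benjamini–Hochberg step-up adjustment, the Wilcoxon rank-sum test, Pearson
correlation, and the Mann–Whitney AUROC — is implemented here from first
principles so every downstream module shares one set of conventions
(two-tailed by default, minimum-likelihood two-sided definitions,
Haldane–Anscombe correction for reporting only).  SciPy is used only for
special functions (log-gamma, t/normal tail probabilities), never for the
tests themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import special

Sidedness = Literal["greater", "less", "two"]

#: Relative tolerance when comparing outcome probabilities in
#: minimum-likelihood two-sided tests.
TWO_SIDED_RTOL = 1e-12

__all__ = [
    "Table2x2",
    "TestResult",
    "fisher_exact_2x2",
    "bh_adjust",
    "rank_sum_test",
    "pearson_r",
    "auroc",
]


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table: rows = in-set/out-of-set, cols = target/non-target."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``q`` is filled in by the caller after multiplicity adjustment; ``effect``
    is an odds ratio (Fisher) or rank-biserial correlation (rank-sum).
    """

    statistic: float
    p: float
    sidedness: Sidedness
    effect: float = math.nan
    q: float | None = None

    def with_q(self, q: float) -> "TestResult":
        return TestResult(self.statistic, self.p, self.sidedness, self.effect, q)


def _check_sidedness(sidedness: str) -> None:
    if sidedness not in ("greater", "less", "two"):
        raise ValueError(f"sidedness must be 'greater', 'less' or 'two', got {sidedness!r}")


def _hypergeom_logpmf_support(table: Table2x2) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of the conditional (hypergeometric) law over its full support.

    Conditions on both margins; the support variable is the top-left cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1 = a + b  # in-set margin
    c1 = a + c  # target margin
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    lg = special.gammaln
    logpmf = (
        lg(r1 + 1) - lg(k + 1) - lg(r1 - k + 1)
        + lg(n - r1 + 1) - lg(c1 - k + 1) - lg(n - r1 - (c1 - k) + 1)
        - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
    )
    return k, logpmf


def fisher_exact_2x2(table: Table2x2, sidedness: Sidedness = "two") -> TestResult:
    """Fisher's exact test for a 2x2 table, conditional on both margins.

    One-sided "greater" sums P(X >= a) over the hypergeometric support of the
    top-left cell; "two" sums every outcome whose probability does not exceed
    the observed outcome's (minimum-likelihood definition), with relative
    tolerance ``TWO_SIDED_RTOL`` on the probability comparison.

    The reported effect is the sample odds ratio ad/bc; 0.5 is added to every
    cell (Haldane–Anscombe) only when some cell is zero, and only for the
    odds ratio — never for the p-value.
    """
    _check_sidedness(sidedness)
    k, logpmf = _hypergeom_logpmf_support(table)
    pmf = np.exp(logpmf)
    obs = table.a
    p_obs = pmf[np.searchsorted(k, obs)]
    if sidedness == "greater":
        p = float(pmf[k >= obs].sum())
    elif sidedness == "less":
        p = float(pmf[k <= obs].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1.0 + TWO_SIDED_RTOL)].sum())
    p = min(1.0, p)

    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return TestResult(statistic=float(obs), p=p, sidedness=sidedness, effect=odds_ratio)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _rank(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sorted_v = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


#: Largest combined sample size for which the exact rank-sum null
#: distribution is enumerated (tie-free data only).
RANK_SUM_EXACT_MAX_N = 12


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], sidedness: Sidedness = "two"
) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of ``x`` against ``y``.

    Exact p by enumeration of all rank assignments when
    ``len(x)+len(y) <= RANK_SUM_EXACT_MAX_N`` and the data are tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    "greater" tests whether ``x`` tends to exceed ``y``.  The effect is the
    rank-biserial correlation 2U/(n_x n_y) - 1.
    """
    _check_sidedness(sidedness)
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = xa.size, ya.size
    n = nx + ny
    pooled = np.concatenate([xa, ya])
    ranks = _rank(pooled)
    w_obs = float(ranks[:nx].sum())
    u_obs = w_obs - nx * (nx + 1) / 2.0
    effect = 2.0 * u_obs / (nx * ny) - 1.0

    has_ties = np.unique(pooled).size < n
    if n <= RANK_SUM_EXACT_MAX_N and not has_ties:
        # Enumerate the rank-sum null distribution exactly.
        all_ranks = np.arange(1, n + 1)
        sums = np.fromiter(
            (sum(comb) for comb in combinations(all_ranks, nx)),
            dtype=float,
            count=math.comb(n, nx),
        )
        total = sums.size
        p_greater = float(np.count_nonzero(sums >= w_obs)) / total
        p_less = float(np.count_nonzero(sums <= w_obs)) / total
    else:
        mean_u = nx * ny / 2.0
        tie_counts = np.unique(pooled, return_counts=True)[1]
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
        var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            return TestResult(statistic=u_obs, p=1.0, sidedness=sidedness, effect=effect)
        sd = math.sqrt(var_u)
        p_greater = float(special.ndtr(-(u_obs - mean_u - 0.5) / sd))
        p_less = float(special.ndtr((u_obs - mean_u + 0.5) / sd))

    if sidedness == "greater":
        p = p_greater
    elif sidedness == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return TestResult(statistic=u_obs, p=min(1.0, p), sidedness=sidedness, effect=effect)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t-distribution (n-2 df)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(special.stdtr(n - 2, -abs(t)))
    return r, min(1.0, p)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    ``labels`` are binary with 1 = positive class; ties between a positive
    and a negative score count 1/2.  Invariant under strictly increasing
    transforms of the scores.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if s.shape != lab.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and of equal length")
    if not set(np.unique(lab)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    n_pos = int(np.count_nonzero(lab == 1))
    n_neg = int(np.count_nonzero(lab == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = _rank(s)
    u = float(ranks[lab == 1].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
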