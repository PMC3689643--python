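"""Rank-based and survival group-comparison tests, from first principles.

The suite covers the tests conventionally applied to small-animal efficacy
studies: Kruskal–Wallis with Dunn-type pairwise multiple comparisons
(Bonferroni-adjusted, two-tailed), the Peto–Peto modification of the
Gehan–Wilcoxon weighted log-rank test for survival, the Mann–Whitney U test,
and Tukey's HSD. Each rank test switches automatically to an exact
permutation p-value for very small samples (total n <= 10 by default), where
the asymptotic approximations are unreliable.

Statistics are implemented directly (rank sums, hypergeometric log-rank
moments, studentized range) rather than delegated, so that the exact and
asymptotic branches share one statistic definition; library implementations
serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_TOTAL_N = 10  # switch to exact/permutation p below this total sample size


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    method: Literal["asymptotic", "permutation"]
    pairwise: Optional[dict[tuple[int, int], float]] = field(default=None)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn pairwise
# ---------------------------------------------------------------------------


def _kw_h(ranks: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal–Wallis H from pooled midranks."""
    n = ranks.size
    h = 0.0
    start = 0
    for ni in sizes:
        r = ranks[start : start + ni].sum()
        h += r * r / ni
        start += ni
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    if tie == 0.0:
        return 0.0
    return h / tie


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: Literal["auto", "asymptotic", "permutation"] = "auto",
) -> TestResult:
    """Kruskal–Wallis rank test across >= 2 groups.

    Pairwise multiple comparisons use Dunn's z on mean ranks with Bonferroni
    adjustment, two-tailed, reported in ``pairwise`` keyed by group-index
    pairs. An exact permutation p (full enumeration of group assignments) is
    used when the total sample is small.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    if n < 3:
        raise ValueError("need total n >= 3")
    ranks = sps.rankdata(pooled)
    h_obs = _kw_h(ranks, sizes)

    if np.ptp(pooled) == 0:  # all observations identical
        return TestResult("kruskal_wallis", 0.0, 1.0, "asymptotic", _dunn(ranks, sizes))

    use_exact = method == "permutation" or (method == "auto" and n <= EXACT_TOTAL_N)
    if use_exact:
        count = total = 0
        for perm_ranks in _group_assignments(ranks, sizes):
            total += 1
            if _kw_h(perm_ranks, sizes) >= h_obs - 1e-12:
                count += 1
        p = count / total
        meth: Literal["asymptotic", "permutation"] = "permutation"
    else:
        p = float(sps.chi2.sf(h_obs, df=len(groups) - 1))
        meth = "asymptotic"
    return TestResult("kruskal_wallis", float(h_obs), p, meth, _dunn(ranks, sizes))


def _group_assignments(values: np.ndarray, sizes: Sequence[int]):
    """Yield every ordered partition of *values* into groups of the given sizes."""
    idx = tuple(range(values.size))

    def rec(remaining: tuple[int, ...], k: int, acc: list[int]):
        if k == len(sizes):
            yield values[np.array(acc)]
            return
        for comb in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in comb)
            yield from rec(rest, k + 1, acc + list(comb))

    yield from rec(idx, 0, [])


def _dunn(ranks: np.ndarray, sizes: Sequence[int]) -> dict[tuple[int, int], float]:
    """Dunn's z pairwise two-tailed p-values, Bonferroni-adjusted."""
    n = ranks.size
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    means = []
    start = 0
    for ni in sizes:
        means.append(ranks[start : start + ni].mean())
        start += ni
    k = len(sizes)
    m = k * (k - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:
                out[(i, j)] = 1.0
                continue
            z = (means[i] - means[j]) / se
            out[(i, j)] = min(1.0, 2.0 * float(sps.norm.sf(abs(z))) * m)
    return out


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "asymptotic", "exact"] = "auto",
) -> TestResult:
    """Two-tailed Mann–Whitney U test with midrank ties.

    The exact branch enumerates all C(n, n1) label assignments and counts
    those with |U − n1·n2/2| at least as large as observed; the asymptotic
    branch uses the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, n1)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_TOTAL_N)
    if use_exact:
        count = total = 0
        for comb in itertools.combinations(range(n), n1):
            total += 1
            u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return TestResult("mann_whitney_u", u_obs, count / total, "permutation")

    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult("mann_whitney_u", u_obs, 1.0, "asymptotic")
    z = max(0.0, dev - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return TestResult("mann_whitney_u", u_obs, p, "asymptotic")


# ---------------------------------------------------------------------------
# Peto–Peto modified Gehan–Wilcoxon (weighted log-rank)
# ---------------------------------------------------------------------------


def _weighted_logrank_z(
    times: np.ndarray,
    events: np.ndarray,
    group: np.ndarray,
    weights: Literal["peto", "logrank"],
) -> float:
    """Z statistic of the weighted log-rank test (group 0 minus expected).

    Peto–Peto weights use the left-continuous pooled Kaplan–Meier estimate
    evaluated just before each event time; unit weights give the standard
    log-rank. Ties use the hypergeometric variance.
    """
    order = np.argsort(times, kind="stable")
    times, events, group = times[order], events[order], group[order]
    event_times = np.unique(times[events])
    num = 0.0
    var = 0.0
    s_left = 1.0  # pooled KM just before the current event time
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        d_j = int((events & (times == t)).sum())
        n0 = int((at_risk & (group == 0)).sum())
        d0 = int((events & (times == t) & (group == 0)).sum())
        w = s_left if weights == "peto" else 1.0
        num += w * (d0 - d_j * n0 / n_j)
        if n_j > 1:
            var += (
                w * w * d_j * (n_j - d_j) * n0 * (n_j - n0) / (n_j * n_j * (n_j - 1))
            )
        s_left *= 1.0 - d_j / n_j
    if var <= 0:
        return 0.0
    return num / math.sqrt(var)


def gehan_wilcoxon_peto(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
    method: Literal["auto", "asymptotic", "permutation"] = "auto",
    weights: Literal["peto", "logrank"] = "peto",
) -> TestResult:
    """Two-sample Peto–Peto weighted log-rank test, two-tailed.

    The permutation branch permutes group labels over the (time, event)
    pairs, enumerating all assignments when feasible.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both survival groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("need at least one event overall")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    n1, n = ta.size, ta.size + tb.size
    group = np.concatenate([np.zeros(n1, dtype=int), np.ones(n - n1, dtype=int)])
    z_obs = _weighted_logrank_z(times, events, group, weights)

    use_perm = method == "permutation" or (method == "auto" and n <= EXACT_TOTAL_N)
    if use_perm:
        count = total = 0
        for comb in itertools.combinations(range(n), n1):
            total += 1
            g = np.ones(n, dtype=int)
            g[list(comb)] = 0
            z = _weighted_logrank_z(times, events, g, weights)
            if abs(z) >= abs(z_obs) - 1e-12:
                count += 1
        return TestResult("gehan_wilcoxon_peto", float(z_obs), count / total, "permutation")

    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z_obs))))
    return TestResult("gehan_wilcoxon_peto", float(z_obs), p, "asymptotic")


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


def tukey_q(groups: Sequence[Sequence[float]]) -> tuple[dict[tuple[int, int], float], int]:
    """Pairwise Tukey(-Kramer) studentized-range statistics and residual df.

    Computing the q statistics separately from their (comparatively costly)
    studentized-range tail probabilities lets large null simulations compare
    against a single critical value instead.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(groups)
    sizes = [g.size for g in groups]
    df = sum(sizes) - k
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    means = [g.mean() for g in groups]
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    qs: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(mse / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            qs[(i, j)] = abs(means[i] - means[j]) / se if se > 0 else 0.0
    return qs, df


def tukey_hsd(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tukey(-Kramer) honestly-significant-difference pairwise comparisons.

    Returns the largest studentized-range statistic as the headline statistic
    (its p is the familywise smallest pairwise p); per-pair p-values sit in
    ``pairwise``.
    """
    qs, df = tukey_q(groups)
    k = len(groups)
    pairwise = {
        pair: (1.0 if q == 0.0 else float(sps.studentized_range.sf(q, k, df)))
        for pair, q in qs.items()
    }
    q_max = max(qs.values())
    return TestResult("tukey_hsd", q_max, min(pairwise.values()), "asymptotic", pairwise)
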