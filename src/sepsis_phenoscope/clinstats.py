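"""Nonparametric and survival statistics used to profile the phenotypes.

Self-contained implementations (NumPy/SciPy primitives only) of:

* Kruskal-Wallis H with tie correction, chi-square or exact-permutation p;
* Jonckheere-Terpstra trend test with 1/2-counted ties, tie-corrected
  normal approximation, and exact permutation at small n;
* the product-limit (Kaplan-Meier) survival estimator;
* the Mantel log-rank and Gehan-Breslow-Wilcoxon k-sample tests
  (weighted observed-minus-expected chi-square over event times);
* the conservative "higher p" reporting rule: when two tests address the
  same comparison, the larger p value is the one reported.

Exact permutation modes enumerate every distinct assignment of the pooled
observations to groups of the observed sizes; they are enabled
automatically below a small-n threshold per test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "jonckheere_terpstra",
    "higher_p",
    "km_estimate",
    "logrank_mantel",
    "gehan_breslow_wilcoxon",
]

KW_EXACT_MAX_N = 12
JT_EXACT_MAX_N = 10
LOGRANK_EXACT_MAX_N = 8


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    __test__ = False  # not a pytest class despite the name

    method: str
    statistic: float
    p_value: float
    df: int | None = None
    approximation: str = "asymptotic"  # or "exact-permutation"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p value out of range: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)


def _as_groups(groups: list) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(out):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
        if not np.isfinite(g).all():
            raise ValueError(f"group {i} contains non-finite values")
    return out


def _group_assignments(n: int, sizes: list[int]):
    """Yield every distinct split of indices 0..n-1 into ordered groups of
    the given sizes (each split once)."""

    def rec(remaining: tuple[int, ...], sizes: list[int]):
        if len(sizes) == 1:
            yield (remaining,)
            return
        k = sizes[0]
        for head in combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in set(head))
            for tail in rec(rest, sizes[1:]):
                yield (head, *tail)

    yield from rec(tuple(range(n)), sizes)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def _kw_statistic(ranks: np.ndarray, labels: np.ndarray, k: int, tie_denom: float) -> float:
    n = ranks.size
    h = 0.0
    for g in range(k):
        rg = ranks[labels == g]
        h += rg.sum() ** 2 / rg.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_denom if tie_denom > 0 else 0.0


def kruskal_wallis(groups: list, exact: bool | None = None) -> TestResult:
    """Kruskal-Wallis H test across k independent samples.

    Tie-corrected H; p from chi-square with k-1 df, or from the exact
    permutation distribution when total n <= 12 (or ``exact=True``).
    """
    gs = _as_groups(groups)
    k = len(gs)
    sizes = [g.size for g in gs]
    n = sum(sizes)
    pooled = np.concatenate(gs)
    labels = np.repeat(np.arange(k), sizes)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_denom = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie_denom <= 0:  # all observations identical
        return TestResult("kruskal-wallis", 0.0, 1.0, df=k - 1, approximation="degenerate")
    h_obs = _kw_statistic(ranks, labels, k, tie_denom)

    if exact is None:
        exact = n <= KW_EXACT_MAX_N
    if exact:
        count = total = 0
        for assign in _group_assignments(n, sizes):
            lab = np.empty(n, dtype=int)
            for g, idx in enumerate(assign):
                lab[list(idx)] = g
            h = _kw_statistic(ranks, lab, k, tie_denom)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
        return TestResult(
            "kruskal-wallis", h_obs, count / total, df=k - 1,
            approximation="exact-permutation",
        )
    p = float(stats.chi2.sf(h_obs, k - 1))
    return TestResult("kruskal-wallis", h_obs, p, df=k - 1, approximation="chi-square")


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------------


def _jt_statistic(gs: list[np.ndarray]) -> float:
    jt = 0.0
    for a in range(len(gs)):
        xa = np.sort(gs[a])
        for b in range(a + 1, len(gs)):
            xb = gs[b]
            lo = np.searchsorted(xa, xb, side="left")
            hi = np.searchsorted(xa, xb, side="right")
            # count of xa < xb plus half the ties
            jt += lo.sum() + 0.5 * (hi - lo).sum()
    return float(jt)


def _jt_null_moments(sizes: np.ndarray, pooled: np.ndarray) -> tuple[float, float]:
    n = int(sizes.sum())
    mean = (n**2 - (sizes**2).sum()) / 4.0
    _, t = np.unique(pooled, return_counts=True)
    t = t.astype(float)
    ns = sizes.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    ) / (36.0 * n * (n - 1) * (n - 2))
    term3 = ((ns * (ns - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n * (n - 1))
    return float(mean), float(term1 + term2 + term3)


def jonckheere_terpstra(
    groups_in_order: list,
    alternative: str = "two-sided",
    exact: bool | None = None,
) -> TestResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    JT is the sum over ordered group pairs (a < b) of Mann-Whitney counts
    #(x_a < x_b) with ties counted 1/2.  The caller supplies the group
    order; it is part of the hypothesis.  ``alternative`` is one of
    "two-sided", "increasing", "decreasing".
    """
    if alternative not in ("two-sided", "increasing", "decreasing"):
        raise ValueError(f"unknown alternative {alternative!r}")
    gs = _as_groups(groups_in_order)
    sizes = np.array([g.size for g in gs])
    n = int(sizes.sum())
    pooled = np.concatenate(gs)
    jt_obs = _jt_statistic(gs)
    mean, var = _jt_null_moments(sizes, pooled)

    if exact is None:
        exact = n <= JT_EXACT_MAX_N
    if exact:
        vals = []
        for assign in _group_assignments(n, sizes.tolist()):
            vals.append(_jt_statistic([pooled[list(idx)] for idx in assign]))
        vals = np.asarray(vals)
        eps = 1e-12
        if alternative == "increasing":
            p = (vals >= jt_obs - eps).mean()
        elif alternative == "decreasing":
            p = (vals <= jt_obs + eps).mean()
        else:
            p = (np.abs(vals - mean) >= abs(jt_obs - mean) - eps).mean()
        return TestResult(
            "jonckheere-terpstra", jt_obs, float(p),
            approximation="exact-permutation", extras={"null_mean": mean},
        )

    if var <= 0:  # fully tied data: no information about trend
        return TestResult(
            "jonckheere-terpstra", jt_obs, 1.0, approximation="degenerate",
            extras={"null_mean": mean},
        )
    z = (jt_obs - mean) / np.sqrt(var)
    if alternative == "increasing":
        p = float(stats.norm.sf(z))
    elif alternative == "decreasing":
        p = float(stats.norm.cdf(z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(
        "jonckheere-terpstra", jt_obs, min(p, 1.0), approximation="normal",
        extras={"z": float(z), "null_mean": mean},
    )


# ---------------------------------------------------------------------------
# higher-p reporting rule
# ---------------------------------------------------------------------------


def higher_p(a: TestResult, b: TestResult) -> TestResult:
    """Report the more conservative of two tests of the same comparison.

    Returns the argument with the larger p value, annotated with both
    component results; on an exact tie the first argument is returned and
    flagged.
    """
    chosen = a if a.p_value >= b.p_value else b
    return TestResult(
        method=f"higher-p({a.method}, {b.method})",
        statistic=chosen.statistic,
        p_value=chosen.p_value,
        df=chosen.df,
        approximation=chosen.approximation,
        extras={
            "selected": chosen.method,
            "p_values": {a.method: a.p_value, b.method: b.p_value},
            "tie": a.p_value == b.p_value,
        },
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(
    time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Product-limit survival estimate under right censoring.

    Returns (times, survival, at_risk): the distinct event times in
    increasing order, S(t) just after each, and the at-risk count just
    before each.  S(0) = 1 is implicit (an empty prefix product).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no subjects")
    if (time < 0).any() or not np.isfinite(time).all():
        raise ValueError("times must be finite and >= 0")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    out_t, out_s, out_r = [], [], []
    s = 1.0
    n = time.size
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += event[j]
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            out_t.append(t)
            out_s.append(s)
            out_r.append(at_risk)
        i = j
    return np.asarray(out_t), np.asarray(out_s), np.asarray(out_r)


def km_survival_at(
    time: np.ndarray, event: np.ndarray, query: float
) -> float:
    """S(query) from the product-limit estimate (right-continuous step)."""
    t, s, _ = km_estimate(time, event)
    idx = np.searchsorted(t, query, side="right") - 1
    return 1.0 if idx < 0 else float(s[idx])


# ---------------------------------------------------------------------------
# weighted log-rank family
# ---------------------------------------------------------------------------


def _weighted_logrank_statistic(
    time: np.ndarray, event: np.ndarray, labels: np.ndarray, k: int, weight: str
) -> float:
    """Chi-square statistic of the k-sample weighted log-rank test.

    weight = "mantel" (w_t = 1) or "wilcoxon" (w_t = n at risk, the
    Gehan-Breslow generalisation, emphasising early event times).
    """
    order = np.argsort(time, kind="stable")
    time, event, labels = time[order], event[order], labels[order]
    n = time.size
    u = np.zeros(k)
    cov = np.zeros((k, k))
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        at_risk_mask = np.arange(n) >= i
        n_t = n - i
        d_vec = np.bincount(labels[i:j][event[i:j] == 1], minlength=k).astype(float)
        d_t = d_vec.sum()
        if d_t > 0 and n_t > 1:
            n_vec = np.bincount(labels[at_risk_mask], minlength=k).astype(float)
            w = float(n_t) if weight == "wilcoxon" else 1.0
            e_vec = d_t * n_vec / n_t
            u += w * (d_vec - e_vec)
            c = d_t * (n_t - d_t) / (n_t - 1.0)
            outer = np.outer(n_vec, n_vec) / n_t**2
            v = c * (np.diag(n_vec / n_t) - outer)
            cov += w**2 * v
        i = j
    # drop the last group: U sums to 0 and cov is singular by construction
    u_r = u[:-1]
    cov_r = cov[:-1, :-1]
    return float(u_r @ np.linalg.pinv(cov_r) @ u_r)


def _logrank(
    time,
    event,
    group,
    weight: str,
    method_name: str,
    exact: bool | None,
) -> TestResult:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if time.size != event.size or time.size != group.size:
        raise ValueError("time, event and group must have equal lengths")
    uniq = np.unique(group)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if event.sum() == 0:
        raise ValueError("test undefined with zero events")
    k = uniq.size
    labels = np.searchsorted(uniq, group)
    stat_obs = _weighted_logrank_statistic(time, event, labels, k, weight)

    n = time.size
    if exact is None:
        exact = n <= LOGRANK_EXACT_MAX_N
    if exact:
        sizes = np.bincount(labels, minlength=k).tolist()
        count = total = 0
        for assign in _group_assignments(n, sizes):
            lab = np.empty(n, dtype=int)
            for g, idx in enumerate(assign):
                lab[list(idx)] = g
            s = _weighted_logrank_statistic(time, event, lab, k, weight)
            total += 1
            if s >= stat_obs - 1e-12:
                count += 1
        return TestResult(
            method_name, stat_obs, count / total, df=k - 1,
            approximation="exact-permutation",
        )
    p = float(stats.chi2.sf(stat_obs, k - 1))
    return TestResult(method_name, stat_obs, p, df=k - 1, approximation="chi-square")


def logrank_mantel(time, event, group, exact: bool | None = None) -> TestResult:
    """Mantel log-rank k-sample test (unit weights over event times)."""
    return _logrank(time, event, group, "mantel", "logrank-mantel", exact)


def gehan_breslow_wilcoxon(time, event, group, exact: bool | None = None) -> TestResult:
    """Gehan-Breslow-Wilcoxon test (at-risk-count weights: early events
    count more than late ones)."""
    return _logrank(time, event, group, "wilcoxon", "gehan-breslow-wilcoxon", exact)


def survival_comparison(time, event, group) -> TestResult:
    """Mantel log-rank and Gehan-Breslow-Wilcoxon on the same data, with
    the higher p value reported (the conservative convention used for all
    cluster survival comparisons)."""
    return higher_p(
        logrank_mantel(time, event, group),
        gehan_breslow_wilcoxon(time, event, group),
    )
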