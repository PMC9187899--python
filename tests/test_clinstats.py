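"""Nonparametric and survival tests against hand computations, brute-force
permutation oracles, and established library implementations."""

import itertools
import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from sepsis_phenoscope.clinstats import (
    TestResult,
    _weighted_logrank_statistic,
    gehan_breslow_wilcoxon,
    higher_p,
    jonckheere_terpstra,
    km_estimate,
    km_survival_at,
    kruskal_wallis,
    logrank_mantel,
    survival_comparison,
)


def _permutation_oracle(pooled, sizes, statistic, kind="ge", observed=None):
    """Brute-force permutation p value: every distinct ordering of the
    pooled sample split into consecutive groups of the given sizes."""
    pooled = list(pooled)
    n = len(pooled)
    count = total = 0
    seen_stats = []
    for perm in itertools.permutations(range(n)):
        groups = []
        start = 0
        for k in sizes:
            groups.append([pooled[i] for i in perm[start : start + k]])
            start += k
        s = statistic(groups)
        seen_stats.append(s)
        total += 1
    seen_stats = np.asarray(seen_stats)
    if kind == "ge":
        return float((seen_stats >= observed - 1e-12).mean())
    raise ValueError(kind)


class TestKruskalWallis:
    def test_exact_p_for_fully_separated_groups(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.approximation == "exact-permutation"
        assert res.p_value == pytest.approx(0.1)  # 2 of 20 partitions as extreme

    def test_identical_groups_are_null(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_asymptotic(self, rng):
        groups = [rng.normal(size=30), rng.normal(0.5, size=25), rng.normal(1, size=20)]
        ours = kruskal_wallis(groups, exact=False)
        ref = stats.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 4, size=30), rng.integers(0, 4, size=30)]
        ours = kruskal_wallis(groups, exact=False)
        ref = stats.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_two_groups_equal_squared_standardized_wilcoxon(self, rng):
        """For two tie-free groups H equals the squared standardized
        Mann-Whitney statistic."""
        a, b = rng.normal(size=12), rng.normal(0.8, size=15)
        h = kruskal_wallis([a, b], exact=False).statistic
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        na, nb = len(a), len(b)
        z = (u - na * nb / 2) / math.sqrt(na * nb * (na + nb + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_exact_equals_brute_force(self, rng):
        for sizes in ((3, 3), (2, 3, 2)):
            pooled = rng.normal(size=sum(sizes)).round(1)
            groups = np.split(pooled, np.cumsum(sizes)[:-1])
            res = kruskal_wallis([g.tolist() for g in groups], exact=True)

            def stat(gs):
                return kruskal_wallis(gs, exact=False).statistic

            p = _permutation_oracle(pooled, sizes, stat, observed=res.statistic)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestJonckheereTerpstra:
    def test_maximal_trend_statistic_and_exact_p(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], alternative="increasing")
        assert res.statistic == 12.0  # every ordered pair concordant
        # only 1 of the 90 distinct assignments reaches JT = 12
        assert res.p_value == pytest.approx(1 / 90)

    def test_fully_tied_data_is_null(self):
        res = jonckheere_terpstra([[7, 7], [7, 7], [7, 7]], exact=False)
        assert res.statistic == res.extras["null_mean"]
        assert res.p_value == 1.0

    def test_reversal_antisymmetry(self, rng):
        groups = [rng.normal(i * 0.5, size=2).round(2).tolist() for i in range(3)]
        inc = jonckheere_terpstra(groups, alternative="increasing", exact=True)
        dec = jonckheere_terpstra(groups[::-1], alternative="increasing", exact=True)
        # reversing the hypothesized order flips the one-sided exact p up
        # to the probability mass at the observed statistic
        mean = inc.extras["null_mean"]

        def stat(gs):
            return jonckheere_terpstra(gs, exact=False).statistic

        pooled = [v for g in groups for v in g]
        vals = []
        sizes = [len(g) for g in groups]
        for assign in itertools.permutations(range(len(pooled))):
            gs, start = [], 0
            for k in sizes:
                gs.append([pooled[i] for i in assign[start : start + k]])
                start += k
            vals.append(stat(gs))
        vals = np.asarray(vals)
        mass_at = (np.abs(vals - inc.statistic) < 1e-9).mean()
        assert inc.p_value + dec.p_value == pytest.approx(1 + mass_at, abs=1e-9)

    def test_exact_equals_brute_force(self, rng):
        sizes = (3, 2, 3)
        pooled = rng.integers(0, 5, size=sum(sizes)).astype(float)
        groups = np.split(pooled, np.cumsum(sizes)[:-1])
        res = jonckheere_terpstra(
            [g.tolist() for g in groups], alternative="increasing", exact=True
        )

        def stat(gs):
            return jonckheere_terpstra(gs, exact=False).statistic

        p = _permutation_oracle(pooled, sizes, stat, observed=res.statistic)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_monotone_power_in_effect_size(self, rng):
        """Rejection rate under a location trend grows with the effect."""
        power = []
        for delta in (0.0, 0.5, 1.0):
            rej = 0
            for _ in range(200):
                groups = [rng.normal(i * delta, size=15) for i in range(3)]
                p = jonckheere_terpstra(groups, alternative="increasing", exact=False)
                rej += p.p_value < 0.05
            power.append(rej / 200)
        assert power[0] < power[1] < power[2]

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1], [2]], alternative="sideways")


class TestHigherP:
    def test_selects_larger_p(self):
        a = TestResult("kw", 5.0, 0.01)
        b = TestResult("jt", 2.0, 0.04)
        assert higher_p(a, b).p_value == 0.04
        assert higher_p(a, b).extras["selected"] == "jt"

    def test_tie_returns_first_and_flags(self):
        a = TestResult("kw", 5.0, 0.03)
        b = TestResult("jt", 2.0, 0.03)
        res = higher_p(a, b)
        assert res.extras["selected"] == "kw" and res.extras["tie"]

    def test_p_one_dominates(self):
        assert higher_p(TestResult("a", 0, 1.0), TestResult("b", 0, 0.5)).p_value == 1.0


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        # 4 subjects, deaths at day 5 and 10, two survivors censored later
        t, s, r = km_estimate([5, 10, 12, 12], [1, 1, 0, 0])
        np.testing.assert_array_equal(t, [5, 10])
        np.testing.assert_allclose(s, [0.75, 0.5])
        np.testing.assert_array_equal(r, [4, 3])
        assert km_survival_at([5, 10, 12, 12], [1, 1, 0, 0], 4.9) == 1.0

    def test_all_censored_curve_stays_at_one(self):
        t, s, _ = km_estimate([3, 7, 9], [0, 0, 0])
        assert len(t) == 0
        assert km_survival_at([3, 7, 9], [0, 0, 0], 28) == 1.0

    def test_single_death_drops_to_zero(self):
        assert km_survival_at([3], [1], 3) == 0.0

    def test_matches_lifelines_on_censored_data(self, rng):
        time = rng.exponential(10, size=200).round(1)
        event = (rng.random(200) < 0.7).astype(int)
        t, s, _ = km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for ti, si in zip(t, s):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-10
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrankFamily:
    def _random_surv(self, rng, n=60, k=3):
        time = rng.exponential(10, size=n).round(2)
        event = (rng.random(n) < 0.8).astype(int)
        group = rng.integers(0, k, size=n)
        while len(np.unique(group)) < k:
            group = rng.integers(0, k, size=n)
        return time, event, group

    def test_identical_groups_are_null(self):
        time = [1, 2, 3, 1, 2, 3]
        event = [1, 1, 1, 1, 1, 1]
        group = [0, 0, 0, 1, 1, 1]
        res = logrank_mantel(time, event, group, exact=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_observed_minus_expected(self):
        """Two groups of 2, deaths at 1,2 (A) and 3,4 (B), no censoring.

        Event table: t=1 n=4 (2 A), d=1 -> E_A = 1/2; t=2 n=3 (1 A),
        d=1 -> E_A = 1/3; t=3 n=2 (0 A), d=1 -> E_A = 0; t=4 n=1 skipped
        (no variance).  U_A = 2 - 5/6 = 7/6; V_A = 1/4 + 2/9 = 17/36;
        chi2 = U^2 / V = (7/6)^2 / (17/36) = 49/17.
        """
        res = logrank_mantel([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1], exact=False)
        assert res.statistic == pytest.approx(49 / 17, rel=1e-10)

    def test_matches_lifelines_mantel(self, rng):
        time, event, group = self._random_surv(rng)
        ours = logrank_mantel(time, event, group, exact=False)
        ref = multivariate_logrank_test(time, group, event)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_matches_lifelines_wilcoxon_weighting(self, rng):
        time, event, group = self._random_surv(rng)
        ours = gehan_breslow_wilcoxon(time, event, group, exact=False)
        ref = multivariate_logrank_test(time, group, event, weightings="wilcoxon")
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-8)

    def test_gbw_reduces_to_logrank_when_risk_sets_constant(self):
        """With a single event time the GBW weight is a constant factor
        that cancels in the chi-square."""
        time = [5, 5, 9, 9]
        event = [1, 1, 0, 0]
        group = [0, 1, 0, 1]
        a = logrank_mantel(time, event, group, exact=False).statistic
        b = gehan_breslow_wilcoxon(time, event, group, exact=False).statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_exact_equals_brute_force(self, rng):
        time = rng.exponential(10, size=6).round(1)
        event = np.array([1, 1, 0, 1, 1, 0])
        group = np.array([0, 0, 0, 1, 1, 1])
        res = logrank_mantel(time, event, group, exact=True)
        labels = np.searchsorted(np.unique(group), group)

        count = total = 0
        for perm in itertools.permutations(range(6)):
            lab = labels[list(perm)]
            s = _weighted_logrank_statistic(
                time.copy(), event.copy(), lab.copy(), 2, "mantel"
            )
            total += 1
            count += s >= res.statistic - 1e-12
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_zero_events_undefined(self):
        with pytest.raises(ValueError):
            logrank_mantel([1, 2], [0, 0], [0, 1])

    def test_survival_comparison_reports_higher_p(self, rng):
        time, event, group = self._random_surv(rng)
        combined = survival_comparison(time, event, group)
        pm = logrank_mantel(time, event, group, exact=False).p_value
        pw = gehan_breslow_wilcoxon(time, event, group, exact=False).p_value
        assert combined.p_value == max(pm, pw)
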