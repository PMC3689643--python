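"""Statistical tests vs independent oracles (scipy, lifelines, enumeration)."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from precombi.inference import (
    _weighted_logrank_z,
    gehan_wilcoxon_peto,
    kruskal_wallis,
    mann_whitney_u,
    tukey_hsd,
    tukey_q,
)


class TestKruskalWallis:
    def test_identical_rank_distributions_give_zero(self):
        r = kruskal_wallis([(1, 2, 3), (1, 2, 3)])
        assert r.statistic == pytest.approx(0.0)

    def test_three_separated_groups_hand_value(self):
        r = kruskal_wallis([(1, 2, 3), (4, 5, 6), (7, 8, 9)], method="asymptotic")
        assert r.statistic == pytest.approx(7.2)
        assert r.p_value == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        groups = [rng.integers(0, 5, size=n).astype(float) for n in (12, 15, 9)]
        mine = kruskal_wallis(groups, method="asymptotic")
        ref = sps.kruskal(*groups)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_all_identical_observations(self):
        r = kruskal_wallis([(2.0, 2.0), (2.0, 2.0, 2.0)])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_exact_p_equals_enumeration_oracle(self):
        groups = [(1.0, 5.0, 2.0), (4.0, 3.0, 8.0), (9.0, 7.0, 6.0)]
        mine = kruskal_wallis(groups, method="permutation")
        # independent oracle: enumerate assignments via scipy H statistic
        pooled = np.concatenate(groups)
        h_obs = sps.kruskal(*groups).statistic
        count = total = 0
        for c1 in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in c1]
            for c2 in itertools.combinations(rest, 3):
                c3 = [i for i in rest if i not in c2]
                h = sps.kruskal(pooled[list(c1)], pooled[list(c2)], pooled[c3]).statistic
                total += 1
                count += h >= h_obs - 1e-12
        assert mine.p_value == pytest.approx(count / total)

    def test_dunn_pairwise_present_and_bounded(self):
        r = kruskal_wallis([(1, 2, 3, 4), (2, 3, 4, 5), (8, 9, 10, 11)])
        assert set(r.pairwise) == {(0, 1), (0, 2), (1, 2)}
        assert all(0 <= p <= 1 for p in r.pairwise.values())
        assert r.pairwise[(0, 2)] < r.pairwise[(0, 1)]


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_tiny_exact_enumeration(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)

    def test_shift_invariance_of_u(self):
        x, y = [1.0, 4.0, 2.5], [3.0, 5.0, 0.5]
        u0 = mann_whitney_u(x, y).statistic
        u1 = mann_whitney_u([v + 7 for v in x], [v + 7 for v in y]).statistic
        assert u0 == u1

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(0.5, 1, size=25)
        mine = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic")
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_exact_matches_scipy_exact(self):
        x, y = [1.0, 5.0, 3.0], [2.0, 8.0, 9.0, 4.0]
        mine = mann_whitney_u(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue)


class TestGehanWilcoxonPeto:
    def test_identical_groups_statistic_zero(self):
        r = gehan_wilcoxon_peto([1, 2, 3], [1] * 3, [1, 2, 3], [1] * 3)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == 1.0

    def test_label_swap_negates_statistic(self):
        ta, tb = [1.0, 4.0, 2.0, 8.0], [3.0, 9.0, 5.0, 10.0]
        r1 = gehan_wilcoxon_peto(ta, [1] * 4, tb, [1] * 4)
        r2 = gehan_wilcoxon_peto(tb, [1] * 4, ta, [1] * 4)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_permutation_p_equals_enumeration(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, dtype=bool)
        r = gehan_wilcoxon_peto(times[:3], events[:3], times[3:], events[3:])
        assert r.method == "permutation"
        # independent enumeration of all 20 label assignments
        zs = []
        for comb in itertools.combinations(range(6), 3):
            g = np.ones(6, dtype=int)
            g[list(comb)] = 0
            zs.append(_weighted_logrank_z(times, events, g, "peto"))
        z_obs = abs(r.statistic)
        p = np.mean([abs(z) >= z_obs - 1e-12 for z in zs])
        assert r.p_value == pytest.approx(p)

    def test_unit_weights_reproduce_logrank(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(11)
        ta, tb = rng.exponential(10, 15), rng.exponential(16, 15)
        ea, eb = rng.random(15) > 0.25, rng.random(15) > 0.25
        mine = gehan_wilcoxon_peto(ta, ea, tb, eb, method="asymptotic", weights="logrank")
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert mine.statistic**2 == pytest.approx(ref.test_statistic)
        assert mine.p_value == pytest.approx(ref.p_value)

    def test_peto_weights_downweight_late_events(self):
        # one early and one late separation: Peto weighting emphasises the early one
        times = np.array([1.0, 1.5, 2, 9, 10, 11])
        events = np.ones(6, dtype=bool)
        g_early = np.array([0, 0, 1, 0, 1, 1])
        z_peto = _weighted_logrank_z(times, events, g_early, "peto")
        z_lr = _weighted_logrank_z(times, events, g_early, "logrank")
        assert abs(z_peto) != pytest.approx(abs(z_lr))

    def test_requires_events_and_nonempty_groups(self):
        with pytest.raises(ValueError):
            gehan_wilcoxon_peto([], [], [1], [True])
        with pytest.raises(ValueError):
            gehan_wilcoxon_peto([1, 2], [0, 0], [3, 4], [0, 0])


class TestTukey:
    def test_identical_groups_p_one(self):
        r = tukey_hsd([[1, 2, 3], [1, 2, 3]])
        assert all(p == pytest.approx(1.0, abs=1e-12) for p in r.pairwise.values())

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, size=8) for m in (0, 0.3, 1.2)]
        mine = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for (i, j), p in mine.pairwise.items():
            assert p == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_extreme_separation_significant(self):
        r = tukey_hsd([[0, 0, 0.1], [10, 10, 10.1]])
        assert r.p_value < 0.001

    def test_q_closed_form(self):
        g1, g2 = [0.0, 0.0, 0.1], [10.0, 10.0, 10.1]
        qs, df = tukey_q([g1, g2])
        mse = (np.var(g1, ddof=1) + np.var(g2, ddof=1)) / 2
        q_expected = 10.0 / math.sqrt(mse / 3)
        assert qs[(0, 1)] == pytest.approx(q_expected)
        assert df == 4
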