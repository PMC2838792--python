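"""Four-group LRT, symptom profiles, and permutation p-values."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cladelink.io import TraitMatrix
from cladelink.nesting import Clade
from cladelink.reference import lrt_grid_statistic
from cladelink.symptoms import (FourGroupCounts, bh_adjust, four_group_counts,
                                lrt_symptom, permutation_p, symptom_profile)


class TestProfile:
    def _matrix(self, presence_fraction, n=10):
        k = round(presence_fraction * n)
        col = [1.0] * k + [0.0] * (n - k)
        return TraitMatrix(pd.DataFrame({"t": col},
                                        index=[f"F:{i}" for i in range(n)]))

    def test_trait_present_in_all_members_included(self):
        m = self._matrix(1.0)
        clade = Clade("1_0", 1, 0, frozenset(m.individual_ids))
        assert symptom_profile(clade, m) == ["t"]

    def test_exactly_seventy_percent_excluded(self):
        m = self._matrix(0.7)
        clade = Clade("1_0", 1, 0, frozenset(m.individual_ids))
        assert symptom_profile(clade, m) == []
        assert symptom_profile(clade, m, prevalence_threshold=0.69) == ["t"]

    def test_matches_direct_proportion_recount(self):
        rng = np.random.default_rng(12)
        arr = rng.integers(0, 2, size=(30, 8)).astype(float)
        arr[rng.random((30, 8)) < 0.1] = np.nan
        m = TraitMatrix(pd.DataFrame(arr, index=[f"F:{i}" for i in range(30)],
                                     columns=[f"t{j}" for j in range(8)]))
        members = frozenset(list(m.individual_ids)[:17])
        clade = Clade("1_0", 1, 0, members)
        got = set(symptom_profile(clade, m))
        for j, t in enumerate(m.trait_names):
            vals = [m.frame.loc[u, t] for u in members]
            vals = [v for v in vals if not math.isnan(v)]
            frac = sum(v >= 1 for v in vals) / len(vals)
            assert (t in got) == (frac > 0.70)

    def test_ordinal_presence_is_any_severity(self):
        m = TraitMatrix(pd.DataFrame({"t": [3.0, 2.0, 1.0, 1.0, 0.0]},
                                     index=[f"F:{i}" for i in range(5)]))
        clade = Clade("1_0", 1, 0, frozenset(m.individual_ids))
        assert symptom_profile(clade, m) == ["t"]  # 4/5 = 0.8 > 0.7


class TestLRT:
    def test_equal_rates_give_zero(self):
        r = lrt_symptom(FourGroupCounts(0, 0, 5, 20, 2, 5, 3, 15))
        # p2 = 0.25 and pooled p34 = 5/20 = 0.25
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_counts_give_zero(self):
        r = lrt_symptom(FourGroupCounts(0, 0, 0, 10, 0, 10, 0, 10))
        assert r.statistic == 0.0 and r.defined

    def test_spec_style_counts_match_grid_search(self):
        r = lrt_symptom(FourGroupCounts(0, 0, 2, 20, 8, 10, 9, 10))
        g = lrt_grid_statistic(2, 20, 8, 10, 9, 10, resolution=1e-6)
        assert r.statistic == pytest.approx(g, abs=1e-6)
        assert r.statistic == pytest.approx(25.4400503, abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_counts_match_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        ns = rng.integers(1, 40, 3)
        xs = [int(rng.integers(0, n + 1)) for n in ns]
        r = lrt_symptom(FourGroupCounts(0, 0, xs[0], int(ns[0]),
                                        xs[1], int(ns[1]), xs[2], int(ns[2])))
        g = lrt_grid_statistic(xs[0], int(ns[0]), xs[1], int(ns[1]),
                               xs[2], int(ns[2]), resolution=1e-6)
        assert r.statistic == pytest.approx(g, abs=1e-5)

    def test_group_one_cancels(self):
        a = lrt_symptom(FourGroupCounts(0, 0, 4, 12, 6, 9, 7, 11))
        b = lrt_symptom(FourGroupCounts(55, 80, 4, 12, 6, 9, 7, 11))
        assert a.statistic == b.statistic

    def test_containment_boundary_two_vs_four(self):
        # clade inside the diagnostic category: group 3 empty
        r = lrt_symptom(FourGroupCounts(0, 0, 3, 30, 0, 0, 9, 10))
        g = lrt_grid_statistic(3, 30, 0, 0, 9, 10, resolution=1e-6)
        assert r.defined and r.statistic == pytest.approx(g, abs=1e-5)
        assert set(r.p_alt) == {"p2", "p34"}

    def test_disjoint_boundary_two_vs_three(self):
        r = lrt_symptom(FourGroupCounts(0, 0, 3, 30, 9, 10, 0, 0))
        g = lrt_grid_statistic(3, 30, 9, 10, 0, 0, resolution=1e-6)
        assert r.defined and r.statistic == pytest.approx(g, abs=1e-5)

    def test_single_nonempty_group_undefined_not_p1(self):
        r = lrt_symptom(FourGroupCounts(0, 0, 3, 30, 0, 0, 0, 0))
        assert not r.defined
        assert math.isnan(r.statistic)

    def test_counts_validated(self):
        with pytest.raises(Exception):
            FourGroupCounts(0, 0, 5, 3, 0, 0, 0, 0)


class TestFourGroupCounts:
    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(9)
        n = 40
        m = TraitMatrix(pd.DataFrame(
            {"t": rng.integers(0, 2, n).astype(float)},
            index=[f"F:{i}" for i in range(n)]))
        ids = m.individual_ids
        clade = set(rng.choice(ids, 15, replace=False))
        cat = set(rng.choice(ids, 18, replace=False))
        c = four_group_counts("t", m, clade, cat)
        assert c.n1 + c.n2 + c.n3 + c.n4 == n
        assert c.n4 == len(clade & cat)
        assert c.n3 == len(clade - cat)
        assert c.n2 == len(cat - clade)
        assert c.x1 + c.x2 + c.x3 + c.x4 == int(m.frame["t"].sum())


class TestPermutation:
    def _cohort(self, seed=0, effect=False):
        rng = np.random.default_rng(seed)
        n = 120
        ids = [f"F:{i}" for i in range(n)]
        clade = set(ids[:30])
        cat = set(ids[15:60])
        p = np.full(n, 0.3)
        if effect:
            p[:30] = 0.85
        col = (rng.random(n) < p).astype(float)
        m = TraitMatrix(pd.DataFrame({"t": col}, index=ids))
        return m, clade, cat

    def test_zero_statistic_gives_p_near_one(self):
        m = TraitMatrix(pd.DataFrame({"t": [1.0] * 40},
                                     index=[f"F:{i}" for i in range(40)]))
        ids = m.individual_ids
        r = permutation_p("t", m, set(ids[:10]), set(ids[5:20]),
                          n_perm=200, seed=0)
        assert r.statistic == 0.0
        assert r.perm_p == pytest.approx(1.0, abs=0.01)

    def test_same_seed_identical(self):
        m, clade, cat = self._cohort(3)
        a = permutation_p("t", m, clade, cat, n_perm=300, seed=7)
        b = permutation_p("t", m, clade, cat, n_perm=300, seed=7)
        assert a.perm_p == b.perm_p

    def test_strong_effect_detected(self):
        m, clade, cat = self._cohort(5, effect=True)
        r = permutation_p("t", m, clade, cat, n_perm=500, seed=1)
        assert r.perm_p < 0.01

    def test_pvalue_convention_floor(self):
        m, clade, cat = self._cohort(5, effect=True)
        r = permutation_p("t", m, clade, cat, n_perm=100, seed=1)
        assert r.perm_p >= 1 / 101

    def test_agrees_with_chi2_on_large_null(self):
        # asymptotically chi-square(1) under H0: QQ agreement at key quantiles
        # (the statistic is discrete, so a KS test would reject on ties alone)
        rng = np.random.default_rng(4)
        stats_ = []
        for _ in range(1000):
            x2 = rng.binomial(200, 0.4)
            x3 = rng.binomial(100, 0.4)
            x4 = rng.binomial(100, 0.4)
            r = lrt_symptom(FourGroupCounts(0, 0, int(x2), 200, int(x3), 100,
                                            int(x4), 100))
            stats_.append(r.statistic)
        stats_ = np.asarray(stats_)
        assert stats_.mean() == pytest.approx(1.0, abs=0.15)
        qs = [0.5, 0.9, 0.95]
        emp = np.quantile(stats_, qs)
        theo = stats.chi2(1).ppf(qs)
        assert np.allclose(emp, theo, rtol=0.25, atol=0.1)


def test_bh_adjustment_monotone_and_bounded():
    p = [0.001, 0.02, 0.04, 0.9, 0.5]
    adj = bh_adjust(p)
    assert all(0 <= a <= 1 for a in adj)
    order = np.argsort(p)
    assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-12
               for i in range(len(p) - 1))
    assert adj[0] == pytest.approx(0.005)
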