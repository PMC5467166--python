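"""Gene-set enrichment, BH correction and connectivity comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comod import (
    GeneSet,
    bh_adjust,
    connectivity_set_comparison,
    fisher_enrichment,
    resampling_region_enrichment,
)


def hypergeom_tail_enumeration(N, K, n, a):
    """P[X >= a] by explicit enumeration of hypergeometric terms."""
    total = 0.0
    for x in range(a, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisherEnrichment:
    def test_tiny_universe_hand_enumeration(self):
        universe = GeneSet("u", frozenset(["g1", "g2", "g3", "g4"]))
        s = GeneSet("s", frozenset(["g1", "g2"]))
        res = fisher_enrichment(s, s, universe)
        assert res.p == pytest.approx(1 / 6)  # C(2,2)C(2,0)/C(4,2)
        assert res.capture_fraction == 1.0

    def test_overlap_at_expectation_gives_fold_one(self):
        # set 10 of 100, target 50 of 100 -> expected overlap 5
        u = genes("g", 100)
        s = GeneSet("s", frozenset(u[:5] + u[50:55]))  # 5 in target, 5 out
        t = GeneSet("t", frozenset(u[:50]))
        res = fisher_enrichment(s, t, GeneSet("u", frozenset(u)))
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_matches_enumeration_on_random_small_universes(self, rng):
        """One-sided p equals full hypergeometric enumeration, universes <= 50."""
        for _ in range(60):
            N = int(rng.integers(4, 51))
            u = genes("g", N)
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            target = set(rng.choice(u, size=K, replace=False))
            s = set(rng.choice(u, size=n, replace=False))
            res = fisher_enrichment(
                GeneSet("s", frozenset(s)), GeneSet("t", frozenset(target)), GeneSet("u", frozenset(u))
            )
            expected = hypergeom_tail_enumeration(N, K, n, len(s & target))
            assert res.p == pytest.approx(max(expected, np.finfo(float).tiny), rel=1e-10)

    def test_relabelling_invariance(self, rng):
        u = genes("g", 40)
        s = set(rng.choice(u, 12, replace=False))
        t = set(rng.choice(u, 15, replace=False))
        res1 = fisher_enrichment(GeneSet("s", frozenset(s)), GeneSet("t", frozenset(t)), GeneSet("u", frozenset(u)))
        relab = {g: f"x{i}" for i, g in enumerate(u)}
        res2 = fisher_enrichment(
            GeneSet("s", frozenset(relab[g] for g in s)),
            GeneSet("t", frozenset(relab[g] for g in t)),
            GeneSet("u", frozenset(relab.values())),
        )
        assert res1.p == res2.p and res1.fold_enrichment == res2.fold_enrichment

    def test_out_of_universe_genes_dropped_with_warning(self):
        u = GeneSet("u", frozenset(genes("g", 10)))
        s = GeneSet("s", frozenset(["g0", "g1", "not_on_array"]))
        with pytest.warns(UserWarning, match="outside the universe"):
            res = fisher_enrichment(s, GeneSet("t", frozenset(["g0"])), u)
        assert res.a + res.b == 2

    def test_empty_after_intersection_rejected(self):
        u = GeneSet("u", frozenset(genes("g", 5)))
        with pytest.raises(ValueError):
            fisher_enrichment(GeneSet("s", frozenset(["zz"])), GeneSet("t", frozenset(["g0"])), u)


class TestBHAdjust:
    def test_single_and_tied_pvalues(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_matches_brute_force_definition(self, rng):
        """q_i = min over j>=i of p_(j) * m / j, on 100 random vectors."""
        for _ in range(100):
            m = int(rng.integers(1, 25))
            p = rng.uniform(1e-6, 1, m)
            q = bh_adjust(p)
            order = np.argsort(p)
            brute = np.empty(m)
            sorted_p = p[order]
            for i in range(m):
                brute[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
            assert np.allclose(q[order], brute, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


class TestConnectivitySetComparison:
    def test_identical_sets_ratio_one(self, rng):
        k = pd.Series(rng.gamma(2, 1, 30), index=genes("g", 30))
        s = GeneSet("s", frozenset(k.index))
        ratio, _ = connectivity_set_comparison(k, s, s)
        assert ratio == 1.0

    def test_extreme_separation_matches_hypergeometric(self, rng):
        """Set k_in all above background max: the median-dichotomized
        table is maximally skewed and p equals the hypergeometric tail."""
        k = pd.Series(np.r_[np.full(10, 100.0) + rng.random(10), rng.random(30)], index=genes("g", 40))
        s = GeneSet("s", frozenset(genes("g", 10)))
        bg = GeneSet("bg", frozenset(genes("g", 40)))
        ratio, p = connectivity_set_comparison(k, s, bg)
        assert ratio > 1
        # 20 genes above the pooled median, all 10 set genes among them
        expected = hypergeom_tail_enumeration(40, 20, 10, 10)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_null_gives_uniform_p(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            k = pd.Series(rng.gamma(2, 1, 60), index=genes("g", 60))
            s = GeneSet("s", frozenset(rng.choice(k.index, 20, replace=False)))
            bg = GeneSet("bg", frozenset(k.index))
            ratio, p = connectivity_set_comparison(k, s, bg)
            ps.append(p)
        # discrete p-values: check conservative-or-uniform behaviour
        assert 0.2 <= np.mean(np.array(ps) <= 0.5) <= 0.65
        assert np.mean(ps) > 0.4


class TestResamplingRegionEnrichment:
    def test_equal_proportions_not_enriched(self):
        res = resampling_region_enrichment(5, 50, [10] * 100, [100] * 100)
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p >= 0.5

    def test_extreme_case_matches_hypergeometric_tail(self):
        res = resampling_region_enrichment(10, 10, [0], [1000])
        expected = hypergeom_tail_enumeration(1010, 10, 10, 10)
        assert res.p == pytest.approx(expected, rel=1e-9)

    def test_pooling_identity(self):
        """100 random sets with identical proportions pool to that proportion."""
        res = resampling_region_enrichment(30, 100, [30] * 100, [100] * 100)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_hits_exceeding_totals_rejected(self):
        with pytest.raises(ValueError):
            resampling_region_enrichment(11, 10, [1], [10])


class TestWorkedOverlapNumbers:
    def test_open_chromatin_capture_fraction(self):
        """A 340-gene set with 168 genes inside the module reports 49%."""
        u = genes("g", 17000)
        module = GeneSet("module", frozenset(u[:168] + u[400:3264]))  # 3032 genes
        open_chromatin = GeneSet("oc", frozenset(u[:340]))
        res = fisher_enrichment(open_chromatin, module, GeneSet("u", frozenset(u)))
        assert res.a == 168
        assert res.capture_percent == 49

    def test_replication_preservation_percentage(self):
        """152 of 168 initial genes found in the replication module -> 90%."""
        u = genes("g", 17000)
        initial = GeneSet("initial", frozenset(u[:168]))
        replication = GeneSet("rep", frozenset(u[:152] + u[1000:3287]))
        res = fisher_enrichment(initial, replication, GeneSet("u", frozenset(u)))
        assert res.a == 152
        assert res.capture_percent == 90
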