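"""Signature building, concordance, CDF shifts, detrending."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comod import (
    DifferentialSignature,
    GeneSet,
    build_signature,
    cdf_shift,
    consistent_gene_set,
    de_overlap_chi2,
    directional_concordance,
    intensity_detrend,
    signature_variance_scan,
)


def sig_from(genes, log2fc, p, label="sig"):
    return DifferentialSignature.from_arrays(genes, log2fc, p, label)


def two_group_expression(rng, n_genes=50, n_per_group=10, shift_genes=(), shift=1.0):
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    X = pd.DataFrame(
        rng.normal(8, 1, size=(n_genes, 2 * n_per_group)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=cols,
    )
    X.loc[list(shift_genes), [c for c in cols if c.startswith("b")]] += shift
    pheno = pd.DataFrame(
        {"group": [0] * n_per_group + [1] * n_per_group}, index=pd.Index(cols, name="sample_id")
    )
    return X, pheno


class TestBuildSignature:
    def test_planted_shift_recovered(self, rng):
        X, pheno = two_group_expression(rng, shift_genes=["g0"], shift=1.0)
        sig = build_signature(X, pheno, "group")
        se = np.sqrt(2 / 10)  # two-sample SE at sd=1, n=10 per group
        assert abs(sig.table.loc["g0", "log2fc"] - 1.0) <= 3 * se

    def test_identical_groups_uniform_pvalues(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(40):
            X, pheno = two_group_expression(rng, n_genes=25)
            pvals.extend(build_signature(X, pheno, "group").table["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_confounder_adjustment_removes_shift(self, rng):
        """A shift explained entirely by a covariate must vanish."""
        X, pheno = two_group_expression(rng, n_genes=20)
        conf = rng.normal(0, 1, len(pheno))
        pheno["batch"] = conf
        X_conf = X + 2.0 * conf[None, :]
        raw = build_signature(X_conf, pheno, "group")
        adj = build_signature(X_conf, pheno, "group", covariates=("batch",))
        # partial-regression oracle: adjusted fold-changes shrink to noise
        assert np.abs(adj.table["log2fc"]).mean() < np.abs(raw.table["log2fc"]).mean()
        assert np.abs(adj.table["log2fc"]).mean() < 0.5

    def test_single_sample_group_rejected(self, rng):
        X, pheno = two_group_expression(rng)
        pheno_bad = pheno.copy()
        pheno_bad["group"] = [0] + [1] * (len(pheno) - 1)
        with pytest.raises(ValueError):
            build_signature(X, pheno_bad, "group")


class TestDirectionalConcordance:
    def test_identical_and_flipped(self, rng):
        genes = [f"g{i}" for i in range(60)]
        fc = rng.normal(0, 1, 60)
        ref = sig_from(genes, fc, np.full(60, 0.01))
        same = directional_concordance(ref, ref, alpha=1.0)
        assert same.concordant_fraction == 1.0
        flipped = sig_from(genes, -fc, np.full(60, 0.01))
        assert directional_concordance(ref, flipped, alpha=1.0).concordant_fraction == 0.0

    def test_independent_directions_near_half(self, rng):
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        ref = sig_from(genes, rng.normal(0, 1, n), rng.uniform(1e-3, 1, n))
        test = sig_from(genes, rng.normal(0, 1, n), np.full(n, 0.01))
        res = directional_concordance(ref, test, alpha=1.0)
        assert abs(res.concordant_fraction - 0.5) <= 3 * np.sqrt(0.25 / n)
        bg = GeneSet("bg", frozenset(genes))
        in_set = GeneSet("s", frozenset(genes[:400]))
        res_bg = directional_concordance(ref, test, gene_set=in_set, alpha=1.0, background=bg)
        assert 0.8 < res_bg.fold_enrichment < 1.25

    def test_no_shared_genes_rejected(self, rng):
        a = sig_from(["g1"] * 0 + ["a0", "a1"], [1.0, -1.0], [0.01, 0.01])
        b = sig_from(["b0", "b1"], [1.0, -1.0], [0.01, 0.01])
        with pytest.raises(ValueError):
            directional_concordance(a, b)


class TestConsistentGeneSet:
    def test_perfect_kd_mimic_and_oe_reversal(self, rng):
        genes = [f"g{i}" for i in range(30)]
        fc = rng.normal(0, 1, 30)
        ref = sig_from(genes, fc, np.full(30, 0.001))
        kd = sig_from(genes, fc * 0.8, np.full(30, 0.001))
        oe = sig_from(genes, -fc * 1.2, np.full(30, 0.001))
        found, res = consistent_gene_set(ref, kd, oe)
        assert found.gene_ids == frozenset(genes)
        assert res.n_concordant == 30

    def test_same_direction_oe_gives_empty_set(self, rng):
        genes = [f"g{i}" for i in range(20)]
        fc = rng.normal(0, 1, 20)
        ref = sig_from(genes, fc, np.full(20, 0.001))
        kd = sig_from(genes, fc, np.full(20, 0.001))
        with pytest.raises(ValueError):
            # empty qualifying set is allowed; GeneSet requires non-empty
            consistent_gene_set(ref, kd, kd)

    def test_constructed_forty_gene_truth_recovered(self, rng):
        """Exactly the 40 genes built to qualify are returned."""
        n = 200
        genes = [f"g{i}" for i in range(n)]
        fc = rng.normal(0, 1, n)
        fc[np.abs(fc) < 0.1] = 0.5  # no zero directions
        ref = sig_from(genes, fc, np.full(n, 0.001))
        kd_fc, oe_fc = fc.copy(), -fc.copy()
        kd_p = np.full(n, 0.001)
        oe_p = np.full(n, 0.001)
        # spoil all but the first 40: wrong oe direction or non-significant kd
        oe_fc[40:120] = fc[40:120]
        kd_p[120:] = 0.5
        found, _ = consistent_gene_set(ref, sig_from(genes, kd_fc, kd_p), sig_from(genes, oe_fc, oe_p))
        assert found.gene_ids == frozenset(genes[:40])

    def test_invariant_to_magnitude_transform(self, rng):
        n = 60
        genes = [f"g{i}" for i in range(n)]
        fc = rng.normal(0, 1, n)
        p_kd = rng.uniform(1e-4, 1, n)
        p_oe = rng.uniform(1e-4, 1, n)
        p_kd[:10] = p_oe[:10] = 0.01  # guarantee a non-empty qualifying set
        ref = sig_from(genes, fc, np.full(n, 0.01))
        kd = sig_from(genes, fc * rng.uniform(0.5, 2, n), p_kd)
        oe = sig_from(genes, -fc * rng.uniform(0.5, 2, n), p_oe)
        set1, _ = consistent_gene_set(ref, kd, oe)
        kd2 = sig_from(genes, np.sign(kd.table["log2fc"]) * np.exp(np.abs(kd.table["log2fc"])), p_kd)
        oe2 = sig_from(genes, np.sign(oe.table["log2fc"]) * np.exp(np.abs(oe.table["log2fc"])), p_oe)
        set2, _ = consistent_gene_set(ref, kd2, oe2)
        assert set1.gene_ids == set2.gene_ids


class TestCdfShift:
    def test_identical_and_disjoint_samples(self, rng):
        x = rng.normal(size=50)
        assert cdf_shift(x, x)[0] == 0.0
        assert cdf_shift(x, x + 100)[0] == 1.0

    def test_matches_ecdf_oracle(self, rng):
        a, b = rng.normal(0, 1, 37), rng.normal(0.5, 1.3, 61)
        ks, curves = cdf_shift(a, b)
        grid = np.sort(np.concatenate([a, b]))
        diff = max(
            abs((a <= v).mean() - (b <= v).mean()) for v in grid
        )
        assert ks == pytest.approx(diff, abs=1e-12)
        assert curves["set_x"].shape == (37,)

    def test_invariant_under_common_monotone_transform(self, rng):
        a, b = rng.normal(1, 0.3, 40), rng.normal(1.4, 0.5, 50)
        ks1, _ = cdf_shift(a, b)
        ks2, _ = cdf_shift(np.exp(a), np.exp(b))
        assert ks1 == pytest.approx(ks2, abs=1e-12)


class TestDeOverlapChi2:
    def test_hand_computed_table(self):
        """chi2 on [[30,20],[20,130]] computed as sum (O-E)^2/E."""
        u = [f"g{i}" for i in range(200)]
        deA = GeneSet("a", frozenset(u[:50]))
        deB = GeneSet("b", frozenset(u[:30] + u[50:70]))
        chi2, p = de_overlap_chi2(deA, deB, GeneSet("u", frozenset(u)))
        obs = np.array([[30, 20], [20, 130]], dtype=float)
        row, col, N = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / N
        manual = ((obs - exp) ** 2 / exp).sum()
        assert chi2 == pytest.approx(manual, abs=1e-10)

    def test_identical_sizeable_lists_highly_significant(self):
        u = [f"g{i}" for i in range(500)]
        de = GeneSet("a", frozenset(u[:100]))
        _, p = de_overlap_chi2(de, de, GeneSet("u", frozenset(u)))
        assert p < 1e-6

    def test_sparse_table_falls_back_to_fisher(self):
        u = [f"g{i}" for i in range(40)]
        deA = GeneSet("a", frozenset(u[:2]))
        deB = GeneSet("b", frozenset(u[2:4]))
        with pytest.warns(UserWarning, match="Fisher"):
            chi2, p = de_overlap_chi2(deA, deB, GeneSet("u", frozenset(u)))
        assert np.isnan(chi2) and 0 < p <= 1


class TestIntensityDetrend:
    def test_identity_and_linear_distortion(self, rng):
        ref = np.sort(rng.uniform(4, 12, 400))
        assert np.allclose(intensity_detrend(ref, ref), ref, atol=1e-8)
        distorted = ref + 0.5 * ref
        corrected = intensity_detrend(distorted, ref)
        slope = stats.linregress(ref, corrected).slope
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_cubic_distortion_removed(self, rng):
        ref = np.sort(rng.uniform(4, 12, 500))
        distorted = ref + 0.02 * (ref - 8) ** 3 + rng.normal(0, 0.01, 500)
        corrected = intensity_detrend(distorted, ref, spline_df=8)
        resid = corrected - ref
        r2 = stats.linregress(ref, resid).rvalue ** 2
        assert r2 < 0.01

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            intensity_detrend(np.ones(5), np.ones(5), spline_df=8)


class TestSignatureVarianceScan:
    def test_extreme_signature_hits_floor(self, rng):
        V = pd.DataFrame(
            rng.uniform(0, 1, size=(100, 3)),
            index=[f"g{i}" for i in range(100)],
            columns=["study1", "study2", "study3"],
        )
        V.loc[[f"g{i}" for i in range(10)], "study1"] = 10.0  # top variances
        p = signature_variance_scan(V, GeneSet("s", frozenset(f"g{i}" for i in range(10))), n_resample=500, seed=1)
        assert p["study1"] == pytest.approx(1 / 501)

    def test_exchangeable_null_is_uniformish(self, rng):
        V = pd.DataFrame(
            rng.uniform(0, 1, size=(200, 1)), index=[f"g{i}" for i in range(200)], columns=["s"]
        )
        ps = []
        for seed in range(60):
            s = GeneSet("s", frozenset(rng.choice(V.index, 20, replace=False)))
            ps.append(signature_variance_scan(V, s, n_resample=200, seed=seed)["s"])
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_deterministic_under_seed(self, rng):
        V = pd.DataFrame(rng.uniform(0, 1, (50, 2)), index=[f"g{i}" for i in range(50)], columns=["a", "b"])
        s = GeneSet("s", frozenset(f"g{i}" for i in range(8)))
        p1 = signature_variance_scan(V, s, n_resample=200, seed=3)
        p2 = signature_variance_scan(V, s, n_resample=200, seed=3)
        pd.testing.assert_series_equal(p1, p2)
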