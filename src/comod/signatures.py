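"""Differential-expression signatures and cross-dataset concordance.

A signature is a per-gene table of log2 fold-change, p-value and
direction for one contrast (e.g. diabetic vs non-diabetic donors, or a
knockdown vs control).  The operations here quantify how well two
signatures agree: directional concordance of the significant genes
against a reference, Fisher enrichment of that agreement over a
background, identification of genes responding consistently to opposed
perturbations (knockdown mimics the disease, overexpression reverses
it), CDF shifts of fold-change distributions, chi-squared overlap of
differentially expressed gene lists across studies, spline-based
intensity detrending for cross-platform comparison, and a resampling
scan for studies where a gene signature is unusually variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GeneSet

__all__ = [
    "DifferentialSignature",
    "ConcordanceResult",
    "build_signature",
    "directional_concordance",
    "consistent_gene_set",
    "cdf_shift",
    "de_overlap_chi2",
    "intensity_detrend",
    "signature_variance_scan",
]


@dataclass
class DifferentialSignature:
    """Per-gene log2FC / p / direction for one contrast."""

    contrast_label: str
    table: pd.DataFrame  # index gene_id; columns log2fc, p_value, direction

    def __post_init__(self) -> None:
        required = {"log2fc", "p_value", "direction"}
        if not required <= set(self.table.columns):
            missing = required - set(self.table.columns)
            raise ValueError(f"signature table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate gene ids in signature")
        sign = np.sign(self.table["log2fc"]).astype(int)
        if not (sign == self.table["direction"]).all():
            raise ValueError("direction column inconsistent with log2fc sign")
        if ((self.table["p_value"] <= 0) | (self.table["p_value"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p_value"] < alpha]

    @classmethod
    def from_arrays(cls, gene_ids, log2fc, p_value, contrast_label: str) -> "DifferentialSignature":
        log2fc = np.asarray(log2fc, dtype=float)
        tab = pd.DataFrame(
            {"log2fc": log2fc, "p_value": np.asarray(p_value, dtype=float), "direction": np.sign(log2fc).astype(int)},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return cls(contrast_label=contrast_label, table=tab)


@dataclass
class ConcordanceResult:
    """Directional agreement of a test signature with a reference."""

    n_compared: int
    n_concordant: int
    concordant_fraction: float
    fold_enrichment: float
    p: float


def build_signature(
    X: pd.DataFrame,
    pheno: pd.DataFrame,
    group_trait: str,
    gene_set: GeneSet | None = None,
    covariates: tuple[str, ...] = (),
    contrast_label: str | None = None,
) -> DifferentialSignature:
    """Differential signature for a binary group contrast.

    Without covariates the per-gene log2FC is the difference of group
    means on the log2 scale with Welch-test p-values; with covariates
    each gene is fit by ordinary least squares on group + covariates and
    the group coefficient and its p-value are reported.
    """
    if group_trait not in pheno.columns:
        raise ValueError(f"trait {group_trait!r} not in phenotype table")
    groups = pheno.loc[X.columns, group_trait]
    uniq = np.unique(groups.dropna())
    if uniq.size != 2:
        raise ValueError(f"{group_trait!r} is not binary in these samples")
    genes = list(gene_set.gene_ids & set(X.index)) if gene_set is not None else list(X.index)
    if gene_set is not None and not genes:
        raise ValueError("gene set shares no genes with the expression matrix")
    sub = X.loc[sorted(genes)] if gene_set is not None else X
    g1 = groups == uniq[1]
    g0 = groups == uniq[0]
    if g1.sum() < 3 or g0.sum() < 3:
        raise ValueError("each group needs at least 3 samples")
    label = contrast_label or f"{group_trait}:{uniq[1]} vs {uniq[0]}"

    if not covariates:
        a = sub.loc[:, g1.to_numpy()].to_numpy()
        b = sub.loc[:, g0.to_numpy()].to_numpy()
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        return DifferentialSignature.from_arrays(sub.index, log2fc, np.clip(p, np.finfo(float).tiny, 1.0), label)

    import statsmodels.api as sm

    design = pd.DataFrame({"group": (groups == uniq[1]).astype(float)})
    for c in covariates:
        design[c] = pheno.loc[X.columns, c].astype(float).to_numpy()
    Xd = sm.add_constant(design.to_numpy())
    fc = np.empty(sub.shape[0])
    pv = np.empty(sub.shape[0])
    for i, (_, row) in enumerate(sub.iterrows()):
        fit = sm.OLS(row.to_numpy(dtype=float), Xd).fit()
        fc[i] = fit.params[1]
        pv[i] = fit.pvalues[1]
    return DifferentialSignature.from_arrays(sub.index, fc, np.clip(pv, np.finfo(float).tiny, 1.0), label)


def directional_concordance(
    reference: DifferentialSignature,
    test: DifferentialSignature,
    gene_set: GeneSet | None = None,
    alpha: float = 0.05,
    background: GeneSet | None = None,
) -> ConcordanceResult:
    """Fraction of significant test genes changing like the reference.

    Over genes shared by both signatures (restricted to ``gene_set``
    when given) with test p < alpha, counts those whose test direction
    equals the reference direction.  When a ``background`` universe is
    given, a Fisher exact test compares the concordant-DE rate inside
    the set against the background genes, and fold_enrichment is the
    ratio of the two rates; otherwise an exact binomial test against
    0.5 is reported.
    """
    shared = reference.genes.intersection(test.genes)
    if len(shared) == 0:
        raise ValueError("signatures share no genes")
    in_set = shared if gene_set is None else shared.intersection(sorted(gene_set.gene_ids))
    if len(in_set) < 10:
        raise ValueError("fewer than 10 shared genes to compare")

    def concordant_de_mask(genes: pd.Index) -> pd.Series:
        sig = test.table.loc[genes, "p_value"] < alpha
        agree = test.table.loc[genes, "direction"] == reference.table.loc[genes, "direction"]
        return sig & agree

    sig_mask = test.table.loc[in_set, "p_value"] < alpha
    n_compared = int(sig_mask.sum())
    n_concordant = int(concordant_de_mask(in_set).sum())
    frac = n_concordant / n_compared if n_compared else float("nan")

    if background is not None:
        bg = shared.intersection(sorted(background.gene_ids)).difference(in_set)
        if len(bg) == 0:
            raise ValueError("background contains no genes outside the set")
        bg_hits = int(concordant_de_mask(bg).sum())
        table = [[n_concordant, len(in_set) - n_concordant], [bg_hits, len(bg) - bg_hits]]
        _, p = stats.fisher_exact(table, alternative="greater")
        set_rate = n_concordant / len(in_set)
        bg_rate = bg_hits / len(bg)
        fold = set_rate / bg_rate if bg_rate > 0 else float("inf")
    else:
        p = float(stats.binomtest(n_concordant, n_compared, 0.5).pvalue) if n_compared else 1.0
        fold = frac / 0.5 if n_compared else float("nan")
    return ConcordanceResult(
        n_compared=n_compared,
        n_concordant=n_concordant,
        concordant_fraction=float(frac),
        fold_enrichment=float(fold),
        p=float(max(p, np.finfo(float).tiny)),
    )


def consistent_gene_set(
    reference: DifferentialSignature,
    kd: DifferentialSignature,
    oe: DifferentialSignature,
    alpha: float = 0.05,
) -> tuple[GeneSet, ConcordanceResult]:
    """Genes moved like the disease by knockdown and oppositely by
    overexpression.

    A gene qualifies when kd p < alpha, oe p < alpha, the knockdown
    direction matches the reference and the overexpression direction is
    its negation.  The qualifying rate is tested by one-sided Fisher
    exact test against the chance rate: both perturbations significant
    and a 1-in-4 sign pattern, estimated from the observed per-signature
    significance rates.
    """
    shared = reference.genes.intersection(kd.genes).intersection(oe.genes)
    if len(shared) == 0:
        raise ValueError("signatures share no genes")
    r = reference.table.loc[shared]
    k = kd.table.loc[shared]
    o = oe.table.loc[shared]
    qualify = (
        (k["p_value"] < alpha)
        & (o["p_value"] < alpha)
        & (k["direction"] == r["direction"])
        & (o["direction"] == -r["direction"])
        & (r["direction"] != 0)
    )
    n = len(shared)
    n_q = int(qualify.sum())
    rate_kd = float((k["p_value"] < alpha).mean())
    rate_oe = float((o["p_value"] < alpha).mean())
    expected_rate = 0.25 * rate_kd * rate_oe
    n_exp = expected_rate * n
    # one-sided Fisher of observed qualifying count vs expected count
    table = [[n_q, n - n_q], [int(round(n_exp)), n - int(round(n_exp))]]
    _, p = stats.fisher_exact(table, alternative="greater")
    fold = n_q / n_exp if n_exp > 0 else float("inf")
    genes = GeneSet(name=f"consistent@{alpha:g}", gene_ids=frozenset(shared[qualify]))
    result = ConcordanceResult(
        n_compared=n,
        n_concordant=n_q,
        concordant_fraction=n_q / n,
        fold_enrichment=float(fold),
        p=float(max(p, np.finfo(float).tiny)),
    )
    return genes, result


def cdf_shift(
    fold_changes_set: np.ndarray, fold_changes_background: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Two-sample Kolmogorov-Smirnov separation of fold-change CDFs.

    Returns the KS statistic and the two empirical CDF polylines
    (sorted values and cumulative fractions) for plotting.
    """
    a = np.asarray(fold_changes_set, dtype=float)
    b = np.asarray(fold_changes_background, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = stats.ks_2samp(a, b, method="asymp" if max(a.size, b.size) > 1000 else "auto")
    curves = {
        "set_x": np.sort(a),
        "set_y": np.arange(1, a.size + 1) / a.size,
        "background_x": np.sort(b),
        "background_y": np.arange(1, b.size + 1) / b.size,
    }
    return float(ks.statistic), curves


def de_overlap_chi2(deA: GeneSet, deB: GeneSet, universe: GeneSet) -> tuple[float, float]:
    """Chi-squared association of joint DE membership across two studies.

    The 2x2 table classifies universe genes by membership in each DE
    list; no continuity correction by default.  When any expected cell
    is below 1, falls back to Fisher's exact test with a warning and
    returns (nan, fisher_p).
    """
    U = universe.gene_ids
    a_set = deA.gene_ids & U
    b_set = deB.gene_ids & U
    both = len(a_set & b_set)
    only_a = len(a_set) - both
    only_b = len(b_set) - both
    neither = len(U) - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        warnings.warn("expected cell below 1; falling back to Fisher's exact test", stacklevel=2)
        _, p = stats.fisher_exact(table)
        return float("nan"), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(max(p, np.finfo(float).tiny))


def intensity_detrend(
    sample_means: np.ndarray, reference_means: np.ndarray, spline_df: int = 8
) -> np.ndarray:
    """Remove intensity-dependent distortion between two mean profiles.

    Fits a B-spline regression of the sample's per-gene means on the
    reference means and returns residuals + reference, i.e. the sample
    profile with any smooth intensity-dependent trend removed and its
    level aligned to the reference.
    """
    from sklearn.linear_model import LinearRegression
    from sklearn.preprocessing import SplineTransformer

    y = np.asarray(sample_means, dtype=float)
    x = np.asarray(reference_means, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("sample and reference means must be equal-length vectors")
    if spline_df < 3:
        raise ValueError("spline_df must be at least 3")
    if y.size < spline_df + 2:
        raise ValueError("too few genes for the requested spline_df")
    n_knots = max(spline_df - 1, 2)
    basis = SplineTransformer(degree=3, n_knots=n_knots, extrapolation="linear")
    B = basis.fit_transform(x[:, None])
    fit = LinearRegression().fit(B, y)
    residuals = y - fit.predict(B)
    return residuals + x


def signature_variance_scan(
    variance_matrix: pd.DataFrame,
    gene_set: GeneSet,
    n_resample: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Studies where a gene set is more variable than chance.

    ``variance_matrix`` holds per-gene expression variances (rows:
    genes, columns: studies).  Per study, the set's mean variance is
    compared with ``n_resample`` random same-size gene sets; the
    add-one-smoothed exceedance fraction is the p-value.
    """
    if n_resample < 100:
        raise ValueError("n_resample must be at least 100")
    genes = sorted(gene_set.gene_ids & set(variance_matrix.index))
    if len(genes) == 0:
        raise ValueError("gene set shares no genes with the variance matrix")
    if len(genes) > len(variance_matrix):
        raise ValueError("gene set larger than the gene universe")
    rng = np.random.default_rng(seed)
    V = variance_matrix.to_numpy(dtype=float)
    set_idx = variance_matrix.index.get_indexer(genes)
    observed = V[set_idx].mean(axis=0)
    n_genes = V.shape[0]
    exceed = np.zeros(V.shape[1], dtype=int)
    for _ in range(n_resample):
        draw = rng.choice(n_genes, size=len(genes), replace=False)
        exceed += V[draw].mean(axis=0) >= observed
    p = (exceed + 1) / (n_resample + 1)
    return pd.Series(p, index=variance_matrix.columns, name="p_value")
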