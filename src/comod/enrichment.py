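"""Gene-set enrichment and related exact tests.

Implements the 2x2 overlap machinery used throughout the analysis:
hypergeometric (Fisher exact) enrichment of one gene set in another
within a stated universe, Benjamini-Hochberg correction, a
median-dichotomized Fisher comparison of intramodular connectivity
between gene sets, and the pooled-resampling enrichment statistic for
motif-region hit counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "fisher_enrichment",
    "bh_adjust",
    "connectivity_set_comparison",
    "resampling_region_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene identifiers."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    """A 2x2 overlap test.

    Counts: a = in-set & in-target, b = in-set & out-of-target,
    c = out-of-set & in-target, d = out & out; a+b+c+d = universe size.
    capture_fraction = a / (a + b) is the fraction of the set captured
    by the target; fold_enrichment is observed over expected overlap
    with expected = (a+b)(a+c)/N.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    fold_enrichment: float
    capture_fraction: float
    p: float
    q: float
    sided: str

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def capture_percent(self) -> int:
        """Capture fraction rounded to a whole percent, as reported in text."""
        return int(round(100.0 * self.capture_fraction))


def fisher_enrichment(
    set_: GeneSet, target: GeneSet, universe: GeneSet, sided: str = "one"
) -> EnrichmentResult:
    """Exact hypergeometric enrichment of ``set_`` inside ``target``.

    Genes outside the universe are dropped with a warning (array
    annotation mismatches are the norm).  One-sided p is the upper
    hypergeometric tail P[X >= a]; two-sided sums table probabilities
    no larger than the observed one (Fisher's rule).
    """
    if sided not in {"one", "two"}:
        raise ValueError("sided must be 'one' or 'two'")
    U = universe.gene_ids
    s = set_.gene_ids & U
    t = target.gene_ids & U
    dropped = (set_.gene_ids | target.gene_ids) - U
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) outside the universe dropped: "
            f"{', '.join(sorted(dropped)[:5])}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    if not s:
        raise ValueError("gene set empty after intersecting with the universe")
    N = len(U)
    a = len(s & t)
    b = len(s) - a
    c = len(t) - a
    d = N - a - b - c
    if sided == "one":
        p = float(stats.hypergeom.sf(a - 1, N, len(t), len(s)))
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    expected = len(s) * len(t) / N
    fold = a / expected if expected > 0 else float("inf")
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return EnrichmentResult(
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=float(odds),
        fold_enrichment=float(fold),
        capture_fraction=a / len(s),
        p=p,
        q=p,
        sided=sided,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def connectivity_set_comparison(
    k_in,
    set_: GeneSet,
    background: GeneSet,
    method: str = "fisher-median",
) -> tuple[float, float]:
    """Is the gene set better connected than the background genes?

    ``k_in`` is a mapping/Series of intramodular connectivity indexed
    by gene id, covering both sets.  Returns (mean_ratio, p) with
    mean_ratio = mean k_in(set) / mean k_in(background); the hub claim
    "X% higher connectivity" corresponds to mean_ratio = 1 + X/100 when
    the background is the whole module.  The default test dichotomizes
    k_in at the pooled median over set union background and applies a
    one-sided Fisher exact test to (set membership) x (above median);
    ``method='ranksum'`` uses a one-sided Mann-Whitney U test of the
    set against the non-set background genes instead.
    """
    import pandas as pd

    k = pd.Series(k_in, dtype=float)
    set_genes = sorted(set_.gene_ids & set(k.index))
    bg_genes = sorted(background.gene_ids & set(k.index))
    if not set_genes or not bg_genes:
        raise ValueError("set and background must both have connectivity values")
    mean_ratio = k.loc[set_genes].mean() / k.loc[bg_genes].mean()
    universe = sorted(set(set_genes) | set(bg_genes))
    in_set = np.array([g in set_.gene_ids for g in universe])
    vals = k.loc[universe].to_numpy()
    if method == "fisher-median":
        above = vals > np.median(vals)
        table = [
            [int((in_set & above).sum()), int((in_set & ~above).sum())],
            [int((~in_set & above).sum()), int((~in_set & ~above).sum())],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
    elif method == "ranksum":
        if (~in_set).sum() == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(vals[in_set], vals[~in_set], alternative="greater").pvalue)
    else:
        raise ValueError("method must be 'fisher-median' or 'ranksum'")
    return float(mean_ratio), float(max(p, np.finfo(float).tiny))


def resampling_region_enrichment(
    observed_hits: int,
    observed_total: int,
    random_hits,
    random_totals,
) -> EnrichmentResult:
    """Enrichment of motif hits in observed regions vs resampled regions.

    The resampled background sets (e.g. 100 draws of random genomic
    regions) are pooled into a single background proportion, and a
    one-tailed Fisher exact test asks whether the observed hit
    proportion exceeds it.  fold_enrichment is the ratio of the two
    proportions.  The counts themselves come from an external motif
    scanner; only the statistic lives here.
    """
    random_hits = np.asarray(random_hits, dtype=int)
    random_totals = np.asarray(random_totals, dtype=int)
    if random_hits.size == 0 or random_hits.shape != random_totals.shape:
        raise ValueError("random_hits and random_totals must be equal-length, non-empty")
    if observed_total <= 0 or np.any(random_totals <= 0):
        raise ValueError("totals must be positive")
    if observed_hits > observed_total or np.any(random_hits > random_totals):
        raise ValueError("hits cannot exceed totals")
    pooled_hits = int(random_hits.sum())
    pooled_total = int(random_totals.sum())
    table = [
        [int(observed_hits), int(observed_total - observed_hits)],
        [pooled_hits, pooled_total - pooled_hits],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    obs_prop = observed_hits / observed_total
    pooled_prop = pooled_hits / pooled_total
    fold = obs_prop / pooled_prop if pooled_prop > 0 else float("inf")
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return EnrichmentResult(
        a=int(observed_hits),
        b=int(observed_total - observed_hits),
        c=pooled_hits,
        d=pooled_total - pooled_hits,
        odds_ratio=float(odds),
        fold_enrichment=float(fold),
        capture_fraction=obs_prop,
        p=p,
        q=p,
        sided="one",
    )
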