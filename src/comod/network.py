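"""Weighted co-expression network construction.

The network is built from a genes x samples matrix of log2 expression
values in four steps: (1) a similarity matrix of absolute Pearson
correlations, (2) a soft-thresholded adjacency obtained by raising the
similarity to an integer power beta, (3) selection of beta by the
scale-free topology criterion (log-log linearity of the degree
distribution), and (4) the topological overlap matrix (TOM), whose
complement is the clustering dissimilarity.

All matrices are dense numpy arrays ordered like the input gene list;
the contract is desk-scale (default cap 20,000 genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GENE_CAP = 20_000
DEFAULT_BETA_GRID = tuple(range(1, 13))
DEFAULT_R2_THRESHOLD = 0.8
DEFAULT_N_BINS = 10

__all__ = [
    "CoexpressionNetwork",
    "ScaleFreeFit",
    "BetaChoice",
    "compute_similarity",
    "soft_adjacency",
    "connectivity",
    "scale_free_fit",
    "pick_beta",
    "compute_tom",
    "tom_dissimilarity",
    "build_network",
]


@dataclass
class ScaleFreeFit:
    """Goodness of the power-law fit to the connectivity distribution."""

    r_squared: float
    slope: float
    n_bins_used: int


@dataclass
class BetaChoice:
    """Soft power chosen by the scale-free criterion.

    ``flagged`` is True when no beta on the grid reached the R^2
    threshold, in which case ``beta`` is the grid value with maximal R^2.
    """

    beta: int
    r_squared: float
    flagged: bool
    scan: pd.DataFrame  # columns: beta, r_squared, slope


@dataclass
class CoexpressionNetwork:
    """Similarity, adjacency, TOM and dissimilarity for one cohort."""

    gene_ids: list[str]
    S: np.ndarray
    A: np.ndarray
    beta: int
    TOM: np.ndarray
    D: np.ndarray
    k: np.ndarray
    beta_choice: BetaChoice | None = field(default=None, repr=False)


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(g) for g in X.index]
    X = np.asarray(X, dtype=float)
    return X, [f"g{i}" for i in range(X.shape[0])]


def compute_similarity(X: pd.DataFrame | np.ndarray, gene_cap: int = DEFAULT_GENE_CAP) -> np.ndarray:
    """Absolute Pearson correlation of every gene pair.

    Parameters
    ----------
    X : genes x samples matrix of log2 expression (DataFrame indexed by
        gene id, or plain array).

    Returns
    -------
    Symmetric matrix ``S`` with ``S[i, j] = |cor(x_i, x_j)|`` and unit
    diagonal.
    """
    values, gene_ids = _as_matrix(X)
    if values.ndim != 2:
        raise ValueError("expression must be a 2-D genes x samples matrix")
    n_genes, n_samples = values.shape
    if n_genes > gene_cap:
        raise ValueError(
            f"{n_genes} genes exceeds the dense-matrix cap of {gene_cap}; "
            "raise gene_cap explicitly if this is intended"
        )
    if n_samples < 3:
        raise ValueError("at least 3 samples are required to correlate genes")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [gene_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance gene(s): {', '.join(bad[:10])}")
    S = np.abs(np.corrcoef(values))
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def _check_square_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return M


def soft_adjacency(S: np.ndarray, beta: int) -> np.ndarray:
    """Raise the similarity elementwise to the soft power ``beta``.

    The diagonal is set to 1; connectivity computations exclude it.
    """
    if int(beta) != beta or beta < 1:
        raise ValueError(f"beta must be a positive integer, got {beta!r}")
    S = _check_square_symmetric(S, "similarity")
    if S.min() < 0 or S.max() > 1 + 1e-12:
        raise ValueError("similarity values must lie in [0, 1]")
    A = np.power(S, int(beta))
    np.fill_diagonal(A, 1.0)
    return A


def connectivity(A: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum of off-diagonal adjacencies."""
    A = _check_square_symmetric(A, "adjacency")
    return A.sum(axis=1) - np.diag(A)


def scale_free_fit(k: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> ScaleFreeFit:
    """Fit of the degree distribution to a power law p(k) ~ k^-gamma.

    Connectivities are binned into ``n_bins`` equal-width bins; per
    non-empty bin the mean connectivity and the empirical frequency are
    computed, and log10 frequency is regressed on log10 mean
    connectivity.  Returns the R^2 of that regression and its slope
    (an estimate of -gamma).
    """
    k = np.asarray(k, dtype=float)
    if k.ndim != 1 or k.size < 3:
        raise ValueError("k must be a vector of at least 3 connectivities")
    if np.any(k < 0):
        raise ValueError("connectivities must be non-negative")
    if np.ptp(k) == 0:
        raise ValueError("all connectivities identical: degree distribution degenerate")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.empty(n_bins)
    freq = np.empty(n_bins)
    for b in range(n_bins):
        members = k[idx == b]
        if members.size:
            mean_k[b] = members.mean()
            freq[b] = members.size / k.size
        else:
            mean_k[b] = np.nan
            freq[b] = np.nan
    keep = np.isfinite(mean_k) & (mean_k > 0) & (freq > 0)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable bins; degree distribution too concentrated")
    x = np.log10(mean_k[keep])
    y = np.log10(freq[keep])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in binned connectivity")
    res = stats.linregress(x, y)
    return ScaleFreeFit(r_squared=float(res.rvalue**2), slope=float(res.slope), n_bins_used=int(keep.sum()))


def pick_beta(
    S: np.ndarray,
    beta_grid: tuple[int, ...] = DEFAULT_BETA_GRID,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
) -> BetaChoice:
    """Choose the smallest soft power meeting the scale-free criterion.

    Scans ``beta_grid`` in ascending order and returns the first beta
    whose scale-free fit R^2 reaches ``r2_threshold``.  When none
    qualifies the beta with maximal R^2 is returned and the choice is
    flagged.
    """
    if len(beta_grid) == 0:
        raise ValueError("beta_grid must not be empty")
    if list(beta_grid) != sorted(beta_grid):
        raise ValueError("beta_grid must be ascending")
    rows = []
    for beta in beta_grid:
        A = soft_adjacency(S, beta)
        k = connectivity(A)
        try:
            fit = scale_free_fit(k, n_bins=n_bins)
            rows.append((int(beta), fit.r_squared, fit.slope))
        except ValueError:
            rows.append((int(beta), np.nan, np.nan))
    scan = pd.DataFrame(rows, columns=["beta", "r_squared", "slope"])
    ok = scan[scan["r_squared"] >= r2_threshold]
    if len(ok):
        row = ok.iloc[0]
        return BetaChoice(beta=int(row["beta"]), r_squared=float(row["r_squared"]), flagged=False, scan=scan)
    if scan["r_squared"].isna().all():
        raise ValueError("scale-free fit failed for every beta on the grid")
    row = scan.loc[scan["r_squared"].idxmax()]
    return BetaChoice(beta=int(row["beta"]), r_squared=float(row["r_squared"]), flagged=True, scan=scan)


def compute_tom(A: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    l_ij = sum_{u != i,j} a_iu * a_uj and k excludes the diagonal;
    omega_ii = 1.  High overlap means the two genes share network
    neighbours, not merely a strong direct edge.
    """
    A = _check_square_symmetric(A, "adjacency")
    if A.min() < 0 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(A), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = A.sum(axis=1) - 1.0
    # (A @ A)_ij counts u over all indices incl. i and j; with unit
    # diagonal the i and j terms each contribute a_ij.
    L = A @ A - 2.0 * A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        TOM = (L + A) / denom
    TOM[~np.isfinite(TOM)] = 0.0
    np.fill_diagonal(TOM, 1.0)
    TOM = np.clip((TOM + TOM.T) / 2.0, 0.0, 1.0)
    return TOM


def tom_dissimilarity(TOM: np.ndarray) -> np.ndarray:
    """Clustering distance d_ij = 1 - omega_ij (zero diagonal)."""
    TOM = _check_square_symmetric(TOM, "TOM")
    if TOM.min() < -1e-12 or TOM.max() > 1 + 1e-12:
        raise ValueError("TOM values must lie in [0, 1]")
    D = 1.0 - TOM
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)


def build_network(
    X: pd.DataFrame,
    beta: int | None = None,
    beta_grid: tuple[int, ...] = DEFAULT_BETA_GRID,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    gene_cap: int = DEFAULT_GENE_CAP,
) -> CoexpressionNetwork:
    """Full chain similarity -> soft power -> adjacency -> TOM -> dissimilarity.

    ``beta`` overrides the scale-free selection when given.
    """
    S = compute_similarity(X, gene_cap=gene_cap)
    choice = None
    if beta is None:
        choice = pick_beta(S, beta_grid=beta_grid, r2_threshold=r2_threshold)
        beta = choice.beta
    A = soft_adjacency(S, beta)
    TOM = compute_tom(A)
    D = tom_dissimilarity(TOM)
    gene_ids = [str(g) for g in X.index] if isinstance(X, pd.DataFrame) else [f"g{i}" for i in range(S.shape[0])]
    return CoexpressionNetwork(
        gene_ids=gene_ids, S=S, A=A, beta=int(beta), TOM=TOM, D=D, k=connectivity(A), beta_choice=choice
    )
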