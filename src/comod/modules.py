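"""Module detection and module summaries.

Modules are contiguous branches of an average-linkage hierarchical
clustering of the TOM dissimilarity, obtained with a static height cut.
Each module is summarised by its eigengene — the first principal
component of the standardized member expression — and each gene by its
intramodular connectivity k_in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_CUT_HEIGHT = None  # adaptive plateau cut; pass a float for a static cut
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_MIN_SIGNAL = 2.0  # modules must beat this multiple of the Marchenko-Pastur edge

__all__ = [
    "ModulePartition",
    "Eigengene",
    "detect_modules",
    "module_eigengene",
    "all_eigengenes",
    "intramodular_connectivity",
]


@dataclass
class ModulePartition:
    """Gene -> module labels; label 0 marks unassigned/background genes.

    Nonzero labels are numbered 1..n_modules by decreasing module size.
    """

    labels: pd.Series  # index: gene id, values: int
    n_modules: int
    min_module_size: int
    cut_height: float | None = None

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        counts.name = "size"
        return counts


@dataclass
class Eigengene:
    """First principal component of a module's standardized expression.

    ``values`` has zero mean and unit Euclidean norm across samples and
    is sign-aligned to correlate positively with the mean standardized
    member profile.  ``sign_flipped`` records whether the raw SVD vector
    was negated to satisfy that convention.
    """

    module_id: int
    values: pd.Series  # index: sample id
    variance_explained: float
    sign_flipped: bool


def _adaptive_cut(Z: np.ndarray, min_module_size: int) -> np.ndarray:
    """Scale-free dendrogram cut: midpoint of the best-cut plateau.

    The TOM dissimilarity scale shifts with the soft power, so an
    absolute cut height does not transfer between networks.  Instead
    every candidate height (midpoints between consecutive distinct
    merge heights) is scored by the number of clusters of at least
    ``min_module_size`` it produces, and the middle of the plateau of
    heights achieving the maximum is used: low enough that modules have
    not merged with each other, high enough that they are completely
    assembled.
    """
    heights = np.unique(Z[:, 2])
    if heights.size < 2:
        return fcluster(Z, t=heights[0], criterion="distance")
    candidates = (heights[:-1] + heights[1:]) / 2.0
    scored: list[tuple[int, np.ndarray]] = []
    for t in candidates:
        raw = fcluster(Z, t=t, criterion="distance")
        n_big = int((np.bincount(raw) >= min_module_size).sum())
        scored.append((n_big, raw))
    best = max(s[0] for s in scored)
    plateau = [raw for n_big, raw in scored if n_big == best]
    return plateau[len(plateau) // 2]


def _signal_strength(values: np.ndarray) -> float:
    """First-PC variance explained of a standardized genes x samples block."""
    M = values - values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    M = np.divide(M, sd, out=M, where=sd > 0)
    s = np.linalg.svd(M, compute_uv=False)
    total = float(np.sum(s**2))
    return float(s[0] ** 2 / total) if total > 0 else 0.0


def detect_modules(
    D: np.ndarray,
    gene_ids: list[str] | None = None,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float | None = DEFAULT_CUT_HEIGHT,
    expression: pd.DataFrame | None = None,
    min_signal: float = DEFAULT_MIN_SIGNAL,
) -> ModulePartition:
    """Average-linkage clustering of the dissimilarity into modules.

    With an explicit ``cut_height`` the dendrogram is cut at that fixed
    height; by default the cut is chosen adaptively (see
    :func:`_adaptive_cut`), which is invariant to the overall scale of
    the dissimilarity.  Clusters smaller than ``min_module_size`` are
    relabelled 0 (background); the rest are renumbered by decreasing
    size.

    When ``expression`` is given (genes x samples, indexed like the
    dissimilarity), candidate modules must additionally show coherent
    expression: the variance explained by their first principal
    component has to exceed ``min_signal`` times the Marchenko-Pastur
    null edge (1 + sqrt(n_genes/n_samples))^2 / n_genes.  This prunes
    the chance clusters an adaptive cut would otherwise promote on
    structureless data.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("dissimilarity must be square")
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]

    Z = linkage(squareform(D, checks=False), method="average")
    if cut_height is None:
        raw = _adaptive_cut(Z, min_module_size)
    else:
        if not 0 < cut_height < 1:
            raise ValueError("cut_height must lie in (0, 1)")
        raw = fcluster(Z, t=cut_height, criterion="distance")

    counts = pd.Series(raw).value_counts()
    kept = counts[counts >= min_module_size]
    if expression is not None and len(kept):
        n_samples = expression.shape[1]
        coherent = []
        for c in kept.index:
            members = np.flatnonzero(raw == c)
            ve = _signal_strength(expression.iloc[members].to_numpy(dtype=float))
            mp_edge = (1.0 + np.sqrt(members.size / n_samples)) ** 2 / members.size
            if ve >= min_signal * mp_edge:
                coherent.append(c)
        kept = kept[coherent]
    # big first; ties broken by the original cluster id for determinism
    order = sorted(kept.index, key=lambda c: (-kept[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap.get(c, 0) for c in raw], index=pd.Index(gene_ids, name="gene_id"), name="module")
    return ModulePartition(
        labels=labels, n_modules=len(order), min_module_size=min_module_size, cut_height=cut_height
    )


def _standardize_rows(values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant expression for gene(s): {', '.join(gene_ids[i] for i in flat[:10])}")
    return (values - mean) / sd


def module_eigengene(X: pd.DataFrame, partition: ModulePartition, module_id: int) -> Eigengene:
    """Eigengene of one module: first right singular vector of the
    standardized members x samples matrix.

    variance_explained is the first squared singular value over the
    total.  When the mean standardized member profile is (numerically)
    zero — e.g. a module of exactly cancelling profiles — the sign is
    aligned to the first member gene instead.
    """
    members = partition.members(module_id)
    if len(members) < 2:
        raise ValueError(f"module {module_id} is absent or has fewer than 2 genes")
    sub = X.loc[members]
    M = _standardize_rows(sub.to_numpy(dtype=float), members)
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    eig = Vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))

    reference = M.mean(axis=0)
    if np.linalg.norm(reference) < 1e-10 * np.sqrt(M.shape[1]):
        reference = M[0]
    flipped = False
    if float(reference @ eig) < 0:
        eig = -eig
        flipped = True
    return Eigengene(
        module_id=int(module_id),
        values=pd.Series(eig, index=X.columns, name=f"ME{module_id}"),
        variance_explained=var_explained,
        sign_flipped=flipped,
    )


def all_eigengenes(X: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """Samples x modules table of eigengene values (columns ME1..MEn)."""
    cols = {}
    for m in range(1, partition.n_modules + 1):
        cols[f"ME{m}"] = module_eigengene(X, partition, m).values
    return pd.DataFrame(cols)


def intramodular_connectivity(
    A: np.ndarray, partition: ModulePartition, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene connectivity restricted to the gene's own module.

    For gene i in module m, k_in(i) = sum over other module-m genes of
    a_ij.  Background genes (label 0) get k_in relative to other
    background genes, marked by the ``background`` flag.
    """
    A = np.asarray(A, dtype=float)
    labels = partition.labels
    if gene_ids is None:
        gene_ids = list(labels.index)
    if A.shape[0] != len(labels):
        raise ValueError("adjacency and partition cover different gene counts")
    lab = labels.to_numpy()
    k_in = np.zeros(len(lab))
    for m in np.unique(lab):
        mask = lab == m
        sub = A[np.ix_(mask, mask)]
        k_in[mask] = sub.sum(axis=1) - np.diag(sub)
    return pd.DataFrame(
        {"module": lab, "k_in": k_in, "background": lab == 0},
        index=pd.Index(gene_ids, name="gene_id"),
    )
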