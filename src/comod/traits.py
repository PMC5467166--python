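"""Eigengene- and gene-level trait association.

Continuous traits (HbA1c, insulin secretion) are analysed by linear
regression and binary disease status by logistic regression, optionally
adjusted for age, sex and BMI.  Secretion measures are log-transformed
before fitting because raw insulin release is strongly right-skewed.
The module also provides the hub analysis: per-gene expression-trait
correlations and their correlation with intramodular connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: traits fitted on the log scale; raw values must be strictly positive
LOG_TRANSFORMED_TRAITS = ("secretion_glucose", "secretion_K")

__all__ = [
    "TraitAssociation",
    "LOG_TRANSFORMED_TRAITS",
    "associate_eigengene_trait",
    "gene_trait_correlations",
    "connectivity_trait_correlation",
]


@dataclass
class TraitAssociation:
    """One predictor-trait regression result."""

    predictor_id: str
    trait_name: str
    model: str  # "linear" | "logistic"
    beta: float
    p_value: float
    covariates: tuple[str, ...]
    n: int
    converged: bool = True
    one_sided: bool = False


def _is_binary(values: np.ndarray) -> bool:
    uniq = np.unique(values[~np.isnan(values)])
    return uniq.size == 2 and set(uniq) <= {0.0, 1.0}


def associate_eigengene_trait(
    eigengene: pd.Series,
    pheno: pd.DataFrame,
    trait: str,
    covariates: tuple[str, ...] = (),
    sample_filter: Callable[[pd.DataFrame], pd.Series] | None = None,
    one_sided: bool = False,
    hypothesized_sign: int = 0,
    predictor_id: str = "eigengene",
) -> TraitAssociation:
    """Regression of a trait on an eigengene, adjusted for covariates.

    The eigengene is standardized to zero mean and unit SD over the
    analysed samples so the reported beta is per-SD of module
    expression.  Binary traits use logistic regression (trait as the
    outcome); continuous traits use linear regression.  Secretion
    traits are log-transformed first.  ``sample_filter`` receives the
    phenotype table and returns a boolean mask (e.g. non-diabetic
    donors with BMI above the median of the analysed subset).

    With ``one_sided`` the Wald p is halved when the estimated beta
    matches ``hypothesized_sign`` (or whatever sign was observed when
    the hypothesized sign is 0) and reported as 1 - p/2 otherwise.
    """
    common = eigengene.index.intersection(pheno.index)
    sub = pheno.loc[common]
    mask = pd.Series(True, index=common) if sample_filter is None else sample_filter(sub).astype(bool)
    sub = sub[mask]
    if trait not in sub.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    y = sub[trait].astype(float)
    keep = y.notna()
    for c in covariates:
        keep &= sub[c].notna()
    sub = sub[keep]
    y = y[keep]
    if len(sub) < 10:
        raise ValueError(f"only {len(sub)} samples after filtering; need at least 10")
    if y.nunique() < 2:
        raise ValueError(f"trait {trait!r} is constant in the analysed samples")

    x = eigengene.loc[sub.index].to_numpy(dtype=float)
    x = (x - x.mean()) / x.std()
    design = pd.DataFrame({"eigengene": x}, index=sub.index)
    for c in covariates:
        design[c] = sub[c].astype(float)
    X = sm.add_constant(design)

    binary = _is_binary(y.to_numpy())
    converged = True
    if binary:
        model_name = "logistic"
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            beta = float(fit.params["eigengene"])
            p = float(fit.pvalues["eigengene"])
            if not np.isfinite(p) or abs(beta) > 50:
                converged = False
        except Exception:
            converged = False
        if not converged:
            return TraitAssociation(
                predictor_id=predictor_id,
                trait_name=trait,
                model=model_name,
                beta=float("nan"),
                p_value=float("nan"),
                covariates=tuple(covariates),
                n=len(sub),
                converged=False,
                one_sided=one_sided,
            )
    else:
        model_name = "linear"
        if trait in LOG_TRANSFORMED_TRAITS:
            if (y <= 0).any():
                raise ValueError(f"trait {trait!r} has non-positive values; cannot log-transform")
            y = np.log(y)
        fit = sm.OLS(y, X).fit()
        beta = float(fit.params["eigengene"])
        p = float(fit.pvalues["eigengene"])

    if one_sided:
        sign = hypothesized_sign if hypothesized_sign != 0 else int(np.sign(beta) or 1)
        p = p / 2.0 if np.sign(beta) == sign else 1.0 - p / 2.0
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return TraitAssociation(
        predictor_id=predictor_id,
        trait_name=trait,
        model=model_name,
        beta=beta,
        p_value=p,
        covariates=tuple(covariates),
        n=len(sub),
        converged=converged,
        one_sided=one_sided,
    )


def gene_trait_correlations(X: pd.DataFrame, pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Pearson correlation of every gene's expression with a trait.

    Binary traits are coded 0/1, making this the point-biserial
    correlation.
    """
    if trait not in pheno.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    t = pheno.loc[X.columns, trait].astype(float).to_numpy()
    if np.std(t) == 0:
        raise ValueError(f"trait {trait!r} has zero variance")
    V = X.to_numpy(dtype=float)
    sd = V.std(axis=1)
    if np.any(sd == 0):
        bad = X.index[np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance gene(s): {', '.join(map(str, bad[:10]))}")
    Vc = V - V.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    r = (Vc @ tc) / (np.linalg.norm(Vc, axis=1) * np.linalg.norm(tc))
    return pd.Series(np.clip(r, -1.0, 1.0), index=X.index, name=f"r_{trait}")


def connectivity_trait_correlation(
    k_in: np.ndarray,
    gene_trait_r: np.ndarray,
    method: str = "spearman",
) -> tuple[float, float]:
    """Do hub genes carry the trait signal?

    Correlates intramodular connectivity with the absolute gene-trait
    correlation across module genes, by Spearman rank (default) or
    Pearson correlation; returns (r, p).
    """
    k = np.asarray(k_in, dtype=float)
    r_abs = np.abs(np.asarray(gene_trait_r, dtype=float))
    if k.shape != r_abs.shape:
        raise ValueError("k_in and gene_trait_r must have equal length")
    if method == "spearman":
        res = stats.spearmanr(k, r_abs)
    elif method == "pearson":
        res = stats.pearsonr(k, r_abs)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(res.statistic), float(res.pvalue)
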