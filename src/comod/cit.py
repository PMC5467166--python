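"""Causal inference test (CIT) for dose -> mediator -> outcome trios.

Given a categorical intervention dose L, a candidate mediator G (gene
expression) and an outcome T (e.g. insulin secretion), the test asks
whether the data support the causal chain L -> G -> T rather than a
reactive (L -> T -> G) or independent relationship.  Four component
conditions are assessed:

1. L and T are associated;
2. L and G are associated given T;
3. G and T are associated given L;
4. L and T are conditionally independent given G.

Conditions 1-3 are standard nested-model F-tests.  Condition 4 is an
equivalence-type test: its null hypothesis is that a direct L->T effect
remains after conditioning on G, and SMALL p-values are evidence FOR
conditional independence.  The null distribution is generated by
permutation: the mediator is replaced by G* = fitted(G|L) + permuted
residuals, which preserves the L-G association while destroying G's
ability to absorb the L->T path, and the observed conditional F
statistic for L in T ~ L + G is compared against the F statistics
obtained with each G*.  The omnibus p-value is the maximum of the four
components (intersection-union test); the reactive omnibus is the same
construction with the roles of G and T exchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["CITResult", "cit_test", "cit_component_regressions"]


@dataclass
class CITResult:
    """Component and omnibus p-values of one causal inference test."""

    p1: float  # L associated with T
    p2: float  # L associated with G given T
    p3: float  # G associated with T given L
    p4: float  # equivalence test: L independent of T given G
    omnibus_causal: float
    omnibus_reactive: float
    verdict: str  # causal | reactive | independent | undecided
    n: int
    n_perm: int
    seed: int


def _dummies(L: np.ndarray) -> np.ndarray:
    """Indicator columns for all but the first dose level."""
    levels = np.unique(L)
    return (L[:, None] == levels[None, 1:]).astype(float)


def _nested_f(y: np.ndarray, X_red: np.ndarray, X_full: np.ndarray) -> tuple[float, float]:
    """F-test of the extra columns of X_full over X_red (both with intercept)."""
    n = y.size
    rss_red = _rss(y, X_red)
    rss_full = _rss(y, X_full)
    q = X_full.shape[1] - X_red.shape[1]
    df2 = n - X_full.shape[1]
    if df2 <= 0:
        raise ValueError("too few observations for the F-test")
    num = max(rss_red - rss_full, 0.0) / q
    den = rss_full / df2
    if den <= 0:
        return float("inf"), float(np.finfo(float).tiny)
    F = num / den
    return float(F), float(stats.f.sf(F, q, df2))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _cond4_p(
    L: np.ndarray, G: np.ndarray, T: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation equivalence-test p for T independent of L given G."""
    n = L.size
    D = _dummies(L)
    ones = np.ones((n, 1))
    XL = np.hstack([ones, D])  # intercept + dose indicators

    X_red = np.hstack([ones, G[:, None]])
    X_full = np.hstack([ones, D, G[:, None]])
    F_obs, _ = _nested_f(T, X_red, X_full)

    # G* = fitted(G | L) + permuted residuals: keeps the L-G link but
    # breaks G's mediation of any L -> T path.
    beta_g, _, _, _ = np.linalg.lstsq(XL, G, rcond=None)
    fitted = XL @ beta_g
    resid = G - fitted
    perms = np.stack([rng.permutation(resid) for _ in range(n_perm)], axis=1)
    Gstar = fitted[:, None] + perms  # n x n_perm

    # F* for L in T ~ L + G*, vectorized over permutations via nested RSS.
    q = D.shape[1]
    p_full = 1 + q + 1
    df2 = n - p_full

    # reduced model T ~ 1 + G*
    Tc = T - T.mean()
    Gc = Gstar - Gstar.mean(axis=0, keepdims=True)
    syy = float(Tc @ Tc)
    sxy = Tc @ Gc
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    rss_red = syy - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)

    # full model via Frisch-Waugh: partial XL out of T and G*
    PL = XL @ np.linalg.pinv(XL)
    rT = T - PL @ T
    rG = Gstar - PL @ Gstar
    rTT = float(rT @ rT)
    rTG = rT @ rG
    rGG = np.einsum("ij,ij->j", rG, rG)
    rss_full = rTT - np.where(rGG > 0, rTG**2 / np.where(rGG > 0, rGG, 1.0), 0.0)

    F_star = ((rss_red - rss_full) / q) / (rss_full / df2)
    return float((1 + np.sum(F_star <= F_obs)) / (n_perm + 1))


def _half_cit(
    L: np.ndarray, G: np.ndarray, T: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Component p-values for the chain L -> G -> T."""
    n = L.size
    D = _dummies(L)
    ones = np.ones((n, 1))
    # 1: T ~ L vs intercept
    _, p1 = _nested_f(T, ones, np.hstack([ones, D]))
    # 2: G ~ L + T vs G ~ T
    _, p2 = _nested_f(G, np.hstack([ones, T[:, None]]), np.hstack([ones, D, T[:, None]]))
    # 3: T ~ G + L vs T ~ L
    _, p3 = _nested_f(T, np.hstack([ones, D]), np.hstack([ones, D, G[:, None]]))
    p4 = _cond4_p(L, G, T, n_perm, rng)
    return p1, p2, p3, p4


def cit_test(
    L,
    G,
    T,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CITResult:
    """Run the four-condition causal inference test on one trio.

    ``L`` is the categorical dose (any hashable levels; at least 3
    observations per level), ``G`` and ``T`` continuous vectors.  The
    verdict compares both omnibus p-values to ``alpha``: causal when
    only the causal omnibus rejects, reactive when only the reactive
    one does, independent when neither does, undecided when both do.
    """
    L = np.asarray(L)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (L.size == G.size == T.size):
        raise ValueError("L, G, T must have equal length")
    levels, counts = np.unique(L, return_counts=True)
    if levels.size < 2:
        raise ValueError("dose must have at least 2 levels")
    if counts.min() < 3:
        raise ValueError("need at least 3 observations per dose level")
    if n_perm < 100:
        warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)

    rng_c = np.random.default_rng(seed)
    rng_r = np.random.default_rng(seed)  # same stream: G/T swap is an exact role exchange
    p1, p2, p3, p4 = _half_cit(L, G, T, n_perm, rng_c)
    q1, q2, q3, q4 = _half_cit(L, T, G, n_perm, rng_r)
    omnibus_causal = max(p1, p2, p3, p4)
    omnibus_reactive = max(q1, q2, q3, q4)
    if omnibus_causal < alpha <= omnibus_reactive:
        verdict = "causal"
    elif omnibus_reactive < alpha <= omnibus_causal:
        verdict = "reactive"
    elif omnibus_causal >= alpha and omnibus_reactive >= alpha:
        verdict = "independent"
    else:
        verdict = "undecided"
    return CITResult(
        p1=p1,
        p2=p2,
        p3=p3,
        p4=p4,
        omnibus_causal=omnibus_causal,
        omnibus_reactive=omnibus_reactive,
        verdict=verdict,
        n=int(L.size),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def cit_component_regressions(L, G, T) -> pd.DataFrame:
    """Reporting table of the four condition-level regressions.

    The dose enters numerically (its actual values, e.g. 0 / 0.1 / 1
    mM) so the betas are interpretable as per-unit-dose effects;
    factor-coded F-tests live in :func:`cit_test`.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    rows = []

    def ols_term(y, X_cols: dict[str, np.ndarray], term: str) -> tuple[float, float]:
        X = sm.add_constant(pd.DataFrame(X_cols))
        fit = sm.OLS(y, X).fit()
        return float(fit.params[term]), float(fit.pvalues[term])

    b, p = ols_term(G, {"L": L}, "L")
    rows.append(("L_vs_G", b, p))
    b, p = ols_term(T, {"L": L}, "L")
    rows.append(("L_vs_T", b, p))
    b, p = ols_term(G, {"L": L, "T": T}, "L")
    rows.append(("L_vs_G_given_T", b, p))
    b, p = ols_term(T, {"L": L, "G": G}, "L")
    rows.append(("L_vs_T_given_G", b, p))
    return pd.DataFrame(rows, columns=["condition", "beta", "p_value"]).set_index("condition")
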