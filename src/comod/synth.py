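"""Synthetic cohorts, perturbation signatures and causal triplets.

The generator plants the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any data download:

* a modular factor model of log2 expression — each planted module has a
  per-sample latent factor, member genes load on it with Gaussian noise,
  background genes are pure noise;
* a labelled gene subset (emulating genes in islet-selective open
  chromatin) whose loadings carry an additive hub boost, giving them
  elevated intramodular connectivity;
* phenotypes driven by the latent factors: binary disease status via a
  logistic model, HbA1c and log insulin secretion via linear models,
  plus independent age/sex/BMI nuisance covariates;
* perturbation (knockdown / overexpression) differential-expression
  signatures with a controllable directional concordance against a
  reference contrast;
* three-level dose -> mediator -> outcome triplets under causal,
  reactive or independent scenarios.

Defaults mirror the study shape the pipeline targets: 64 donors of whom
roughly 19 have diabetes, five planted modules of 50 genes, log2-scale
Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signatures import DifferentialSignature

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_perturbation_signature",
    "generate_cit_triplet",
    "DEFAULT_TRAIT_EFFECTS",
    "DOSE_LEVELS_MM",
]

#: latent-factor effect sizes per (trait, module); module 1 is the
#: disease-associated module: low factor values mean diabetes, high
#: HbA1c and impaired secretion.
DEFAULT_TRAIT_EFFECTS: dict[str, dict[int, float]] = {
    "t2d_status": {1: -1.2},
    "hba1c": {1: -0.5},
    "secretion_glucose": {1: 0.5},
    "secretion_K": {1: 0.3},
}

#: valproate-style dose levels in mM: none, low, high.
DOSE_LEVELS_MM: tuple[float, ...] = (0.0, 0.1, 1.0)

# intercept giving ~30% disease prevalence when factors are at zero
_T2D_INTERCEPT = -0.87


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated cohort."""

    module_assignment: pd.Series  # gene -> module label (0 = background)
    loadings: pd.Series  # gene -> weight on its module factor
    labelled_set: frozenset[str]
    trait_effects: dict[str, dict[int, float]]
    latent_factors: pd.DataFrame  # samples x modules
    seed: int
    causal_scenario: str | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "module_assignment": {g: int(m) for g, m in self.module_assignment.items()},
            "loadings": {g: float(v) for g, v in self.loadings.items()},
            "labelled_set": sorted(self.labelled_set),
            "trait_effects": {t: {str(m): v for m, v in eff.items()} for t, eff in self.trait_effects.items()},
            "latent_factors": {c: self.latent_factors[c].tolist() for c in self.latent_factors},
            "seed": self.seed,
            "causal_scenario": self.causal_scenario,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_cohort(
    n_samples: int = 64,
    n_genes: int = 500,
    module_sizes: tuple[int, ...] = (50, 50, 50, 50, 50),
    loading: float = 0.8,
    hub_boost: float = 0.2,
    labelled_frac: float = 0.4,
    trait_effects: dict[str, dict[int, float]] | None = None,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a cohort of log2 expression plus phenotypes.

    Per module m a latent factor e_m ~ N(0, 1) is drawn per sample; a
    member gene g has x_g = u_g * e_m + baseline + eps with
    eps ~ N(0, noise_sd^2).  Labelled genes (a ``labelled_frac``
    fraction of module 1) get u_g = loading + hub_boost, other members
    u_g = loading.  Background genes are baseline plus noise.

    Phenotypes: t2d_status ~ Bernoulli(logistic(alpha + sum beta_m e_m));
    hba1c and log secretion are linear in the factors plus noise;
    age, sex and BMI are independent nuisance covariates.

    Returns (expression genes x samples, phenotype table, truth).
    """
    module_sizes = tuple(int(s) for s in module_sizes)
    if sum(module_sizes) > n_genes:
        raise ValueError("sum of module sizes exceeds n_genes")
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not 0 < loading <= 1:
        raise ValueError("loading must lie in (0, 1]")
    if hub_boost < 0:
        raise ValueError("hub_boost must be non-negative")
    if trait_effects is None:
        trait_effects = DEFAULT_TRAIT_EFFECTS

    rng = np.random.default_rng(seed)
    n_modules = len(module_sizes)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]

    labels = np.zeros(n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size

    loadings = np.zeros(n_genes)
    loadings[labels > 0] = loading
    labelled: list[str] = []
    if module_sizes:
        module1 = np.flatnonzero(labels == 1)
        n_lab = int(round(labelled_frac * module1.size))
        labelled_idx = module1[:n_lab]
        loadings[labelled_idx] = loading + hub_boost
        labelled = [gene_ids[i] for i in labelled_idx]

    E = rng.standard_normal((n_samples, n_modules))  # latent factors
    X = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    for m in range(1, n_modules + 1):
        mask = labels == m
        X[mask] += np.outer(loadings[mask], E[:, m - 1])
    X += baseline

    def factor_sum(trait: str) -> np.ndarray:
        out = np.zeros(n_samples)
        for m, beta in trait_effects.get(trait, {}).items():
            out += beta * E[:, m - 1]
        return out

    logit = _T2D_INTERCEPT + factor_sum("t2d_status")
    t2d = rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))
    hba1c = 5.7 + factor_sum("hba1c") + rng.normal(0, 0.5, n_samples)
    # secretion is linear in the factors on the log scale, hence positive
    log_secr_glu = 1.0 + factor_sum("secretion_glucose") + rng.normal(0, 0.5, n_samples)
    log_secr_k = 0.5 + factor_sum("secretion_K") + rng.normal(0, 0.5, n_samples)

    pheno = pd.DataFrame(
        {
            "t2d_status": t2d.astype(int),
            "hba1c": hba1c,
            "secretion_glucose": np.exp(log_secr_glu),
            "secretion_K": np.exp(log_secr_k),
            "age": rng.normal(58, 10, n_samples).round(1),
            "sex": rng.integers(0, 2, n_samples),
            "bmi": rng.normal(27, 4, n_samples).round(1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    expr = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    truth = SyntheticTruth(
        module_assignment=pd.Series(labels, index=expr.index, name="module"),
        loadings=pd.Series(loadings, index=expr.index, name="loading"),
        labelled_set=frozenset(labelled),
        trait_effects={t: dict(e) for t, e in trait_effects.items()},
        latent_factors=pd.DataFrame(E, index=pheno.index, columns=[f"factor_{m}" for m in range(1, n_modules + 1)]),
        seed=int(seed),
        params={
            "n_samples": n_samples,
            "n_genes": n_genes,
            "module_sizes": list(module_sizes),
            "loading": loading,
            "hub_boost": hub_boost,
            "labelled_frac": labelled_frac,
            "noise_sd": noise_sd,
            "baseline": baseline,
        },
    )
    return expr, pheno, truth


def generate_perturbation_signature(
    truth: SyntheticTruth,
    reference: DifferentialSignature,
    concordance: float,
    flip: bool = False,
    alpha_frac: float = 0.5,
    seed: int = 0,
    magnitude_mu: float = -1.0,
    magnitude_sigma: float = 0.6,
) -> DifferentialSignature:
    """Simulate a perturbation contrast with controlled concordance.

    Each gene covered by ``reference`` (nonzero direction) is concordant
    with the reference direction with probability ``concordance`` and
    discordant otherwise; ``flip`` negates the target direction, so a
    knockdown-mimicking signature uses flip=False against a disease
    contrast and an overexpression-rescue signature uses flip=True.
    A fraction ``alpha_frac`` of genes is nominally significant
    (p < 0.05); fold-change magnitudes are LogNormal(magnitude_mu,
    magnitude_sigma) on the |log2FC| scale.
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must lie in [0, 1]")
    if not 0 <= alpha_frac <= 1:
        raise ValueError("alpha_frac must lie in [0, 1]")
    table = reference.table
    covered = table.index[table["direction"] != 0]
    if len(covered) == 0:
        raise ValueError("reference signature covers no directed genes")
    rng = np.random.default_rng(seed)
    ref_dir = table.loc[covered, "direction"].to_numpy()
    target = -ref_dir if flip else ref_dir
    concordant = rng.random(len(covered)) < concordance
    direction = np.where(concordant, target, -target)
    magnitude = rng.lognormal(magnitude_mu, magnitude_sigma, len(covered))
    significant = rng.random(len(covered)) < alpha_frac
    p = np.where(
        significant,
        rng.uniform(1e-6, 0.05, len(covered)),
        rng.uniform(0.05, 1.0, len(covered)),
    )
    out = pd.DataFrame(
        {"log2fc": direction * magnitude, "p_value": p},
        index=pd.Index(covered, name="gene_id"),
    )
    label = f"perturbation(concordance={concordance:g}, flip={flip})"
    return DifferentialSignature(contrast_label=label, table=out.assign(direction=np.sign(out["log2fc"]).astype(int)))


def generate_cit_triplet(
    n: int = 300,
    scenario: str = "causal",
    dose_levels: tuple[float, ...] = DOSE_LEVELS_MM,
    b_LG: float = 2.0,
    b_GT: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dose / mediator-expression / outcome table.

    The dose L is balanced over ``dose_levels`` and enters the linear
    structure through its numeric value (mM).  Scenarios:

    * causal:      G = b_LG * L + eps,  T = b_GT * G + eps
    * reactive:    T = b_LG * L + eps,  G = b_GT * T + eps
    * independent: L, G, T mutually independent
    """
    if n < 30:
        raise ValueError("need at least 30 observations")
    if scenario not in {"causal", "reactive", "independent"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    levels = np.asarray(dose_levels, dtype=float)
    if levels.size < 2:
        raise ValueError("need at least 2 dose levels")
    rng = np.random.default_rng(seed)
    L = np.resize(levels, n)  # balanced assignment
    rng.shuffle(L)
    if scenario == "causal":
        G = b_LG * L + rng.normal(0, noise_sd, n)
        T = b_GT * G + rng.normal(0, noise_sd, n)
    elif scenario == "reactive":
        T = b_LG * L + rng.normal(0, noise_sd, n)
        G = b_GT * T + rng.normal(0, noise_sd, n)
    else:
        G = rng.normal(0, noise_sd, n)
        T = rng.normal(0, noise_sd, n)
    return pd.DataFrame({"L": L, "G": G, "T": T})
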