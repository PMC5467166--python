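"""End-to-end analysis pipeline.

Chains similarity -> soft power -> adjacency -> TOM -> module detection
-> eigengenes -> trait association -> labelled-set enrichment and hub
analysis on either user-supplied tables or a synthetic cohort, and
persists every result as TSV/JSON together with a run log recording
seeds and parameters.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .enrichment import GeneSet, connectivity_set_comparison, fisher_enrichment
from .modules import all_eigengenes, detect_modules, intramodular_connectivity, module_eigengene
from .network import DEFAULT_BETA_GRID, DEFAULT_R2_THRESHOLD, build_network
from .synth import generate_cohort
from .traits import associate_eigengene_trait, connectivity_trait_correlation, gene_trait_correlations

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``expression_path`` or ``synthetic`` must be set;
    ``synthetic`` holds keyword arguments for
    :func:`comod.synth.generate_cohort`.
    """

    out_dir: str | Path = "comod_out"
    expression_path: str | None = None
    phenotype_path: str | None = None
    gene_sets_path: str | None = None
    synthetic: dict | None = None
    beta: int | None = None
    beta_grid: tuple[int, ...] = DEFAULT_BETA_GRID
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    cut_height: float | None = None  # None = adaptive scale-free cut
    min_module_size: int = 30
    traits: tuple[str, ...] = ("t2d_status", "hba1c", "secretion_glucose", "secretion_K")
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.expression_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError("config needs exactly one of expression_path or a synthetic block")
        if self.cut_height is not None and not 0 < self.cut_height < 1:
            raise ValueError("cut_height must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be at least 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("beta_grid", "traits", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineReport:
    """Where a run wrote its outputs and what it found."""

    out_dir: Path
    beta: int
    n_modules: int
    associations: pd.DataFrame
    enrichment: dict | None = None
    run_log: dict = field(default_factory=dict)


def _stage(log: dict, name: str, started: float) -> None:
    log["stages"].append({"stage": name, "seconds": round(time.perf_counter() - started, 3)})


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and persist all outputs under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "seed": config.seed,
        "parameters": {
            "beta": config.beta,
            "beta_grid": list(config.beta_grid),
            "r2_threshold": config.r2_threshold,
            "cut_height": config.cut_height,
            "min_module_size": config.min_module_size,
            "traits": list(config.traits),
            "covariates": list(config.covariates),
            "alpha": config.alpha,
        },
        "stages": [],
    }
    failed_marker = out / "failed"

    def abort(stage: str, err: Exception) -> None:
        failed_marker.mkdir(exist_ok=True)
        (failed_marker / "stage.txt").write_text(f"{stage}: {err}\n")
        (out / "run_log.json").write_text(json.dumps(log, indent=1))

    stage = "load"
    try:
        t0 = time.perf_counter()
        truth = None
        labelled_set: GeneSet | None = None
        if config.synthetic is not None:
            synth_kwargs = dict(config.synthetic)
            synth_kwargs.setdefault("seed", config.seed)
            log["seed"] = synth_kwargs["seed"]
            X, pheno, truth = generate_cohort(**synth_kwargs)
            cio.write_expression_table(X, out / "expression.tsv")
            cio.write_phenotype_table(pheno, out / "phenotypes.csv")
            truth.to_json(out / "truth.json")
            if truth.labelled_set:
                labelled_set = GeneSet("labelled", frozenset(truth.labelled_set))
                cio.write_gene_sets({"labelled": labelled_set}, out / "gene_sets.gmt")
            log["synthetic"] = {k: v for k, v in synth_kwargs.items()}
        else:
            X = cio.read_expression_table(config.expression_path)
            pheno = cio.read_phenotype_table(config.phenotype_path) if config.phenotype_path else None
            if config.gene_sets_path:
                sets = cio.read_gene_sets(config.gene_sets_path)
                if sets:
                    labelled_set = next(iter(sets.values()))
        _stage(log, stage, t0)

        stage = "network"
        t0 = time.perf_counter()
        net = build_network(
            X, beta=config.beta, beta_grid=config.beta_grid, r2_threshold=config.r2_threshold
        )
        log["beta"] = net.beta
        if net.beta_choice is not None:
            log["beta_scan"] = net.beta_choice.scan.to_dict("records")
            log["beta_flagged"] = net.beta_choice.flagged
        _stage(log, stage, t0)

        stage = "modules"
        t0 = time.perf_counter()
        partition = detect_modules(
            net.D,
            gene_ids=net.gene_ids,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            expression=X,
        )
        partition.labels.to_csv(out / "modules.tsv", sep="\t")
        k_in = intramodular_connectivity(net.A, partition)
        k_in.to_csv(out / "k_in.tsv", sep="\t", float_format="%.17g")
        if partition.n_modules >= 1:
            eigs = all_eigengenes(X, partition)
            eigs.to_csv(out / "eigengenes.tsv", sep="\t", float_format="%.17g")
        _stage(log, stage, t0)

        stage = "associations"
        t0 = time.perf_counter()
        rows = []
        if pheno is not None and partition.n_modules >= 1:
            for m in range(1, partition.n_modules + 1):
                eig = module_eigengene(X, partition, m)
                for trait in config.traits:
                    if trait not in pheno.columns:
                        continue
                    for covs in ((), tuple(c for c in config.covariates if c in pheno.columns)):
                        try:
                            res = associate_eigengene_trait(
                                eig.values, pheno, trait, covariates=covs, predictor_id=f"ME{m}"
                            )
                        except ValueError:
                            continue
                        rows.append(
                            {
                                "predictor": res.predictor_id,
                                "trait": res.trait_name,
                                "model": res.model,
                                "beta": res.beta,
                                "p_value": res.p_value,
                                "n": res.n,
                                "covariates": "+".join(res.covariates) or "none",
                                "converged": res.converged,
                            }
                        )
        associations = pd.DataFrame(rows)
        associations.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.17g")
        _stage(log, stage, t0)

        stage = "enrichment"
        t0 = time.perf_counter()
        enrichment_summary = None
        if labelled_set is not None and partition.n_modules >= 1 and pheno is not None:
            universe = GeneSet("universe", frozenset(map(str, X.index)))
            # module most associated with the first trait (smallest p)
            if len(associations):
                best = associations.loc[associations["p_value"].idxmin(), "predictor"]
                best_module = int(str(best).removeprefix("ME"))
            else:
                best_module = 1
            module_set = GeneSet(f"module{best_module}", frozenset(partition.members(best_module)))
            enr = fisher_enrichment(labelled_set, module_set, universe)
            captured = sorted(labelled_set.gene_ids & module_set.gene_ids)
            mean_ratio, p_kin = (float("nan"), float("nan"))
            if captured and len(captured) < len(module_set):
                k_mod = k_in.loc[list(module_set.gene_ids), "k_in"]
                mean_ratio, p_kin = connectivity_set_comparison(
                    k_mod, GeneSet("captured", frozenset(captured)), module_set
                )
            trait0 = next((t for t in config.traits if t in pheno.columns), None)
            hub_r, hub_p = (float("nan"), float("nan"))
            if trait0 is not None:
                r_trait = gene_trait_correlations(X.loc[list(module_set.gene_ids)], pheno, trait0)
                k_mod = k_in.loc[r_trait.index, "k_in"]
                hub_r, hub_p = connectivity_trait_correlation(k_mod, r_trait, method="spearman")
            enrichment_summary = {
                "module": best_module,
                "module_size": len(module_set),
                "labelled_in_module": enr.a,
                "capture_fraction": enr.capture_fraction,
                "fold_enrichment": enr.fold_enrichment,
                "p": enr.p,
                "kin_mean_ratio": mean_ratio,
                "kin_p": p_kin,
                "hub_trait_spearman_r": hub_r,
                "hub_trait_spearman_p": hub_p,
            }
            (out / "enrichment.json").write_text(json.dumps(enrichment_summary, indent=1))
        _stage(log, stage, t0)

        log["n_modules"] = partition.n_modules
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
    except Exception as err:  # persist partial results before propagating
        abort(stage, err)
        raise

    return PipelineReport(
        out_dir=out,
        beta=net.beta,
        n_modules=partition.n_modules,
        associations=associations,
        enrichment=enrichment_summary,
        run_log=log,
    )
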