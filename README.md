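# comod — co-expression module analysis for islet transcriptomes

`comod` re-implements, as a tested and reusable Python library, the
network-biology workflow used to link a pancreatic-islet gene
co-expression module to type 2 diabetes (T2D): weighted co-expression
network construction, module detection, eigengene–trait association,
gene-set and hub-connectivity enrichment, cross-dataset signature
concordance, and a causal inference test for dose → mediator → outcome
experiments.  It is aimed at computational biologists who want each of
those stages as a plain, inspectable function operating on pandas
DataFrames, with a synthetic-data generator that makes the whole
pipeline runnable and testable without any external cohort.

## The model

Starting from a genes × samples matrix of log2 expression values
*x*, the network is built as in the WGCNA framework:

- similarity: *s*ᵢⱼ = |cor(*x*ᵢ, *x*ⱼ)| (absolute Pearson correlation);
- soft-thresholded adjacency: *a*ᵢⱼ = *s*ᵢⱼ^β, with the integer power β
  chosen as the smallest value for which the degree distribution
  p(*k*) of connectivities *k*ᵢ = Σⱼ≠ᵢ *a*ᵢⱼ is approximately
  scale-free (R² of the log–log regression of p(*k*) on *k* ≥ 0.8);
- topological overlap: ωᵢⱼ = (*l*ᵢⱼ + *a*ᵢⱼ) / (min(*k*ᵢ, *k*ⱼ) + 1 −
  *a*ᵢⱼ), with *l*ᵢⱼ = Σᵤ *a*ᵢᵤ*a*ᵤⱼ, which measures shared network
  neighbourhood rather than a single strong edge;
- dissimilarity *d*ᵢⱼ = 1 − ωᵢⱼ, clustered by average linkage and cut
  into modules (adaptive, scale-invariant cut by default; static
  height optional).

Each module is summarised by its **eigengene** (first principal
component of the standardized member expression), which is regressed
on clinical traits — logistic for T2D status, linear for HbA1c and
log-transformed insulin secretion, optionally adjusted for age, sex
and BMI.  Gene sets (e.g. genes in islet-selective open chromatin) are
tested for module capture by Fisher's exact test with
Benjamini–Hochberg correction, and for elevated intramodular
connectivity *k*ᵢₙ.  Perturbation signatures are compared with a
reference contrast by directional concordance, and the **causal
inference test** (CIT) evaluates whether an intervention dose L acts
on an outcome T through a mediator gene G via four conditions (L–T
association, L–G given T, G–T given L, and a permutation-based
equivalence test of L ⫫ T given G), combined as an intersection–union
omnibus p = max(p₁…p₄).

## Worked example

```sh
python examples/01_network_and_modules.py
```

```
cohort: 500 genes x 64 donors, 18 with T2D
soft power beta = 2 (scale-free fit R^2 = 0.806)
detected 5 modules, sizes: [72, 54, 52, 50, 44]
adjusted Rand index vs planted modules = 0.833
```

The generator plants five 50-gene modules in a 64-donor cohort; the
full chain (similarity → β → TOM → clustering) recovers them almost
exactly (adjusted Rand index 0.83; label 0 marks background genes).
The remaining examples cover trait association, enrichment, signature
concordance and causal inference, e.g.:

```sh
python examples/05_causal_inference.py
```

```
causal       omnibus causal=0.001 reactive=0.923 -> verdict: causal
reactive     omnibus causal=0.923 reactive=0.001 -> verdict: reactive
independent  omnibus causal=0.860 reactive=0.853 -> verdict: independent
```

A small causal omnibus alongside a large reactive one supports the
chain dose → expression → secretion; the other scenarios resolve
accordingly.

A thin CLI mirrors the library (`comod simulate`, `comod network`,
`comod modules`, `comod associate`, `comod enrich`,
`comod signature ...`, `comod cit run`, `comod pipeline --config
config.yaml`).

## Layout

- `src/comod/` — the library (`synth`, `network`, `modules`, `traits`,
  `enrichment`, `signatures`, `cit`, `io`, `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — modelling assumptions, parameter choices and
  known limitations
- `tests/` — pytest suite, including oracle-equivalence and
  calibration checks
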