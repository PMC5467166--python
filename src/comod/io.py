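"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column gene ids, header =
sample ids), phenotypes as CSV indexed by sample id, gene sets as GMT
(name TAB description TAB gene ids...), signatures as three-column TSV
and structured results as JSON.  Everything round-trips losslessly at
full float precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSet

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_signature",
    "write_signature",
]


def read_expression_table(path) -> pd.DataFrame:
    """Read a genes x samples TSV of log2 expression values.

    Duplicated gene ids and non-numeric cells are hard errors; the
    error message names the offending id or coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicated gene id(s) in {path}: {', '.join(map(str, dup[:5]))}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"duplicated sample id(s) in {path}")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & df.notna() | df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing cell in {path} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    values.index.name = "gene_id"
    return values.astype(float)


def write_expression_table(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def read_phenotype_table(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, index_col=0)
    pheno.index = pheno.index.astype(str)
    pheno.index.name = "sample_id"
    if pheno.index.has_duplicates:
        raise ValueError(f"duplicated sample id(s) in {path}")
    return pheno


def write_phenotype_table(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index_label="sample_id", float_format="%.17g")


def read_gene_sets(path) -> dict[str, GeneSet]:
    """Read GMT: one set per line, name TAB description TAB gene ids."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and at least one gene")
        name = fields[0]
        ids = [g for g in fields[2:] if g]
        if not ids:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no gene ids")
        if len(set(ids)) < len(ids):
            warnings.warn(f"{path}:{lineno}: duplicate gene ids in set {name!r} deduplicated", stacklevel=2)
        sets[name] = GeneSet(name=name, gene_ids=frozenset(ids))
    return sets


def write_gene_sets(sets: dict[str, GeneSet], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, gs in sets.items():
            fh.write("\t".join([name, description, *sorted(gs.gene_ids)]) + "\n")


def read_signature(path, contrast_label: str | None = None):
    """Read a signature TSV with columns gene_id, log2fc, p_value."""
    from .signatures import DifferentialSignature

    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "p_value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return DifferentialSignature.from_arrays(
        df["gene_id"].astype(str), df["log2fc"], df["p_value"], contrast_label or str(path)
    )


def write_signature(sig, path) -> None:
    out = sig.table.reset_index()[["gene_id", "log2fc", "p_value"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
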