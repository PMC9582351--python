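"""Readers, writers and cohort merging for the standard flat-text formats.

Expression travels as a genes x samples :class:`pandas.DataFrame` of log2
intensities (TSV with gene IDs in the first column, or GCT 1.2); gene
sets as GMT; clinical annotations and MAF-like mutation calls as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_clinical",
    "read_mutations",
    "merge_cohorts",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def _collapse_duplicate_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated symbol, the row with the largest mean
    expression (the usual microarray probe-collapse convention)."""
    if expr.index.is_unique:
        return expr
    means = expr.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    keep = ~expr.index[order].duplicated()
    kept_positions = np.sort(order[keep])
    return expr.iloc[kept_positions]


def _validate_numeric(expr: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise FormatError(
            f"{path}: non-numeric expression value at gene {gene!r}, sample {col!r}"
        )
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        raise FormatError(f"{path}: missing value in gene {gene!r}")
    return numeric.astype(float)


def read_expression(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read an expression matrix from TSV or GCT 1.2.

    Duplicate gene symbols are collapsed by keeping the row with the
    highest mean expression.
    """
    path = Path(path)
    if dialect is None:
        dialect = "gct" if path.suffix.lower() == ".gct" else "tsv"
    dialect = dialect.lower()
    if dialect not in {"tsv", "gct"}:
        raise ValueError(f"unknown expression dialect {dialect!r}")

    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"{path}: missing GCT '#1.2' header line")
            fh.readline()  # dimensions line (validated against the body below)
            expr = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in expr.columns:
            expr = expr.drop(columns="Description")
        else:  # second column is the description regardless of its name
            expr = expr.drop(columns=expr.columns[0])
    else:
        expr = pd.read_csv(path, sep="\t", index_col=0)

    if expr.empty or expr.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    expr.index = expr.index.astype(str)
    expr.index.name = "gene"
    expr.columns = expr.columns.astype(str)
    expr = _validate_numeric(expr, path)
    return _collapse_duplicate_genes(expr)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    The description column is dropped and duplicate genes within a set
    deduplicated; duplicate set names are an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene ({len(fields)} fields found)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: dict[str, set[str] | list[str]], path: str | Path,
                    description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV indexed by ``sample_id``; validates times and
    event indicators."""
    clin = pd.read_csv(path, sep="\t", index_col=0)
    clin.index = clin.index.astype(str)
    clin.index.name = "sample_id"
    if not clin.index.is_unique:
        raise FormatError(f"{path}: duplicate sample IDs")
    for col in ("os_time", "rfs_time"):
        if col in clin.columns and (clin[col].dropna() < 0).any():
            raise FormatError(f"{path}: negative values in {col}")
    for col in ("os_event", "rfs_event"):
        if col in clin.columns:
            vals = set(clin[col].dropna().unique())
            if not vals <= {0, 1}:
                raise FormatError(f"{path}: {col} must be 0/1")
    return clin


MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like TSV of single mutation calls."""
    maf = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MAF_REQUIRED if c not in maf.columns]
    if missing:
        raise FormatError(f"{path}: missing MAF columns {missing}")
    return maf


def merge_cohorts(
    cohorts: list[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.Series]:
    """Merge >=2 expression cohorts on their shared genes.

    Returns the merged matrix (rows = sorted gene intersection, columns =
    concatenated samples) and a batch-label Series mapping each sample to
    the index of its source cohort.
    """
    if len(cohorts) < 2:
        raise ValueError("merge_cohorts needs at least two cohorts")
    all_samples = pd.Index([])
    for c in cohorts:
        overlap = all_samples.intersection(c.columns)
        if len(overlap):
            raise ValueError(f"duplicate sample IDs across cohorts: {list(overlap)[:5]}")
        all_samples = all_samples.append(pd.Index(c.columns))
    shared = set(cohorts[0].index)
    for c in cohorts[1:]:
        shared &= set(c.index)
    if not shared:
        raise ValueError("cohorts share no genes; nothing to merge")
    genes = sorted(shared)
    merged = pd.concat([c.loc[genes] for c in cohorts], axis=1)
    batch = pd.Series(
        np.concatenate([np.full(c.shape[1], i) for i, c in enumerate(cohorts)]),
        index=merged.columns,
        name="batch",
    )
    return merged, batch
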