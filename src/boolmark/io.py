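"""Readers, writers and cohort merging for expression, annotation and clinical tables.

All tables are single-header-row TSV. The missing-value token is ``NA`` (an
empty cell is also accepted on read). Expression matrices are genes x samples
in log2 units and are taken as already normalized and cross-cohort comparable;
no renormalization is performed here. Gene symbols are opaque keys — no alias
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("boolmark")

MISSING_TOKEN = "NA"

TISSUE_CLASSES = ("CRC", "polyp", "IBD", "normal")
MSI_LEVELS = ("MSI", "MSS", "unknown")
MUTATION_LEVELS = ("mutant", "wildtype", "unknown")

#: clinical columns that must be present in a clinical TSV
CLINICAL_REQUIRED = ("patient_id", "dfs_months", "dfs_event", "stage", "age", "sex")


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with NaN marking missing entries.

    ``values`` is a float DataFrame indexed by gene id with sample-id columns.
    ``annotations`` optionally carries the per-sample annotation table.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression matrix contains non-finite (inf) values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def gene_values(self, gene_id: str) -> pd.Series:
        return self.values.loc[gene_id]


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Empty cells and ``NA`` become missing. Any other non-numeric cell is a
    hard error reporting the offending gene and sample.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dup}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dup}")
    cleaned = raw.replace({"": None, MISSING_TOKEN: None})
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & cleaned.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}: {raw.iat[g, s]!r}"
        )
    return ExpressionMatrix(values=numeric.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_expression_matrix` (missing -> NA)."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def _normalize_categorical(series: pd.Series, levels: tuple[str, ...]) -> pd.Series:
    out = series.fillna("unknown").astype(str)
    out = out.where(out.isin(levels), "unknown")
    return out


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the per-sample annotation TSV, keyed by sample_id.

    Categorical fields outside their enumerations (and absent columns) map to
    ``unknown``. Tissue class must be one of CRC/polyp/IBD/normal.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).replace("", None)
    for col in ("sample_id", "tissue_class"):
        if col not in table.columns:
            raise ValueError(f"annotation table {path} lacks required column {col!r}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in {path}: {dup}")
    table = table.set_index("sample_id")
    bad_tissue = ~table["tissue_class"].isin(TISSUE_CLASSES)
    if bad_tissue.any():
        raise ValueError(
            f"unrecognized tissue_class values in {path}: "
            f"{sorted(table.loc[bad_tissue, 'tissue_class'].unique())}"
        )
    for col, levels in [
        ("msi", MSI_LEVELS),
        ("kras", MUTATION_LEVELS),
        ("braf", MUTATION_LEVELS),
        ("tp53", MUTATION_LEVELS),
    ]:
        if col in table.columns:
            table[col] = _normalize_categorical(table[col], levels)
        else:
            table[col] = "unknown"
    if "cohort_id" not in table.columns:
        table["cohort_id"] = "unknown"
    return table


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical TSV.

    Rows with non-positive DFS times are dropped (count logged). A blank chemo
    cell becomes the explicit ``missing`` category, which baseline tables show
    as a Missing row but all tests exclude.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).replace("", None)
    absent = [c for c in CLINICAL_REQUIRED if c not in table.columns]
    if absent:
        raise ValueError(f"clinical table {path} lacks required column(s): {absent}")
    if table["patient_id"].duplicated().any():
        dup = table.loc[table["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id(s) in {path}: {dup}")
    for col in ("dfs_months", "dss_months", "age", "cea", "ca199"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    for col in ("dfs_event", "dss_event"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce").astype("Int64")
    nonpos = table["dfs_months"].isna() | (table["dfs_months"] <= 0)
    if "dss_months" in table.columns:
        nonpos |= table["dss_months"].notna() & (table["dss_months"] <= 0)
    if nonpos.any():
        logger.warning(
            "read_clinical_table: dropped %d row(s) with non-positive survival time",
            int(nonpos.sum()),
        )
        table = table.loc[~nonpos]
    if "chemo" in table.columns:
        table["chemo"] = table["chemo"].fillna("missing")
    else:
        table["chemo"] = "missing"
    for col, default in [("location", "unknown"), ("grade", "unknown")]:
        if col in table.columns:
            table[col] = table[col].fillna(default)
        else:
            table[col] = default
    return table.set_index("patient_id")


def write_clinical_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def merge_cohorts(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate cohorts; the gene set is the union of input gene sets.

    Genes absent from a source cohort are missing for that cohort's samples.
    Sample id sets must be disjoint.
    """
    if not matrices:
        raise ValueError("merge_cohorts needs at least one matrix")
    seen: set[str] = set()
    for m in matrices:
        overlap = seen & set(m.sample_ids)
        if overlap:
            raise ValueError(f"overlapping sample ids across cohorts: {sorted(overlap)}")
        seen |= set(m.sample_ids)
    merged = pd.concat([m.values for m in matrices], axis=1)
    # preserve gene order: first cohort's genes, then new genes in encounter order
    gene_order: list[str] = []
    known: set[str] = set()
    for m in matrices:
        for g in m.gene_ids:
            if g not in known:
                known.add(g)
                gene_order.append(g)
    merged = merged.loc[gene_order]
    annots = [m.annotations for m in matrices if m.annotations is not None]
    merged_annot = pd.concat(annots) if annots else None
    return ExpressionMatrix(values=merged, annotations=merged_annot)
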