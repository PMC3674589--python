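"""TSV readers/writers shared across the pipeline.

All tables are plain tab-separated text with a header line; expression
matrices have the gene/probe identifier in the first column and sample ids as
the remaining column names.  Identifiers are opaque strings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.index.name = expr.index.name or "gene_id"
    return expr


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_probe_map_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="probe_id"),
                     name="gene_id")


def write_probe_map_tsv(probe_map: pd.Series, path: str | Path) -> None:
    probe_map.rename("gene_id").to_csv(path, sep="\t")


def read_ortholog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog table needs two columns: human_gene, mouse_gene")
    df = df.iloc[:, :2]
    df.columns = ["human_gene", "mouse_gene"]
    return df


def write_ortholog_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_assignment_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="gene_id"),
                     name="module")


def write_assignment_tsv(assignment: pd.Series, path: str | Path) -> None:
    assignment.rename("module").to_csv(path, sep="\t")


def write_table_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
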