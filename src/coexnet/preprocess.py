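"""Microarray-style preprocessing: outlier screen, quantile normalization,
empirical-Bayes batch adjustment, probe collapsing, ortholog projection.

The chain runs in a fixed order — interarray-correlation outlier screen,
quantile normalization, ComBat batch adjustment, collapse of redundant probes
to one row per gene (highest mean probe wins) — and, for the test-species
dataset, re-indexing onto the reference species through a one-to-one ortholog
table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "detect_outlier_samples",
    "quantile_normalize",
    "adjust_batch",
    "collapse_probes",
    "map_orthologs",
    "preprocess_expression",
]


def detect_outlier_samples(expr: pd.DataFrame, z_threshold: float = -2.5) -> list[str]:
    """Flag samples whose mean interarray correlation is an outlier.

    Each sample's mean Pearson correlation with all other samples is computed,
    these means are standardized across samples, and samples falling below
    ``z_threshold`` are returned.  The conventional cut of -2.5 flags nothing
    on homogeneous data.
    """
    if expr.shape[1] < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    cor = np.corrcoef(expr.to_numpy().T)
    n = cor.shape[0]
    mean_iac = (cor.sum(axis=1) - 1.0) / (n - 1)
    sd = mean_iac.std(ddof=1)
    if sd == 0:
        return []
    z = (mean_iac - mean_iac.mean()) / sd
    return [s for s, zi in zip(expr.columns, z) if zi < z_threshold]


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common empirical distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    each column's values are replaced by the reference values at their ranks,
    with ties receiving the mean of the reference values at the tied ranks.
    """
    x = expr.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            "quantile_normalize requires complete data; impute or drop missing values first"
        )
    n_genes, n_samples = x.shape
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n_genes)
        ranked[order] = reference
        # average the reference values over tied entries
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if uniq.size < n_genes:
            sums = np.zeros(uniq.size)
            np.add.at(sums, inv, ranked)
            ranked = (sums / counts)[inv]
        out[:, j] = ranked
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def adjust_batch(expr: pd.DataFrame, meta: pd.DataFrame, batch_col: str = "batch") -> pd.DataFrame:
    """Remove batch effects with parametric empirical-Bayes ComBat.

    Per gene and batch, location and scale parameters are estimated and shrunk
    toward common priors before subtraction, following the standard ComBat
    model (delegated to :func:`scanpy.pp.combat`).  A single-batch matrix is
    returned unchanged.
    """
    missing = [s for s in expr.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    batches = meta.loc[list(expr.columns), batch_col].astype(str)
    counts = batches.value_counts()
    if len(counts) == 1:
        return expr.copy()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batches with fewer than 2 samples: {sorted(small.index)}")
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(
        X=expr.to_numpy(dtype=float).T,
        obs=pd.DataFrame({batch_col: pd.Categorical(batches)}, index=list(expr.columns)),
    )
    sc.pp.combat(adata, key=batch_col)
    return pd.DataFrame(np.asarray(adata.X).T, index=expr.index, columns=expr.columns)


def collapse_probes(probe_expr: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Summarize multiple probes per gene by the probe with highest mean.

    ``probe_map`` maps probe_id -> gene_id (many-to-one).  For each gene the
    row of the probe whose across-sample mean expression is maximal is kept;
    ties break in favour of the first probe in input order.
    """
    unmapped = [p for p in probe_expr.index if p not in probe_map.index]
    if unmapped:
        raise ValueError(f"probes missing from probe map: {unmapped[:10]}")
    genes = probe_map.loc[probe_expr.index].to_numpy()
    means = probe_expr.to_numpy().mean(axis=1)
    best: dict[str, int] = {}
    for pos, (gene, mu) in enumerate(zip(genes, means)):
        if gene not in best or mu > means[best[gene]]:
            best[gene] = pos
    order = sorted(best, key=lambda g: best[g])  # keep first-probe input order
    rows = [best[g] for g in order]
    out = probe_expr.iloc[rows].copy()
    out.index = pd.Index(order, name="gene_id")
    return out


def map_orthologs(mouse_expr: pd.DataFrame, ortholog_table: pd.DataFrame) -> pd.DataFrame:
    """Re-index a mouse matrix by human gene ids via a 1:1 ortholog table.

    Rows of the table whose human or mouse gene appears more than once are
    dropped (one-to-one in both directions), as are genes absent from the
    expression matrix; the number of dropped genes is logged.
    """
    if ortholog_table.empty:
        raise ValueError("ortholog table is empty")
    tab = ortholog_table.drop_duplicates()
    tab = tab[~tab["human_gene"].duplicated(keep=False)]
    tab = tab[~tab["mouse_gene"].duplicated(keep=False)]
    tab = tab[tab["mouse_gene"].isin(mouse_expr.index)]
    if tab.empty:
        raise ValueError("no one-to-one orthologs present in the expression matrix")
    dropped = mouse_expr.shape[0] - tab.shape[0]
    if dropped:
        logger.info("map_orthologs: dropped %d genes without a one-to-one ortholog", dropped)
    out = mouse_expr.loc[tab["mouse_gene"]].copy()
    out.index = pd.Index(tab["human_gene"].to_numpy(), name="gene_id")
    return out


def preprocess_expression(
    probe_expr: pd.DataFrame,
    meta: pd.DataFrame,
    probe_map: pd.Series | None = None,
    z_threshold: float = -2.5,
    batch_col: str = "batch",
) -> tuple[pd.DataFrame, dict]:
    """Run the full preprocessing chain; returns the gene matrix and a log.

    Order: outlier screen -> quantile normalize -> batch adjust -> collapse
    probes (skipped when ``probe_map`` is None).
    """
    outliers = detect_outlier_samples(probe_expr, z_threshold=z_threshold)
    kept = [s for s in probe_expr.columns if s not in outliers]
    expr = probe_expr[kept]
    expr = quantile_normalize(expr)
    expr = adjust_batch(expr, meta, batch_col=batch_col)
    if probe_map is not None:
        expr = collapse_probes(expr, probe_map)
    info = {
        "outlier_samples": outliers,
        "n_samples": expr.shape[1],
        "n_genes": expr.shape[0],
    }
    return expr, info
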