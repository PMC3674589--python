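"""Signed weighted co-expression network construction and module detection.

The network is built from pairwise Pearson correlations soft-thresholded into
a signed adjacency a_ij = ((1 + cor_ij)/2)^beta, so anti-correlated genes get
near-zero adjacency and the network stays weighted rather than binarized.
Genes are clustered by average-linkage hierarchical clustering of the
topological-overlap dissimilarity (1 - TOM), and modules are branches of the
tree found by a dynamic branch cut with a hybrid assignment stage.  Detected
modules are labeled with colors in decreasing size order; unassigned genes
are "grey".

For large gene sets, :func:`blockwise_modules` pre-partitions genes into
blocks by clustering a low-dimensional projection, runs the full pipeline
within each block, and merges modules whose eigengenes are highly correlated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "GREY",
    "STANDARD_COLORS",
    "Dendrogram",
    "correlation_matrix",
    "signed_adjacency",
    "topological_overlap",
    "tom_dissimilarity",
    "average_linkage_tree",
    "dynamic_tree_cut",
    "merge_close_modules",
    "blockwise_modules",
    "label_modules_by_size",
]

GREY = "grey"

# conventional module color sequence, assigned in decreasing module size order
STANDARD_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes.

    ``merges`` is the scipy linkage encoding: row k merges clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` (indices < n are leaves, n + k is
    the cluster formed at row k) at height ``merges[k, 2]``.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_jsonl(self, path: str | Path) -> None:
        """Write the merge list as JSON lines (one merge per line)."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"n_leaves": self.n_leaves, "labels": self.labels}) + "\n")
            for left, right, height, size in self.merges:
                fh.write(
                    json.dumps(
                        {"left": int(left), "right": int(right),
                         "height": float(height), "size": int(size)}
                    )
                    + "\n"
                )


def correlation_matrix(expr: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """All pairwise Pearson correlations between gene profiles.

    Complete data uses the fast matrix path; matrices with missing values
    fall back to pairwise-complete correlations requiring at least
    ``min_periods`` shared samples.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation_matrix needs at least 3 samples")
    x = expr.to_numpy(dtype=float)
    has_nan = np.isnan(x).any()
    variances = np.nanvar(x, axis=1)
    zero_var = expr.index[variances == 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance genes: {zero_var[:10]}")
    if not has_nan:
        cor = np.corrcoef(x)
    else:
        cor = expr.T.corr(min_periods=min_periods).to_numpy()
        if np.isnan(cor).any():
            raise ValueError(
                f"gene pairs with fewer than {min_periods} shared complete samples"
            )
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: float = 12.0):
    """Soft-threshold a correlation matrix into a signed adjacency.

    a_ij = ((1 + cor_ij) / 2) ** beta, diagonal forced to 1.  With the
    conventional beta = 12, uncorrelated genes get adjacency 0.5**12 and
    anti-correlated genes essentially 0.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    c = np.asarray(cor, dtype=float)
    adj = np.abs(0.5 + 0.5 * c) ** beta
    np.fill_diagonal(adj, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def topological_overlap(adj: pd.DataFrame | np.ndarray):
    """Topological overlap matrix of a (signed) adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; the diagonal is 1.  Shared
    network neighbours thus augment direct adjacency.
    """
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1) - 1.0  # diagonal is 1
    # sum over all u of a_iu a_uj equals (A @ A)_ij; removing u = i and u = j
    # (each contributing a_ij since the diagonal is 1) leaves numerator - a_ij
    numerator = a @ a - 2.0 * a + a
    min_k = np.minimum.outer(k, k)
    denominator = min_k + 1.0 - a
    denominator = np.where(np.abs(denominator) < np.finfo(float).eps, np.finfo(float).eps,
                           denominator)
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def tom_dissimilarity(tom: pd.DataFrame | np.ndarray):
    """d = 1 - TOM with a zero diagonal; the clustering input."""
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    if isinstance(tom, pd.DataFrame):
        return pd.DataFrame(d, index=tom.index, columns=tom.columns)
    return d


def average_linkage_tree(diss: pd.DataFrame | np.ndarray) -> Dendrogram:
    """UPGMA (average linkage) tree of a symmetric dissimilarity matrix."""
    d = np.asarray(diss, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if (d < 0).any():
        raise ValueError("dissimilarity must be non-negative")
    labels = (
        list(diss.index) if isinstance(diss, pd.DataFrame) else [str(i) for i in range(len(d))]
    )
    condensed = d[np.triu_indices_from(d, k=1)]
    merges = linkage(condensed, method="average")
    return Dendrogram(merges=merges, labels=labels)


def _cluster_members(merges: np.ndarray, n: int) -> list[list[int]]:
    """Leaf members of the cluster formed at each merge row."""
    members: list[list[int]] = []
    for k in range(merges.shape[0]):
        row: list[int] = []
        for side in (int(merges[k, 0]), int(merges[k, 1])):
            if side < n:
                row.append(side)
            else:
                row.extend(members[side - n])
        members.append(row)
    return members


def dynamic_tree_cut(
    dend: Dendrogram,
    diss: pd.DataFrame | np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
) -> pd.Series:
    """Cut tree branches into modules, with a hybrid assignment stage.

    The tree is cut at ``cut_height`` (by default a fraction of the maximum
    merge height controlled by ``deep_split``: 0.99 down to 0.95 of the
    maximum for deep_split 0..4, deeper splits cutting lower); branches with
    at least ``min_module_size`` leaves become modules and everything else is
    provisionally grey.  The hybrid stage then assigns each grey gene to the
    closest module when its average dissimilarity to that module's genes is
    below the module branch's own top internal merge height.

    Returns a gene -> color label series (size-ordered colors, grey =
    unassigned).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in (0, 1, 2, 3, 4):
        raise ValueError("deep_split must be in {0, 1, 2, 3, 4}")
    d = np.asarray(diss, dtype=float)
    n = dend.n_leaves
    if d.shape[0] != n:
        raise ValueError("dendrogram and dissimilarity disagree on gene count")
    merges = dend.merges
    if cut_height is None:
        cut_height = (0.99 - 0.01 * deep_split) * float(merges[:, 2].max())
    flat = fcluster(merges, t=cut_height, criterion="distance")
    labels = np.full(n, GREY, dtype=object)
    members = _cluster_members(merges, n)
    # top internal merge height per flat cluster (0 for singletons)
    branch_height: dict[int, float] = {}
    for k in range(merges.shape[0]):
        if merges[k, 2] > cut_height:
            continue
        cid = flat[members[k][0]]
        branch_height[cid] = max(branch_height.get(cid, 0.0), float(merges[k, 2]))
    module_ids = [
        cid for cid in np.unique(flat) if np.count_nonzero(flat == cid) >= min_module_size
    ]
    for j, cid in enumerate(module_ids):
        labels[flat == cid] = f"module_{j + 1}"
    if module_ids:
        grey_idx = np.flatnonzero(labels == GREY)
        if grey_idx.size:
            mod_rows = {cid: np.flatnonzero(flat == cid) for cid in module_ids}
            mean_d = np.column_stack(
                [d[np.ix_(grey_idx, rows)].mean(axis=1) for rows in mod_rows.values()]
            )
            nearest = np.argmin(mean_d, axis=1)
            for pos, gi in enumerate(grey_idx):
                mj = int(nearest[pos])
                cid = module_ids[mj]
                if mean_d[pos, mj] < branch_height.get(cid, 0.0):
                    labels[gi] = f"module_{mj + 1}"
    assignment = pd.Series(labels, index=pd.Index(dend.labels, name="gene_id"), name="module")
    return label_modules_by_size(assignment)


def label_modules_by_size(assignment: pd.Series) -> pd.Series:
    """Rename non-grey modules by the standard color sequence, largest first.

    Ties in size break by the lexicographically smallest member gene id;
    "grey" is never reassigned.  Relabeling is idempotent.
    """
    sizes = assignment[assignment != GREY].value_counts()
    order = sorted(
        sizes.index,
        key=lambda lab: (-sizes[lab], min(assignment.index[assignment == lab])),
    )
    mapping = {
        lab: (STANDARD_COLORS[i] if i < len(STANDARD_COLORS) else f"module{i + 1}")
        for i, lab in enumerate(order)
    }
    mapping[GREY] = GREY
    return assignment.map(mapping).rename("module")


def merge_close_modules(
    expr: pd.DataFrame, assignment: pd.Series, merge_cut_height: float = 0.15
) -> pd.Series:
    """Merge modules whose eigengenes correlate above 1 - merge_cut_height.

    Eigengene dissimilarity (1 - cor) is clustered by average linkage and cut
    at ``merge_cut_height``; modules in one cluster are combined.
    """
    from .modulestats import module_eigengenes

    modules = sorted(set(assignment) - {GREY})
    if len(modules) < 2:
        return assignment.copy()
    mes, _ = module_eigengenes(expr, assignment, include_grey=False)
    me = mes.loc[modules]
    d = 1.0 - np.corrcoef(me.to_numpy())
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    merges = linkage(d[np.triu_indices_from(d, k=1)], method="average")
    flat = fcluster(merges, t=merge_cut_height, criterion="distance")
    mapping = {}
    for cid in np.unique(flat):
        group = [modules[i] for i in np.flatnonzero(flat == cid)]
        for lab in group:
            mapping[lab] = group[0]
    mapping[GREY] = GREY
    return label_modules_by_size(assignment.map(mapping).rename("module"))


def _partition_blocks(
    expr: pd.DataFrame, max_block_size: int, n_components: int = 30, seed: int = 0
) -> list[np.ndarray]:
    """Pre-partition genes into blocks of <= max_block_size.

    Genes are projected onto the top sample-space principal components and
    k-means-clustered; oversized clusters are split recursively.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = expr.to_numpy(dtype=float)
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    n_comp = min(n_components, x.shape[1] - 1, x.shape[0] - 1)
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    blocks = [np.arange(x.shape[0])]
    done: list[np.ndarray] = []
    while blocks:
        idx = blocks.pop()
        if idx.size <= max_block_size:
            done.append(idx)
            continue
        k = int(np.ceil(idx.size / max_block_size))
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(proj[idx])
        for c in range(k):
            sub = idx[km.labels_ == c]
            if sub.size:
                blocks.append(sub)
    return sorted(done, key=lambda b: b[0])


def blockwise_modules(
    expr: pd.DataFrame,
    beta: float = 12.0,
    min_module_size: int = 30,
    deep_split: int = 2,
    max_block_size: int = 5000,
    merge_cut_height: float = 0.15,
    merge: bool = True,
    cut_height: float | None = None,
    seed: int = 0,
    return_dendrograms: bool = False,
):
    """Detect modules over all genes, blockwise when the gene count is large.

    Runs correlation -> signed adjacency -> TOM -> average-linkage tree ->
    dynamic cut within each block (a single block when ``n_genes <=
    max_block_size``), then optionally merges modules with near-identical
    eigengenes across blocks, and labels modules by size.
    """
    if max_block_size < min_module_size:
        raise ValueError("max_block_size must be >= min_module_size")
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    blocks = (
        [np.arange(expr.shape[0])]
        if expr.shape[0] <= max_block_size
        else _partition_blocks(expr, max_block_size, seed=seed)
    )
    labels = pd.Series(GREY, index=expr.index, name="module")
    dendrograms = []
    offset = 0
    for block in blocks:
        sub = expr.iloc[block]
        cor = correlation_matrix(sub)
        adj = signed_adjacency(cor, beta=beta)
        tom = topological_overlap(adj)
        diss = tom_dissimilarity(tom)
        dend = average_linkage_tree(diss)
        assign = dynamic_tree_cut(
            dend, diss, min_module_size=min_module_size, deep_split=deep_split,
            cut_height=cut_height,
        )
        # make labels unique across blocks before merging
        assign = assign.map(
            lambda lab: lab if lab == GREY else f"b{offset}_{lab}"
        )
        labels.loc[sub.index] = assign
        dendrograms.append(dend)
        offset += 1
    if merge and len(set(labels) - {GREY}) > 1:
        labels = merge_close_modules(expr, labels, merge_cut_height=merge_cut_height)
    else:
        labels = label_modules_by_size(labels)
    if return_dendrograms:
        return labels, dendrograms
    return labels
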