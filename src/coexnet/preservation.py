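"""Permutation-based module preservation between two expression datasets.

Modules defined in a reference dataset (e.g. human) are evaluated in a test
dataset (e.g. mouse, after ortholog mapping) by two families of observed
statistics computed on the module's genes in the test data:

* density family — meanSignedCor (mean off-diagonal correlation), meanAdj
  (mean off-diagonal signed adjacency), propVarExplained (mean squared kME)
  and meanKME (mean signed kME): is the module still a tight cluster?
* connectivity family — cor_kIM, cor_kME, cor_cor: correlations between the
  reference and test versions of intramodular connectivity, eigengene-based
  connectivity, and the vectorized within-module correlation matrix: is the
  module's internal topology the same?

Each statistic is standardized against a permutation null in which a random
gene set of the module's size plays the module in the test data (the
reference-side vectors stay fixed, mirroring test-side label permutation).
Z scores are median-combined within each family; Zsummary is the mean of the
two family medians.  Zsummary > 10 is read as strong evidence of
preservation, Zsummary < 2 as no preservation.  medianRank complements
Zsummary with a module-size-insensitive rank-based composite (rank 1 = most
preserved).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .network import GREY, signed_adjacency
from .modulestats import module_eigengene

__all__ = [
    "DENSITY_STATS",
    "CONNECTIVITY_STATS",
    "observed_stats",
    "permutation_null",
    "summarize_preservation",
    "median_rank",
    "module_preservation",
]

DENSITY_STATS = ("meanSignedCor", "meanAdj", "propVarExplained", "meanKME")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


def _module_vectors(x: np.ndarray, beta: float):
    """(cor matrix, kIM, kME, upper-tri cor) for one module submatrix."""
    cor = np.corrcoef(x)
    np.fill_diagonal(cor, 1.0)
    adj = signed_adjacency(cor, beta=beta)
    kim = adj.sum(axis=1) - 1.0
    expr = pd.DataFrame(x)
    me, _ = module_eigengene(expr, list(expr.index))
    mez = (me.to_numpy() - me.mean()) / me.to_numpy().std(ddof=0)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    kme = np.clip(xz @ mez / x.shape[1], -1.0, 1.0)
    iu = np.triu_indices_from(cor, k=1)
    return cor, adj, kim, kme, cor[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _stats_for_sets(
    ref_x: np.ndarray, test_x: np.ndarray, beta: float
) -> dict[str, float]:
    """All seven preservation statistics for paired ref/test gene sets."""
    _, _, kim_r, kme_r, vec_r = _module_vectors(ref_x, beta)
    cor_t, adj_t, kim_t, kme_t, vec_t = _module_vectors(test_x, beta)
    iu = np.triu_indices_from(cor_t, k=1)
    return {
        "meanSignedCor": float(cor_t[iu].mean()),
        "meanAdj": float(adj_t[iu].mean()),
        "propVarExplained": float((kme_t ** 2).mean()),
        "meanKME": float(kme_t.mean()),
        "cor_kIM": _pearson(kim_r, kim_t),
        "cor_kME": _pearson(kme_r, kme_t),
        "cor_cor": _pearson(vec_r, vec_t),
    }


def observed_stats(
    ref_expr: pd.DataFrame,
    ref_assign: pd.Series,
    test_expr: pd.DataFrame,
    beta: float = 12.0,
    exclude: tuple[str, ...] = (GREY,),
) -> pd.DataFrame:
    """Observed preservation statistics per reference module in the test data.

    Gene ids must be shared (the test matrix already mapped onto reference
    ids).  Modules whose intersection with the test genes has fewer than 3
    genes are skipped with a warning.  Returns a modules x statistics frame
    with a ``size`` column (intersection size used).
    """
    shared = test_expr.index.intersection(ref_expr.index)
    rows = {}
    for lab in sorted(set(ref_assign) - set(exclude)):
        genes = ref_assign.index[ref_assign == lab].intersection(shared)
        if len(genes) < 3:
            warnings.warn(f"module {lab!r}: fewer than 3 shared genes, skipped")
            continue
        s = _stats_for_sets(
            ref_expr.loc[genes].to_numpy(dtype=float),
            test_expr.loc[genes].to_numpy(dtype=float),
            beta,
        )
        s["size"] = len(genes)
        rows[lab] = s
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "module"
    return out


def permutation_null(
    test_expr: pd.DataFrame,
    ref_expr: pd.DataFrame,
    module_genes: list[str],
    n_perm: int = 200,
    seed: int | np.random.SeedSequence = 0,
    beta: float = 12.0,
) -> pd.DataFrame:
    """Null distributions of all statistics for one module's size.

    For each permutation a uniformly random gene set of the module's size is
    treated as the module in the test data, while the reference-side vectors
    of the true module genes stay fixed — the test-side label permutation of
    the cited permutation scheme.  Returns an n_perm x statistics frame;
    reproducible for a fixed seed.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    size = len(module_genes)
    if size > test_expr.shape[0]:
        raise ValueError("module size exceeds number of test genes")
    rng = np.random.default_rng(seed)
    ref_x = ref_expr.loc[module_genes].to_numpy(dtype=float)
    _, _, kim_r, kme_r, vec_r = _module_vectors(ref_x, beta)
    test_x_all = test_expr.to_numpy(dtype=float)
    records = []
    for _ in range(n_perm):
        pick = rng.choice(test_expr.shape[0], size=size, replace=False)
        cor_t, adj_t, kim_t, kme_t, vec_t = _module_vectors(test_x_all[pick], beta)
        iu = np.triu_indices_from(cor_t, k=1)
        records.append(
            {
                "meanSignedCor": float(cor_t[iu].mean()),
                "meanAdj": float(adj_t[iu].mean()),
                "propVarExplained": float((kme_t ** 2).mean()),
                "meanKME": float(kme_t.mean()),
                "cor_kIM": _pearson(kim_r, kim_t),
                "cor_kME": _pearson(kme_r, kme_t),
                "cor_cor": _pearson(vec_r, vec_t),
            }
        )
    return pd.DataFrame.from_records(records)


def summarize_preservation(obs: pd.Series, null: pd.DataFrame) -> dict:
    """Z scores, family composites and permutation p for one module.

    Z_s = (obs_s - mean(null_s)) / sd(null_s); Zdensity/Zconnectivity are the
    medians of their family Zs; Zsummary is their mean.  Permutation p uses
    the add-one estimator p = (1 + #{null >= obs}) / (n_perm + 1) (larger
    statistic = more preserved).  A normal-tail p for Zsummary is reported
    alongside the empirical p.  Zero null sd yields an infinite Z with a
    warning.
    """
    n_perm = null.shape[0]
    out: dict[str, float] = {}
    zs: dict[str, float] = {}
    for stat in ALL_STATS:
        mu = float(null[stat].mean())
        sd = float(null[stat].std(ddof=1))
        o = float(obs[stat])
        if sd == 0:
            warnings.warn(f"zero null sd for {stat}; Z reported as inf")
            z = np.inf if o > mu else (-np.inf if o < mu else 0.0)
        else:
            z = (o - mu) / sd
        zs[stat] = z
        out[f"Z.{stat}"] = z
        out[f"p.{stat}"] = (1 + int((null[stat].to_numpy() >= o).sum())) / (n_perm + 1)
    out["Zdensity"] = float(np.median([zs[s] for s in DENSITY_STATS]))
    out["Zconnectivity"] = float(np.median([zs[s] for s in CONNECTIVITY_STATS]))
    out["Zsummary"] = (out["Zdensity"] + out["Zconnectivity"]) / 2.0
    out["p_normal_Zsummary"] = float(stats.norm.sf(out["Zsummary"]))
    out["nPerm"] = n_perm
    return out


def median_rank(obs: pd.DataFrame) -> pd.Series:
    """Rank-based composite across modules: lower medianRank = more preserved.

    Each statistic column is ranked across modules (rank 1 = most preserved,
    i.e. largest; ties get average ranks) and the median rank over statistics
    is returned per module.
    """
    if obs.shape[0] < 2:
        raise ValueError("median_rank needs at least 2 modules")
    ranks = pd.DataFrame(index=obs.index)
    for stat in ALL_STATS:
        ranks[stat] = stats.rankdata(-obs[stat].to_numpy(), method="average")
    return ranks.median(axis=1).rename("medianRank")


def module_preservation(
    ref_expr: pd.DataFrame,
    ref_assign: pd.Series,
    test_expr: pd.DataFrame,
    beta: float = 12.0,
    n_perm: int = 200,
    seed: int = 0,
    exclude: tuple[str, ...] = (GREY,),
) -> pd.DataFrame:
    """Full preservation analysis of reference modules in a test dataset.

    Returns one row per module: size, observed statistics, per-statistic Z
    and permutation p, Zdensity, Zconnectivity, Zsummary, normal-tail p,
    medianRank, nPerm and seed.  Grey/background genes are excluded from the
    module list but remain part of the permutation sampling pool.
    """
    obs = observed_stats(ref_expr, ref_assign, test_expr, beta=beta, exclude=exclude)
    if obs.empty:
        raise ValueError("no modules with >= 3 shared genes")
    shared = test_expr.index.intersection(ref_expr.index)
    test_shared = test_expr.loc[shared]
    root = np.random.SeedSequence(seed)
    children = root.spawn(obs.shape[0])
    rows = {}
    for child, lab in zip(children, obs.index):
        genes = ref_assign.index[ref_assign == lab].intersection(shared).tolist()
        null = permutation_null(
            test_shared, ref_expr, genes, n_perm=n_perm, seed=child, beta=beta
        )
        rows[lab] = summarize_preservation(obs.loc[lab], null)
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "module"
    result = obs.join(summary)
    if obs.shape[0] >= 2:
        result["medianRank"] = median_rank(obs[list(ALL_STATS)])
    else:
        result["medianRank"] = 1.0
    result["seed"] = seed
    return result
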