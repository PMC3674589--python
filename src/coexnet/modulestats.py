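"""Module eigengenes, module membership (kME) and module-trait association.

A module eigengene (ME) is the first principal component of the module's
gene-standardized expression submatrix — a representative profile that can be
read as a weighted average of the module genes.  Module membership MM(i) =
cor(x_i, ME), also called eigengene-based connectivity, measures how central
gene i is to the module.  Modules are related to traits by correlating each
eigengene with a numeric trait coding (e.g. disease progression 0/1/2) and by
a nonparametric Kruskal-Wallis comparison across groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .network import GREY

__all__ = [
    "module_eigengene",
    "module_eigengenes",
    "module_membership",
    "eigengene_trait_correlation",
    "eigengene_group_test",
    "adjust_pvalues",
    "correlation_pvalue",
    "module_trait_table",
    "plot_eigengene_by_group",
]


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene profile in module")
    return (x - mu) / sd


def module_eigengene(expr: pd.DataFrame, genes: list[str]) -> tuple[pd.Series, float]:
    """First principal component of a module, with variance explained.

    The module submatrix is gene-standardized, its leading right singular
    vector is scaled to unit (ddof=1) variance, and the sign is fixed so the
    eigengene correlates non-negatively with the mean standardized module
    profile.  Returns (eigengene over samples, share of variance explained).
    """
    if len(genes) < 2:
        raise ValueError("module_eigengene needs at least 2 genes")
    if expr.shape[1] < 3:
        raise ValueError("module_eigengene needs at least 3 samples")
    x = _standardize_rows(expr.loc[genes].to_numpy(dtype=float))
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    mean_profile = x.mean(axis=0)
    orient = np.dot(me, mean_profile)
    if orient < 0:
        me = -me
    me = me / me.std(ddof=1)
    return pd.Series(me, index=expr.columns, name="ME"), var_explained


def module_eigengenes(
    expr: pd.DataFrame, assignment: pd.Series, include_grey: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes for every module in an assignment.

    The grey (unassigned background) label is summarized too by default, since
    its eigengene can still track a trait.  Modules with fewer than 2 genes
    are skipped.  Returns (modules x samples eigengene matrix, variance
    explained per module).
    """
    labels = [lab for lab in assignment.unique() if include_grey or lab != GREY]
    rows, varex, kept = [], [], []
    for lab in sorted(labels):
        genes = assignment.index[assignment == lab].tolist()
        if len(genes) < 2:
            continue
        me, ve = module_eigengene(expr, genes)
        rows.append(me.to_numpy())
        varex.append(ve)
        kept.append(lab)
    mes = pd.DataFrame(rows, index=pd.Index(kept, name="module"), columns=expr.columns)
    return mes, pd.Series(varex, index=mes.index, name="var_explained")


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided correlation-test p from the Student t distribution.

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def module_membership(
    expr: pd.DataFrame, mes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MM and its correlation-test p for every gene against every eigengene.

    Returns two genes x modules frames (MM, p.MM); column naming for export
    follows the MM.<color> / p.MM.<color> convention.
    """
    if list(expr.columns) != list(mes.columns):
        raise ValueError("expression and eigengene samples are misaligned")
    n = expr.shape[1]
    x = _standardize_rows(expr.to_numpy(dtype=float))
    e = _standardize_rows(mes.to_numpy(dtype=float))
    mm = np.clip(x @ e.T / n, -1.0, 1.0)
    pmm = correlation_pvalue(mm, n)
    mm_df = pd.DataFrame(mm, index=expr.index, columns=mes.index)
    p_df = pd.DataFrame(pmm, index=expr.index, columns=mes.index)
    return mm_df, p_df


def eigengene_trait_correlation(mes: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Pearson r and two-sided p between each module eigengene and a trait."""
    if list(mes.columns) != list(trait.index):
        raise ValueError("trait is not aligned to the eigengene samples")
    t = trait.to_numpy(dtype=float)
    if np.std(t) == 0:
        raise ValueError("trait is constant")
    n = len(t)
    tz = (t - t.mean()) / t.std(ddof=0)
    e = _standardize_rows(mes.to_numpy(dtype=float))
    r = np.clip(e @ tz / n, -1.0, 1.0)
    return pd.DataFrame({"r": r, "p": correlation_pvalue(r, n)}, index=mes.index)


def eigengene_group_test(me: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across groups, chi-square p.

    All-equal observations return (0, 1) by convention.
    """
    if list(me.index) != list(groups.index):
        raise ValueError("groups are not aligned to the eigengene samples")
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [me[groups == g].to_numpy(dtype=float) for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    values = np.concatenate(samples)
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: 'bonferroni' (min(1, m*p)) or 'bh'."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown method {method!r}; use 'bonferroni' or 'bh'")


def module_trait_table(
    mes: pd.DataFrame, trait: pd.Series, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Per-module trait association table (r, p, Bonferroni p, Kruskal-Wallis).

    Both the correlation test and the nonparametric group test are reported
    side by side; Bonferroni adjusts over the number of modules tested.
    """
    out = eigengene_trait_correlation(mes, trait)
    out["p_bonferroni"] = adjust_pvalues(out["p"].to_numpy(), "bonferroni")
    if groups is not None:
        kh, kp = [], []
        for lab in out.index:
            h, p = eigengene_group_test(mes.loc[lab], groups)
            kh.append(h)
            kp.append(p)
        out["kruskal_H"] = kh
        out["kruskal_p"] = kp
    return out


def plot_eigengene_by_group(me: pd.Series, groups: pd.Series, ax=None):
    """Bar plot of mean eigengene (+/- 1 SE) per group, Kruskal-Wallis p in title."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    levels = list(dict.fromkeys(groups))
    means = [me[groups == g].mean() for g in levels]
    ses = [me[groups == g].sem() for g in levels]
    ax.bar(range(len(levels)), means, yerr=ses, color="tab:gray")
    ax.set_xticks(range(len(levels)), [str(g) for g in levels])
    ax.set_ylabel("module eigengene")
    _, p = eigengene_group_test(me, groups)
    ax.set_title(f"Kruskal-Wallis p = {p:.3g}")
    return ax
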