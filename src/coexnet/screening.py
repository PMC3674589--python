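"""Per-gene screening statistics and cross-species concordant gene selection.

For a binary grouping, each gene gets the point-biserial correlation, a
(Welch by default) two-sample t test, Benjamini-Hochberg q values, group
means and standard errors, a signed fold change, the area under the ROC
curve, and the count of non-missing samples.  For a numeric trait (ordinal
disease progression 0/1/2, or week of age), each gene gets the Pearson
correlation with the trait, the corresponding Student t test, q values and a
concordance-based AUROC analog.

Cross-species concordant genes are those whose correlation with disease
progression exceeds a threshold in the reference species and whose ortholog's
correlation with the disease time course exceeds it in the test species
(both arms, same sign).  Thresholds are applied inclusively so that values
printed at the threshold after rounding are retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .modulestats import adjust_pvalues

__all__ = [
    "screen_binary_trait",
    "screen_numeric_trait",
    "signed_fold_change",
    "auroc",
    "concordance_auroc",
    "select_concordant_genes",
    "sex_confounding_check",
]


def signed_fold_change(mean1, mean2):
    """Signed ratio fold change between two positive group means.

    FC = mean1/mean2 when mean1 > mean2, -mean2/mean1 when mean1 < mean2,
    1 when equal; |FC| >= 1 always.  Non-positive means give NaN (flagged
    missing rather than fabricated).
    """
    m1 = np.asarray(mean1, dtype=float)
    m2 = np.asarray(mean2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(m1 >= m2, m1 / m2, -m2 / m1)
    fc = np.where((m1 > 0) & (m2 > 0), fc, np.nan)
    if np.isscalar(mean1) and np.isscalar(mean2):
        return float(fc)
    return fc


def auroc(values, labels) -> float:
    """Area under the ROC curve by the rank (probability of concordance) form.

    ``labels`` is binary with 1 = first group; ties in ``values`` count 1/2.
    Equivalent to the exhaustive pair-counting estimator.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(v, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def concordance_auroc(values: np.ndarray, trait: np.ndarray) -> float:
    """Concordance (C index) of values against a numeric trait.

    Over pairs with unequal trait values: concordant value pairs count 1,
    value ties count 1/2.  Reduces to :func:`auroc` for a 0/1 trait.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(trait, dtype=float)
    keep = ~np.isnan(v)
    v, t = v[keep], t[keep]
    dv = np.sign(v[:, None] - v[None, :])
    dt = np.sign(t[:, None] - t[None, :])
    iu = np.triu_indices(len(v), k=1)
    dv, dt = dv[iu], dt[iu]
    usable = dt != 0
    if not usable.any():
        raise ValueError("trait is constant")
    agree = (dv[usable] * dt[usable] > 0).sum()
    ties = (dv[usable] == 0).sum()
    return float((agree + 0.5 * ties) / usable.sum())


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = adjust_pvalues(p[ok], "bh")
    return q


def screen_binary_trait(
    expr: pd.DataFrame,
    groups: pd.Series,
    first_group: str | None = None,
    var_equal: bool = False,
) -> pd.DataFrame:
    """Standard two-group differential screen over all genes.

    ``groups`` assigns each sample one of two labels; ``first_group`` names
    the group coded 1 (default: first label encountered).  The t test is
    Welch by default (``var_equal=True`` switches to the pooled-variance
    form).  Constant genes get NaN statistics.  Missing expression values are
    dropped per gene and counted in ``nPresentSamples``.
    """
    groups = groups.loc[list(expr.columns)]
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if first_group is None:
        first_group = levels[0]
    second_group = [g for g in levels if g != first_group][0]
    y = (groups == first_group).to_numpy().astype(float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    x = expr.to_numpy(dtype=float)
    n_genes = x.shape[0]
    cols = {
        k: np.full(n_genes, np.nan)
        for k in (
            "corPearson", "Z", "t.Student", "pvalueStudent", "meanFirstGroup",
            "meanSecondGroup", "SE.FirstGroup", "SE.SecondGroup", "FoldChange",
            "AreaUnderROC",
        )
    }
    n_present = np.zeros(n_genes, dtype=int)
    for i in range(n_genes):
        xi = x[i]
        keep = ~np.isnan(xi)
        n_present[i] = int(keep.sum())
        xi, yi = xi[keep], y[keep]
        a, b = xi[yi == 1], xi[yi == 0]
        if len(a) < 2 or len(b) < 2 or np.std(xi) == 0:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=var_equal)
        cols["t.Student"][i] = t
        cols["pvalueStudent"][i] = p
        cols["corPearson"][i] = np.corrcoef(xi, yi)[0, 1]
        cols["Z"][i] = np.sign(t) * stats.norm.isf(p / 2.0)
        cols["meanFirstGroup"][i] = a.mean()
        cols["meanSecondGroup"][i] = b.mean()
        cols["SE.FirstGroup"][i] = a.std(ddof=1) / np.sqrt(len(a))
        cols["SE.SecondGroup"][i] = b.std(ddof=1) / np.sqrt(len(b))
        cols["FoldChange"][i] = signed_fold_change(a.mean(), b.mean())
        cols["AreaUnderROC"][i] = auroc(xi, yi)
    out = pd.DataFrame(cols, index=expr.index)
    out["q.Student"] = _bh_with_nan(out["pvalueStudent"].to_numpy())
    out["nPresentSamples"] = n_present
    out.attrs["contrast"] = f"{first_group}.vs.{second_group}"
    return out


def screen_numeric_trait(expr: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Correlation screen of every gene against a numeric trait.

    Reports Pearson r, the Student t statistic and two-sided p, BH q, a
    concordance-based AUROC analog and the non-missing sample count.
    """
    trait = trait.loc[list(expr.columns)]
    t_arr = trait.to_numpy(dtype=float)
    if len(t_arr) < 4:
        raise ValueError("need at least 4 samples")
    if np.std(t_arr) == 0:
        raise ValueError("trait is constant")
    x = expr.to_numpy(dtype=float)
    n_genes = x.shape[0]
    cor = np.full(n_genes, np.nan)
    tval = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    area = np.full(n_genes, np.nan)
    n_present = np.zeros(n_genes, dtype=int)
    for i in range(n_genes):
        xi = x[i]
        keep = ~np.isnan(xi)
        n = int(keep.sum())
        n_present[i] = n
        if n < 4 or np.std(xi[keep]) == 0 or np.std(t_arr[keep]) == 0:
            continue
        r = float(np.corrcoef(xi[keep], t_arr[keep])[0, 1])
        cor[i] = r
        tval[i] = r * np.sqrt((n - 2) / max(1.0 - r ** 2, np.finfo(float).tiny))
        pval[i] = 2.0 * stats.t.sf(abs(tval[i]), df=n - 2)
        area[i] = concordance_auroc(xi[keep], t_arr[keep])
    out = pd.DataFrame(
        {
            "corPearson": cor,
            "Z": np.sign(tval) * stats.norm.isf(pval / 2.0),
            "t.Student": tval,
            "pvalueStudent": pval,
            "q.Student": _bh_with_nan(pval),
            "AreaUnderROC": area,
            "nPresentSamples": n_present,
        },
        index=expr.index,
    )
    return out


def select_concordant_genes(
    human_screen: pd.DataFrame,
    mouse_screen: pd.DataFrame,
    orthologs: pd.DataFrame,
    threshold: float = 0.5,
    mm: pd.Series | None = None,
    mm_name: str = "MM.module",
) -> pd.DataFrame:
    """Genes whose progression correlation crosses the threshold in both species.

    "+" rows have both correlations >= ``threshold``; "-" rows have both
    <= ``-threshold`` (inclusive, so values printed at the threshold are
    kept).  ``orthologs`` maps human_gene -> mouse_gene; ``mm`` optionally
    annotates each selected human gene with its membership in a designated
    module.  Rows are sorted by direction then gene id.
    """
    pairs = orthologs[
        orthologs["human_gene"].isin(human_screen.index)
        & orthologs["mouse_gene"].isin(mouse_screen.index)
    ]
    if pairs.empty:
        raise ValueError("no shared genes between the two screening tables")
    ch = human_screen.loc[pairs["human_gene"], "corPearson"].to_numpy()
    ph = human_screen.loc[pairs["human_gene"], "pvalueStudent"].to_numpy()
    cm = mouse_screen.loc[pairs["mouse_gene"], "corPearson"].to_numpy()
    pm = mouse_screen.loc[pairs["mouse_gene"], "pvalueStudent"].to_numpy()
    plus = (ch >= threshold) & (cm >= threshold)
    minus = (ch <= -threshold) & (cm <= -threshold)
    keep = plus | minus
    out = pd.DataFrame(
        {
            "Progression": np.where(plus[keep], "+", "-"),
            "GeneSymbol": pairs["human_gene"].to_numpy()[keep],
            "corHuman": ch[keep],
            "p.Human": ph[keep],
            "corMouse": cm[keep],
            "p.Mouse": pm[keep],
        }
    )
    if mm is not None:
        out[mm_name] = mm.reindex(out["GeneSymbol"]).to_numpy()
    out = out.sort_values(["Progression", "GeneSymbol"]).reset_index(drop=True)
    return out


def sex_confounding_check(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    disease_genes: list[str] | None = None,
    fdr: float = 0.05,
) -> dict:
    """Check that sex does not confound expression among control samples.

    Runs the binary screen with sex as the grouping restricted to controls
    and reports how many genes are sex-associated at the given BH FDR, plus
    the overlap with a supplied disease-associated gene list.
    """
    controls = meta.index[meta["group"] == "control"]
    sub = expr[[s for s in expr.columns if s in set(controls)]]
    sex = meta.loc[list(sub.columns), "sex"]
    if sex.nunique() < 2:
        raise ValueError("both sexes must be present among controls")
    screen = screen_binary_trait(sub, sex, first_group="F")
    hits = screen.index[screen["q.Student"] < fdr].tolist()
    overlap = sorted(set(hits) & set(disease_genes or []))
    return {
        "n_sex_associated": len(hits),
        "sex_associated_genes": hits,
        "n_overlap_with_disease": len(overlap),
        "overlap_genes": overlap,
        "screen": screen,
    }
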