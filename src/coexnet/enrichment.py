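"""Gene-set over-representation analysis for module gene lists.

Module genes (selected by a module-membership cutoff) are tested against a
user-supplied GMT collection with the hypergeometric upper-tail test:
p = P(X >= overlap) where X follows the hypergeometric distribution with the
analysis background as the urn, the set's background hits as successes and
the query list as the draw.  The >=-tail convention is used (the observed
overlap's own pmf term is included).  Bonferroni and Benjamini-Hochberg
corrections are applied over the tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .modulestats import adjust_pvalues

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "select_module_genes_by_mm",
    "hypergeometric_enrichment",
]


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str] = field(default_factory=list)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file: one set per line, name <tab> description <tab> members.

    Duplicate member ids within a set are dropped (first occurrence kept);
    duplicate set names or malformed lines raise with the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(m for m in members if m))
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = GeneSet(name=name, description=desc, genes=genes)
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: dict[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets.values():
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def select_module_genes_by_mm(
    mm: pd.DataFrame, module: str, mm_threshold: float
) -> list[str]:
    """Module gene list by membership cutoff, sorted by descending MM."""
    if module not in mm.columns:
        raise ValueError(f"unknown module {module!r}; have {list(mm.columns)}")
    col = mm[module]
    sel = col[col >= mm_threshold].sort_values(ascending=False)
    return sel.index.tolist()


def hypergeometric_enrichment(
    gene_list: list[str],
    background: list[str],
    sets: dict[str, GeneSet],
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of each set in the list.

    ``gene_list`` must be contained in ``background``.  Sets with zero
    background (population) hits are skipped.  Returns one row per tested
    set: count, population hits, list size, background size, p, Bonferroni
    and BH adjusted p, and the hit gene ids.
    """
    bg = set(background)
    query = set(gene_list)
    missing = sorted(query - bg)
    if missing:
        raise ValueError(f"list genes absent from background: {missing[:10]}")
    n_bg = len(bg)
    n_list = len(query)
    rows = []
    for s in sets.values():
        pop_hits = sum(1 for g in s.genes if g in bg)
        if pop_hits == 0:
            continue
        hits = sorted(query.intersection(s.genes))
        count = len(hits)
        p = float(stats.hypergeom.sf(count - 1, n_bg, pop_hits, n_list))
        rows.append(
            {
                "term": s.name,
                "description": s.description,
                "count": count,
                "population_hits": pop_hits,
                "list_size": n_list,
                "background_size": n_bg,
                "p": min(p, 1.0),
                "hit_genes": ",".join(hits),
            }
        )
    out = pd.DataFrame.from_records(rows)
    if not out.empty:
        out["p_bonferroni"] = adjust_pvalues(out["p"].to_numpy(), "bonferroni")
        out["p_bh"] = adjust_pvalues(out["p"].to_numpy(), "bh")
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
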