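"""Fisher-exact overlap of regulatory categories with gene lists.

Each (category, gene set) pair is tabulated as a 2x2 table within the
background universe and tested one-sided for enrichment (hypergeometric upper
tail). The percent-intersect — overlap relative to the set's background-
restricted size — matches how compartment-list enrichment is usually plotted
(p-value on one axis, percent intersected on the other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .categories import CATEGORY_ORDER
from .difftest import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    """A named gene list (GMT record)."""

    name: str
    description: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name TAB description TAB member ids."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(f"gene set {name!r}: duplicate members deduplicated")
            sets.append(GeneSet(name, description, tuple(unique)))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def hypergeom_tail_p(a: int, background_size: int, set_size: int, category_size: int) -> float:
    """One-sided enrichment p: P(overlap >= a) under fixed margins.

    Overlap of a category of ``category_size`` with a set of ``set_size``
    drawn in a universe of ``background_size``.
    """
    return float(stats.hypergeom.sf(a - 1, background_size, set_size, category_size))


def fisher_overlap(
    category_genes,
    gene_set: GeneSet,
    background,
    upper_case: bool = False,
) -> dict:
    """One-sided Fisher test of a category against a gene set.

    Both lists are intersected with the background before tabulation. The 2x2
    table is (a: category & set, b: category only, c: set only, d: neither);
    p is the hypergeometric upper tail P(overlap >= a). The odds ratio uses a
    0.5 continuity correction only when a cell is zero (annotated).
    """

    def canon(ids):
        return {str(g).upper() for g in ids} if upper_case else {str(g) for g in ids}

    bg = canon(background)
    cat = canon(category_genes) & bg
    if not canon(category_genes) <= bg:
        raise ValueError("category genes must be a subset of the background")
    members = canon(gene_set.members) & bg

    result = {
        "set_name": gene_set.name,
        "set_size_in_background": len(members),
        "category_size": len(cat),
        "a": len(cat & members),
        "b": len(cat - members),
        "c": len(members - cat),
        "d": len(bg - cat - members),
        "testable": bool(cat) and bool(members),
    }
    a, b, c, d = result["a"], result["b"], result["c"], result["d"]
    if not result["testable"]:
        result.update(p=np.nan, odds_ratio=np.nan, continuity=False, pct_intersect=np.nan)
        return result
    result["p"] = hypergeom_tail_p(a, len(bg), a + c, a + b)
    zero_cell = min(a, b, c, d) == 0
    if zero_cell:
        result["odds_ratio"] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        result["odds_ratio"] = (a * d) / (b * c)
    result["continuity"] = zero_cell
    result["pct_intersect"] = 100.0 * a / len(members)
    return result


def enrich_all(
    classification: pd.DataFrame,
    gene_sets: list[GeneSet],
    background=None,
    upper_case: bool = False,
) -> pd.DataFrame:
    """Fisher enrichment of every regulated category against every gene set.

    ``classification`` must carry a ``category`` column indexed by gene id;
    the background defaults to all classified genes. BH FDR is computed across
    all testable rows; rows are ordered by category then p.
    """
    if background is None:
        background = list(classification.index)
    rows = []
    for cat in CATEGORY_ORDER:
        cat_genes = classification.index[classification["category"] == cat.value]
        for gs in gene_sets:
            res = fisher_overlap(cat_genes, gs, background, upper_case=upper_case)
            res["category"] = cat.value
            rows.append(res)
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    ok = table["testable"] & table["p"].notna()
    if ok.any():
        table.loc[ok, "fdr"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    cat_rank = {c.value: i for i, c in enumerate(CATEGORY_ORDER)}
    table = table.sort_values(
        ["category", "p"], key=lambda s: s.map(cat_rank) if s.name == "category" else s
    ).reset_index(drop=True)
    cols = [
        "category", "set_name", "a", "b", "c", "d", "odds_ratio", "continuity",
        "p", "fdr", "pct_intersect", "set_size_in_background", "category_size", "testable",
    ]
    return table[cols]


def scatter_table(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: -log10 p versus percent intersect per row."""
    out = enrichment[["category", "set_name", "pct_intersect"]].copy()
    out["neg_log10_p"] = -np.log10(enrichment["p"].clip(lower=np.finfo(float).tiny))
    return out
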