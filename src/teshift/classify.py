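"""Per-condition translation efficiency and the regulatory classification.

TE is the ratio of normalized footprint abundance to normalized mRNA
abundance. Between two conditions each background gene is assigned to one of
seven classes from three contrasts (mRNA shift, footprint shift, TE shift):
TE-significant genes split into translation-driven classes (footprints moved
too) and buffering classes (footprints held while mRNA moved); TE-constant
genes are up/down-regulated when both assays move concordantly, otherwise
unregulated. Significance means |log2FC| above threshold AND FDR below
threshold, with strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import (
    BUFFERING_CATEGORIES,
    CATEGORY_ORDER,
    TE_SHIFT_CATEGORIES,
    TRANSLATION_DRIVEN_CATEGORIES,
    RegulationCategory,
)
from .containers import ASSAY_RIBO, ASSAY_RNA, CountMatrix
from .difftest import normalized_counts, size_factors


@dataclass
class Thresholds:
    """Significance thresholds: twofold change, FDR 0.01 by default."""

    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.01

    def validate(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not 0 < self.max_fdr <= 1:
            raise ValueError("max_fdr must be in (0, 1]")


def compute_te(
    cm: CountMatrix,
    condition: str,
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene TE in one condition.

    TE = (mean normalized footprint count + pseudocount) /
    (mean normalized mRNA count + pseudocount), replicate means after
    size-factor normalization. The pseudocount keeps TE finite and positive.
    """
    ribo_ids = cm.sample_ids(assay=ASSAY_RIBO, condition=condition)
    rna_ids = cm.sample_ids(assay=ASSAY_RNA, condition=condition)
    if not ribo_ids or not rna_ids:
        raise ValueError(f"condition {condition!r} needs both assays")
    norm = normalized_counts(cm, factors)
    te = (norm[ribo_ids].mean(axis=1) + pseudocount) / (norm[rna_ids].mean(axis=1) + pseudocount)
    te.name = f"te_{condition}"
    return te


def flag_extreme_te(te: pd.Series, hi: float = 3.0, lo: float = 0.33) -> pd.Series:
    """Flag genes with extreme TE: 'high' if TE > hi, 'low' if TE < lo."""
    if (te <= 0).any():
        raise ValueError("TE values must be positive")
    flags = np.where(te > hi, "high", np.where(te < lo, "low", "neither"))
    return pd.Series(flags, index=te.index, name="te_flag")


def _sig(log2fc: float, fdr: float, th: Thresholds) -> bool:
    if np.isnan(log2fc) or np.isnan(fdr):
        return False
    return abs(log2fc) > th.min_abs_log2fc and fdr < th.max_fdr


def classify_gene(
    log2fc_rna: float,
    fdr_rna: float,
    log2fc_ribo: float,
    fdr_ribo: float,
    log2fc_te: float,
    fdr_te: float,
    th: Thresholds | None = None,
) -> RegulationCategory | None:
    """Assign one gene's regulatory class; None when statistics are missing.

    Decision tree: a significant TE shift splits on whether footprints also
    shifted significantly in the same direction (translation-driven) or not
    (buffering); without a TE shift, concordant significant shifts in both
    assays give the TE-constant up/down classes, anything else is unregulated.
    """
    th = th or Thresholds()
    th.validate()
    vals = [log2fc_rna, fdr_rna, log2fc_ribo, fdr_ribo, log2fc_te, fdr_te]
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return None
    if _sig(log2fc_te, fdr_te, th):
        if log2fc_te > 0:
            if _sig(log2fc_ribo, fdr_ribo, th) and log2fc_ribo > 0:
                return RegulationCategory.TRANSLATIONALLY_INDUCED
            return RegulationCategory.RNA_DOWN_TE_UP
        if _sig(log2fc_ribo, fdr_ribo, th) and log2fc_ribo < 0:
            return RegulationCategory.TRANSLATIONALLY_REPRESSED
        return RegulationCategory.RNA_UP_TE_DOWN
    rna_sig = _sig(log2fc_rna, fdr_rna, th)
    ribo_sig = _sig(log2fc_ribo, fdr_ribo, th)
    if rna_sig and ribo_sig and log2fc_rna > 0 and log2fc_ribo > 0:
        return RegulationCategory.UP_TE_CONSTANT
    if rna_sig and ribo_sig and log2fc_rna < 0 and log2fc_ribo < 0:
        return RegulationCategory.DOWN_TE_CONSTANT
    return RegulationCategory.UNREGULATED


def build_gene_stats(
    rna: pd.DataFrame, ribo: pd.DataFrame, te: pd.DataFrame
) -> pd.DataFrame:
    """Join the three contrast tables into one per-gene statistics table."""
    parts = []
    for label, table in (("rna", rna), ("ribo", ribo), ("te", te)):
        sub = table[["log2fc", "se", "p", "fdr"]].rename(
            columns={c: f"{c}_{label}" for c in ("log2fc", "se", "p", "fdr")}
        )
        parts.append(sub)
    return pd.concat(parts, axis=1)


def classify_all(
    stats: pd.DataFrame, th: Thresholds | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every gene of a statistics table.

    Returns the table with a ``category`` column (``unclassifiable`` where a
    statistic is missing, reported separately) and a per-category count
    Series covering the seven classes plus ``unclassifiable``.
    """
    th = th or Thresholds()
    out = stats.copy()
    labels = []
    for row in out.itertuples(index=False):
        cat = classify_gene(
            row.log2fc_rna, row.fdr_rna, row.log2fc_ribo, row.fdr_ribo,
            row.log2fc_te, row.fdr_te, th,
        )
        labels.append(cat.value if cat is not None else "unclassifiable")
    out["category"] = labels
    order = [c.value for c in CATEGORY_ORDER] + ["unclassifiable"]
    counts = out["category"].value_counts().reindex(order, fill_value=0)
    counts.name = "n_genes"
    return out, counts


def category_summary(counts: pd.Series) -> pd.Series:
    """Structural totals: TE-shifted, buffering and translation-driven sums."""
    te_shift = sum(counts.get(c.value, 0) for c in TE_SHIFT_CATEGORIES)
    buffering = sum(counts.get(c.value, 0) for c in BUFFERING_CATEGORIES)
    driven = sum(counts.get(c.value, 0) for c in TRANSLATION_DRIVEN_CATEGORIES)
    te_constant_de = counts.get(RegulationCategory.UP_TE_CONSTANT.value, 0) + counts.get(
        RegulationCategory.DOWN_TE_CONSTANT.value, 0
    )
    return pd.Series(
        {
            "background": int(counts.sum()),
            "te_constant_de": int(te_constant_de),
            "te_shift_total": int(te_shift),
            "buffering": int(buffering),
            "translation_driven": int(driven),
            "unregulated": int(counts.get(RegulationCategory.UNREGULATED.value, 0)),
            "unclassifiable": int(counts.get("unclassifiable", 0)),
        }
    )


def cross_assay_correlation(
    cm: CountMatrix,
    condition: str,
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> float:
    """Pearson correlation of log mRNA vs log footprint abundance.

    Computed on log2 of pseudocount-augmented mean normalized counts across
    the genes of the matrix, within one condition.
    """
    ribo_ids = cm.sample_ids(assay=ASSAY_RIBO, condition=condition)
    rna_ids = cm.sample_ids(assay=ASSAY_RNA, condition=condition)
    if not ribo_ids or not rna_ids:
        raise ValueError(f"condition {condition!r} needs both assays")
    norm = normalized_counts(cm, factors)
    x = np.log2(norm[rna_ids].mean(axis=1) + pseudocount)
    y = np.log2(norm[ribo_ids].mean(axis=1) + pseudocount)
    return float(np.corrcoef(x, y)[0, 1])
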