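"""Background filter, normalization, and the three differential tests.

Filters to genes with at least one read in every library, computes
median-of-ratios size factors, and tests mRNA, footprint and TE shifts for
Neuron vs NPC and ED vs NPC. Also reports the Ribo/RNA cross-assay Pearson
correlation per condition.
"""

from pathlib import Path

import pandas as pd

from teshift import (
    CountMatrix,
    build_gene_stats,
    cross_assay_correlation,
    filter_background,
    size_factors,
    test_assay_shift,
    test_te_shift,
)

DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    cm = CountMatrix.read(DATA / "counts.tsv", DATA / "samples.tsv")
    bg = filter_background(cm)
    print(f"background: {bg.n_genes} of {cm.n_genes} genes "
          "(>= 1 read in all 12 libraries)")
    factors = size_factors(bg)

    lines = []
    for cond in bg.conditions:
        r = cross_assay_correlation(bg, cond, factors=factors)
        lines.append({"condition": cond, "pearson_r": r})
        print(f"Ribo-vs-RNA Pearson r in {cond}: {r:.3f}")
    pd.DataFrame(lines).to_csv(RESULTS / "cross_assay_correlation.tsv", sep="\t",
                               index=False, float_format="%.6g")

    for cond_b in ("Neuron", "ED"):
        stats = build_gene_stats(
            test_assay_shift(bg, "rna", "NPC", cond_b, factors=factors),
            test_assay_shift(bg, "ribo", "NPC", cond_b, factors=factors),
            test_te_shift(bg, "NPC", cond_b, factors=factors),
        )
        stats.to_csv(DATA / f"stats_{cond_b}_vs_NPC.tsv", sep="\t", float_format="%.10g")
        n_sig_te = int(((stats["fdr_te"] < 0.01) & (stats["log2fc_te"].abs() > 1)).sum())
        print(f"{cond_b} vs NPC: {n_sig_te} genes with a significant twofold TE shift")


if __name__ == "__main__":
    main()
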