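"""Simulate the study design: 3 conditions x 2 assays x 2 replicates.

Generates an 8000-gene paired Ribo-seq/RNA-seq count matrix with planted
regulatory categories (effects appear in neurons relative to NPCs; early
differentiation carries no TE changes), two synthetic gene lists for the
enrichment stage, and the ground-truth table. Bulky inputs go to
scratch/data; a small composition summary goes to results/.
"""

from pathlib import Path

from teshift import SimulationConfig, simulate_counts, simulate_gene_lists, write_gmt

SEED = 1
DATA = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    config = SimulationConfig(n_genes=8000, seed=SEED)
    cm, truth = simulate_counts(config)
    cm.write(DATA / "counts.tsv", DATA / "samples.tsv")
    truth.to_csv(DATA / "truth.tsv", sep="\t", float_format="%.6g")

    sets = [
        simulate_gene_lists(truth, enrichment_factor=10.0, seed=SEED + 1, list_size=400),
        simulate_gene_lists(truth, enrichment_factor=1.0, seed=SEED + 2, list_size=400,
                            name="background_draw"),
    ]
    write_gmt(sets, DATA / "gene_sets.gmt")

    composition = truth["category"].value_counts()
    composition.to_csv(RESULTS / "planted_composition.tsv", sep="\t")
    print(f"simulated {cm.n_genes} genes x {len(cm.samples)} libraries "
          f"({', '.join(cm.conditions)})")
    print("planted composition:")
    print(composition.to_string())


if __name__ == "__main__":
    main()
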