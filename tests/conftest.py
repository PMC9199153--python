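import numpy as np
import pandas as pd
import pytest

from teshift import (
    CountMatrix,
    RegulationCategory,
    SimulationConfig,
    build_gene_stats,
    filter_background,
    simulate_counts,
    size_factors,
    test_assay_shift,
    test_te_shift,
)


def make_matrix(counts: np.ndarray, conditions=("A", "B"), n_replicates=1) -> CountMatrix:
    """Wrap a raw array as a CountMatrix with a standard two-assay design."""
    rows = []
    for cond in conditions:
        for assay in ("rna", "ribo"):
            for rep in range(1, n_replicates + 1):
                rows.append((f"{cond}_{assay}_{rep}", assay, cond, str(rep)))
    samples = pd.DataFrame(rows, columns=["sample_id", "assay", "condition", "replicate"])
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples["sample_id"]), samples)


@pytest.fixture(scope="session")
def default_dataset():
    """A moderate simulated dataset under the default study design."""
    cm, truth = simulate_counts(SimulationConfig(n_genes=1500, seed=42))
    return cm, truth


@pytest.fixture(scope="session")
def tested_dataset(default_dataset):
    """Background-filtered dataset with all three contrasts computed."""
    cm, truth = default_dataset
    bg = filter_background(cm)
    factors = size_factors(bg)
    rna = test_assay_shift(bg, "rna", "NPC", "Neuron", factors=factors)
    ribo = test_assay_shift(bg, "ribo", "NPC", "Neuron", factors=factors)
    te = test_te_shift(bg, "NPC", "Neuron", factors=factors)
    stats = build_gene_stats(rna, ribo, te)
    return bg, truth.loc[bg.gene_ids], stats


@pytest.fixture(scope="session")
def powered_dataset():
    """High-power simulation: fixed mean 500, low dispersion, effect 2."""
    lg = float(np.log10(500))
    config = SimulationConfig(
        n_genes=3000, base_mean_log_range=(lg, lg), dispersion=0.01, seed=7
    )
    cm, truth = simulate_counts(config)
    return cm, truth


@pytest.fixture
def null_config():
    return SimulationConfig(
        n_genes=2000,
        dispersion=0.05,
        seed=11,
        category_proportions={RegulationCategory.UNREGULATED: 1.0},
    )
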