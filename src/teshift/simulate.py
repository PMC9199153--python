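"""Synthetic paired Ribo-seq/RNA-seq data with planted ground truth.

The generator emulates the design of a neuronal differentiation time course:
three conditions (NPC, early differentiation, neuron), two assays (RNA-seq and
ribosome footprints) and two replicates each — twelve libraries. Counts are
negative binomial around per-gene means; a chosen fraction of genes carries a
planted regulatory category whose mRNA/footprint log2 fold changes appear in
the final condition only (early differentiation is simulated without TE
changes). Footprint reads are simulated separately as short inserts with
optional 5' template-switch homopolymer artifacts for the trimming stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .categories import CATEGORY_ORDER, RegulationCategory
from .containers import ASSAY_RIBO, ASSAY_RNA, ASSAYS, CountMatrix


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


#: planted (rna, ribo) log2FC signs per category, as multiples of the effect size
CATEGORY_EFFECTS: dict[RegulationCategory, tuple[float, float]] = {
    RegulationCategory.UP_TE_CONSTANT: (1.0, 1.0),
    RegulationCategory.DOWN_TE_CONSTANT: (-1.0, -1.0),
    RegulationCategory.TRANSLATIONALLY_INDUCED: (0.0, 1.0),
    RegulationCategory.TRANSLATIONALLY_REPRESSED: (0.0, -1.0),
    RegulationCategory.RNA_UP_TE_DOWN: (1.0, 0.0),
    RegulationCategory.RNA_DOWN_TE_UP: (-1.0, 0.0),
    RegulationCategory.UNREGULATED: (0.0, 0.0),
}

#: default class mix, mirroring the observed fractions in differentiating neurons
DEFAULT_PROPORTIONS: dict[RegulationCategory, float] = {
    RegulationCategory.UNREGULATED: 0.634,
    RegulationCategory.UP_TE_CONSTANT: 0.076,
    RegulationCategory.DOWN_TE_CONSTANT: 0.076,
    RegulationCategory.RNA_UP_TE_DOWN: 0.061,
    RegulationCategory.RNA_DOWN_TE_UP: 0.061,
    RegulationCategory.TRANSLATIONALLY_INDUCED: 0.046,
    RegulationCategory.TRANSLATIONALLY_REPRESSED: 0.046,
}


@dataclass
class SimulationConfig:
    """Parameters of the count simulator.

    ``base_mean_log_range`` are log10 bounds for the per-gene baseline mean
    (log-uniform). ``dispersion`` is the NB overdispersion alpha in
    ``Var = mu + alpha * mu**2``; zero degenerates to Poisson.
    ``effect_log2fc`` is the planted |log2FC| magnitude, applied in the last
    condition relative to the first; intermediate conditions stay at baseline.
    ``te_baseline_sd`` spreads per-gene baseline log2 TE so that TE varies
    across genes as it does in real libraries.
    """

    n_genes: int = 5000
    conditions: tuple[str, ...] = ("NPC", "ED", "Neuron")
    n_replicates: int = 2
    base_mean_log_range: tuple[float, float] = (0.5, 3.5)
    dispersion: float = 0.05
    depth_factors: tuple[float, ...] | None = None
    category_proportions: dict[RegulationCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_log2fc: float = 2.0
    te_baseline_sd: float = 1.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * len(ASSAYS) * self.n_replicates

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if len(self.conditions) < 2:
            raise ConfigurationError("need at least two conditions")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc must be >= 0")
        if self.te_baseline_sd < 0:
            raise ConfigurationError("te_baseline_sd must be >= 0")
        props = self.category_proportions
        if any(p < 0 for p in props.values()):
            raise ConfigurationError("category proportions must be non-negative")
        unknown = set(props) - set(RegulationCategory)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category proportions must sum to 1")
        if self.depth_factors is not None:
            if len(self.depth_factors) != self.n_samples:
                raise ConfigurationError(
                    f"depth_factors needs {self.n_samples} entries, got {len(self.depth_factors)}"
                )
            if any(d <= 0 for d in self.depth_factors):
                raise ConfigurationError("depth factors must be positive")


def allocate_categories(
    n_genes: int, proportions: dict[RegulationCategory, float]
) -> np.ndarray:
    """Exact largest-remainder allocation of genes to categories.

    Returns an unshuffled array of category labels whose composition realizes
    the requested proportions exactly (up to the integer constraint), so that
    recovery tests can condition on known class sizes.
    """
    cats = [c for c in CATEGORY_ORDER if proportions.get(c, 0.0) > 0]
    quotas = np.array([proportions[c] * n_genes for c in cats])
    counts = np.floor(quotas).astype(int)
    short = n_genes - counts.sum()
    # distribute leftovers by largest fractional part, ties by category order
    order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
    counts[order[:short]] += 1
    return np.repeat([c.value for c in cats], counts)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and the truth table of planted effects.

    Returns the CountMatrix and a per-gene DataFrame with columns
    ``category``, ``log2fc_rna``, ``log2fc_ribo`` (planted last-vs-first
    condition effects), ``base_mean`` and ``baseline_log2_te``. Rows align 1:1
    with the count matrix. Deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    labels = allocate_categories(n, config.category_proportions)
    labels = labels[rng.permutation(n)]
    eff = np.array([CATEGORY_EFFECTS[RegulationCategory(l)] for l in labels])
    lfc_rna = eff[:, 0] * config.effect_log2fc
    lfc_ribo = eff[:, 1] * config.effect_log2fc

    lo, hi = config.base_mean_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, n)
    te0 = rng.normal(0.0, config.te_baseline_sd, n) if config.te_baseline_sd > 0 else np.zeros(n)

    sample_rows = []
    for cond in config.conditions:
        for assay in ASSAYS:
            for rep in range(1, config.n_replicates + 1):
                sample_rows.append((f"{cond}_{assay}_{rep}", assay, cond, str(rep)))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "assay", "condition", "replicate"])
    depths = (
        np.ones(config.n_samples)
        if config.depth_factors is None
        else np.asarray(config.depth_factors, dtype=float)
    )

    last = config.conditions[-1]
    counts = np.empty((n, config.n_samples), dtype=np.int64)
    for j, (_, assay, cond, _) in enumerate(sample_rows):
        te_half = -te0 / 2 if assay == ASSAY_RNA else te0 / 2
        lfc = (lfc_rna if assay == ASSAY_RNA else lfc_ribo) if cond == last else 0.0
        mu = base_mean * np.exp2(te_half + lfc) * depths[j]
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / config.dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))

    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"]), samples)
    truth = pd.DataFrame(
        {
            "category": labels,
            "log2fc_rna": lfc_rna,
            "log2fc_ribo": lfc_ribo,
            "base_mean": base_mean,
            "baseline_log2_te": te0,
        },
        index=gene_ids,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# FASTQ reads with template-switch homopolymer artifacts
# ---------------------------------------------------------------------------


@dataclass
class ArtifactSpec:
    """Description of the planted 5' homopolymer artifact.

    A fraction of reads gets a non-templated poly-C or poly-T run (template
    switching leaves such runs at the cDNA end) prepended to a clean
    footprint-length insert.
    """

    fraction: float = 0.5
    bases: tuple[str, ...] = ("C", "T")
    run_length: tuple[int, int] = (3, 8)
    insert_length: tuple[int, int] = (26, 34)

    def validate(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError("artifact fraction must be in [0, 1]")
        if not set(self.bases) <= set("ACGT"):
            raise ConfigurationError("artifact bases must be nucleotides")
        if self.run_length[0] < 1 or self.run_length[1] < self.run_length[0]:
            raise ConfigurationError("invalid run_length range")
        if self.insert_length[0] < 1 or self.insert_length[1] < self.insert_length[0]:
            raise ConfigurationError("invalid insert_length range")


def simulate_fastq(
    n_reads: int, artifact: ArtifactSpec | None = None, seed: int = 0
) -> list[SeqRecord]:
    """Simulate footprint-like reads; ground truth rides in the description.

    Each record's description carries ``clean=<sequence>`` (the artifact-free
    insert) and ``artifact=<base>:<len>`` or ``artifact=none``, so trimming can
    be scored exactly. Deterministic for a fixed seed.
    """
    if n_reads < 0:
        raise ConfigurationError("n_reads must be >= 0")
    artifact = artifact or ArtifactSpec()
    artifact.validate()
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    records: list[SeqRecord] = []
    for i in range(n_reads):
        length = int(rng.integers(artifact.insert_length[0], artifact.insert_length[1] + 1))
        clean = "".join(alphabet[rng.integers(0, 4, length)])
        if artifact.fraction > 0 and rng.random() < artifact.fraction:
            base = artifact.bases[int(rng.integers(0, len(artifact.bases)))]
            run = int(rng.integers(artifact.run_length[0], artifact.run_length[1] + 1))
            seq = base * run + clean
            tag = f"{base}:{run}"
        else:
            seq = clean
            tag = "none"
        rec = SeqRecord(
            Seq(seq),
            id=f"read{i}",
            description=f"clean={clean} artifact={tag}",
        )
        rec.letter_annotations["phred_quality"] = [
            int(q) for q in rng.integers(30, 41, len(seq))
        ]
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Gene lists for enrichment
# ---------------------------------------------------------------------------


def simulate_gene_lists(
    truth: pd.DataFrame,
    enrichment_factor: float = 10.0,
    seed: int = 0,
    category: RegulationCategory = RegulationCategory.TRANSLATIONALLY_INDUCED,
    list_size: int | None = None,
    name: str | None = None,
):
    """Draw a gene list oversampling one planted category.

    Sampling is without replacement with weight ``enrichment_factor`` on the
    chosen category and 1 elsewhere; ``enrichment_factor`` 1 is a uniform
    background draw (null list). Returns a single
    :class:`~teshift.enrichment.GeneSet`.
    """
    from .enrichment import GeneSet

    if enrichment_factor < 1:
        raise ConfigurationError("enrichment_factor must be >= 1")
    n = len(truth)
    if list_size is None:
        list_size = max(10, n // 20)
    if list_size > n:
        raise ConfigurationError("requested list larger than background")
    rng = np.random.default_rng(seed)
    in_cat = (truth["category"] == category.value).to_numpy()
    weights = np.where(in_cat, float(enrichment_factor), 1.0)
    weights /= weights.sum()
    members = rng.choice(truth.index.to_numpy(), size=list_size, replace=False, p=weights)
    set_name = name or f"{category.value}_x{enrichment_factor:g}"
    return GeneSet(
        name=set_name,
        description=f"synthetic list, factor {enrichment_factor:g} on {category.value}",
        members=tuple(sorted(members)),
    )
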