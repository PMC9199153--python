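"""Core in-memory containers: count matrix plus sample design.

A bulk paired Ribo-seq/RNA-seq experiment is small (a dozen libraries), so the
canonical container is a pandas DataFrame of gene x sample integer counts
together with a sample sheet describing assay, condition and replicate for each
library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ASSAY_RNA = "rna"
ASSAY_RIBO = "ribo"
ASSAYS = (ASSAY_RNA, ASSAY_RIBO)

SAMPLE_SHEET_COLUMNS = ("sample_id", "assay", "condition", "replicate")


@dataclass
class CountMatrix:
    """Gene x sample raw counts with an aligned sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample id, non-negative
        integer counts.
    samples
        Sample sheet with columns ``sample_id``, ``assay`` (``rna``/``ribo``),
        ``condition`` and ``replicate``; one row per counts column, same order.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("counts columns must match sample sheet order")
        bad_assay = set(self.samples["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ValueError(f"unknown assay labels: {sorted(bad_assay)}")
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def sample_ids(self, assay: str | None = None, condition: str | None = None) -> list[str]:
        """Sample ids matching an assay and/or condition, in sheet order."""
        mask = np.ones(len(self.samples), dtype=bool)
        if assay is not None:
            mask &= (self.samples["assay"] == assay).to_numpy()
        if condition is not None:
            mask &= (self.samples["condition"] == condition).to_numpy()
        return list(self.samples.loc[mask, "sample_id"])

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        keep = self.samples[self.samples["sample_id"].isin(sample_ids)]
        return CountMatrix(self.counts[list(keep["sample_id"])], keep.copy())

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples.copy())

    # ---- TSV round trip -------------------------------------------------

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "replicate": str})
        return cls(counts, samples)
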