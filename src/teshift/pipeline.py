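"""End-to-end orchestration: filter, test, classify, enrich, export.

A run is driven by a single YAML config validated up front. Every stage logs
to stderr and a run log; all tables are written as TSV with a fixed float
format so identical inputs give byte-identical outputs, and a JSON manifest
records config hash, input checksums and per-stage row counts so silent input
drift is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    Thresholds,
    build_gene_stats,
    category_summary,
    classify_all,
    compute_te,
    flag_extreme_te,
)
from .containers import ASSAY_RIBO, ASSAY_RNA, CountMatrix
from .difftest import size_factors, test_assay_shift, test_te_shift
from .enrichment import enrich_all, read_gmt, scatter_table
from .preprocess import BackgroundFilter, filter_background

logger = logging.getLogger("teshift")

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end run."""

    counts: str
    samples: str
    outdir: str
    contrasts: list[tuple[str, str]]
    gene_sets: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    background_filter: BackgroundFilter = field(default_factory=BackgroundFilter)
    pseudocount: float = 0.5
    prior_df: float = 20.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {
            "counts", "samples", "outdir", "contrasts", "gene_sets",
            "thresholds", "background_filter", "pseudocount", "prior_df", "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", "unknown-keys", f"unknown config keys: {sorted(unknown)}")
        for key in ("counts", "samples", "outdir", "contrasts"):
            if key not in raw:
                raise PipelineError("config", "missing-key", f"config key {key!r} is required")
        thresholds = Thresholds(**raw.get("thresholds", {}))
        bg = BackgroundFilter(**raw.get("background_filter", {}))
        contrasts = [tuple(pair) for pair in raw["contrasts"]]
        if any(len(pair) != 2 for pair in contrasts):
            raise PipelineError("config", "bad-contrast", "each contrast must be [condA, condB]")
        return cls(
            counts=raw["counts"],
            samples=raw["samples"],
            outdir=raw["outdir"],
            contrasts=contrasts,
            gene_sets=raw.get("gene_sets"),
            thresholds=thresholds,
            background_filter=bg,
            pseudocount=float(raw.get("pseudocount", 0.5)),
            prior_df=float(raw.get("prior_df", 20.0)),
            seed=int(raw.get("seed", 0)),
        )

    def validate_against(self, cm: CountMatrix) -> None:
        conditions = set(cm.samples["condition"])
        for a, b in self.contrasts:
            for cond in (a, b):
                if cond not in conditions:
                    raise PipelineError(
                        "config", "unknown-condition",
                        f"contrast condition {cond!r} not in sample sheet",
                    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index_label: str | None = "gene_id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index=index_label is not None, index_label=index_label)


def export_fc_plane(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (log2FC mRNA, log2FC footprints, category) scatter table."""
    return classified[["log2fc_rna", "log2fc_ribo", "category"]].copy()


def export_te_heatmap(te_by_condition: dict[str, pd.Series]) -> pd.DataFrame:
    """Matrix of log2 TE per gene (rows) per condition (columns, given order)."""
    mat = pd.DataFrame({cond: np.log2(te) for cond, te in te_by_condition.items()})
    mat.columns.name = "condition"
    return mat


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers[:-1]):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)

    manifest: dict = {
        "tool": "teshift",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "contrasts": [list(c) for c in config.contrasts],
                    "thresholds": vars(config.thresholds),
                    "background_filter": {
                        "min_count": config.background_filter.min_count,
                        "scope": config.background_filter.scope,
                    },
                    "pseudocount": config.pseudocount,
                    "prior_df": config.prior_df,
                    "seed": config.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
    }

    try:
        stage = "load"
        cm = CountMatrix.read(config.counts, config.samples)
        manifest["inputs"]["counts"] = _sha256(config.counts)
        manifest["inputs"]["samples"] = _sha256(config.samples)
        config.validate_against(cm)
        manifest["stages"]["load"] = {"genes": cm.n_genes, "samples": len(cm.samples)}
        logger.info("loaded %d genes x %d samples", cm.n_genes, len(cm.samples))

        stage = "filter"
        background = filter_background(cm, config.background_filter)
        manifest["stages"]["filter"] = {"background_genes": background.n_genes}
        logger.info("background: %d genes", background.n_genes)

        stage = "normalize"
        factors = size_factors(background)
        _write(factors.to_frame(), outdir / "size_factors.tsv", index_label="sample_id")
        manifest["stages"]["normalize"] = {"samples": int(factors.size)}

        stage = "te"
        te_by_condition: dict[str, pd.Series] = {}
        for cond in background.conditions:
            te_by_condition[cond] = compute_te(
                background, cond, pseudocount=config.pseudocount, factors=factors
            )
        heatmap = export_te_heatmap(te_by_condition)
        _write(heatmap, outdir / "te_heatmap.tsv")
        manifest["stages"]["te"] = {"genes": len(heatmap), "conditions": heatmap.shape[1]}

        gene_sets = None
        if config.gene_sets:
            stage = "gene_sets"
            gene_sets = read_gmt(config.gene_sets)
            manifest["inputs"]["gene_sets"] = _sha256(config.gene_sets)
            manifest["stages"]["gene_sets"] = {"sets": len(gene_sets)}

        for cond_a, cond_b in config.contrasts:
            tag = f"{cond_b}_vs_{cond_a}"
            stage = f"test:{tag}"
            logger.info("testing %s", tag)
            rna = test_assay_shift(background, ASSAY_RNA, cond_a, cond_b,
                                   factors=factors, prior_df=config.prior_df)
            ribo = test_assay_shift(background, ASSAY_RIBO, cond_a, cond_b,
                                    factors=factors, prior_df=config.prior_df)
            te = test_te_shift(background, cond_a, cond_b,
                               factors=factors, prior_df=config.prior_df)
            stats = build_gene_stats(rna, ribo, te)

            stage = f"classify:{tag}"
            classified, counts = classify_all(stats, config.thresholds)
            classified[f"te_{cond_a}"] = te_by_condition[cond_a]
            classified[f"te_{cond_b}"] = te_by_condition[cond_b]
            classified["te_flag"] = flag_extreme_te(te_by_condition[cond_b])
            _write(classified, outdir / f"classification_{tag}.tsv")
            counts_df = counts.to_frame()
            counts_df.index.name = "category"
            _write(counts_df, outdir / f"category_counts_{tag}.tsv", index_label="category")
            _write(export_fc_plane(classified), outdir / f"fc_plane_{tag}.tsv")
            summary = category_summary(counts)
            manifest["stages"][f"classify:{tag}"] = {k: int(v) for k, v in summary.items()}
            logger.info("%s: %s", tag, summary.to_dict())

            if gene_sets:
                stage = f"enrich:{tag}"
                enr = enrich_all(classified, gene_sets)
                _write(enr, outdir / f"enrichment_{tag}.tsv", index_label=None)
                _write(scatter_table(enr), outdir / f"enrichment_scatter_{tag}.tsv",
                       index_label=None)
                manifest["stages"][f"enrich:{tag}"] = {"rows": len(enr)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, "stage-failed", str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
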