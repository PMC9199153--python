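"""FASTQ template-switch artifact trimming and count background filtering.

Template-switching library preparation prepends non-templated homopolymer
runs (poly-C / poly-T) to the 5' end of reads; :func:`trim_artifacts` strips
them before quantification. :func:`filter_background` implements the
expression filter that defines the analysis background: a gene must have at
least ``min_count`` raw reads in every library of the experiment.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix

_VALID_BASES = set("ACGTN")


@dataclass
class TrimSpec:
    """How to strip homopolymer artifacts.

    ``bases`` are the artifact nucleotides, ``end`` is ``"5p"``, ``"3p"`` or
    ``"both"``, ``min_run`` the shortest run stripped, ``min_len_after`` the
    shortest surviving read.
    """

    bases: tuple[str, ...] = ("C", "T")
    end: str = "5p"
    min_run: int = 3
    min_len_after: int = 20

    def validate(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.min_len_after < 0:
            raise ValueError("min_len_after must be >= 0")
        if not set(self.bases) <= set("ACGT"):
            raise ValueError("artifact bases must be in {A,C,G,T}")
        if self.end not in ("5p", "3p", "both"):
            raise ValueError("end must be '5p', '3p' or 'both'")


def _strip_runs(seq: str, qual: list[int], spec: TrimSpec, from_end: str):
    """Strip successive qualifying homopolymer runs from one end.

    Stripping repeats until the terminal run no longer qualifies, which makes
    the operation idempotent even when runs of the two artifact bases stack.
    """
    while seq:
        base = seq[0] if from_end == "5p" else seq[-1]
        if base not in spec.bases:
            break
        run = 1
        if from_end == "5p":
            while run < len(seq) and seq[run] == base:
                run += 1
        else:
            while run < len(seq) and seq[-run - 1] == base:
                run += 1
        if run < spec.min_run:
            break
        if from_end == "5p":
            seq, qual = seq[run:], qual[run:]
        else:
            seq, qual = seq[:-run], qual[:-run]
    return seq, qual


def trim_artifacts(read: SeqRecord, spec: TrimSpec | None = None) -> tuple[SeqRecord, str]:
    """Trim homopolymer artifact runs off a read.

    Returns ``(record, status)`` with status one of ``"trimmed"``,
    ``"untrimmed"`` or ``"discarded"`` (shorter than ``min_len_after`` after
    trimming). Reads with non-ACGTN characters are passed through untrimmed
    with a warning.
    """
    spec = spec or TrimSpec()
    spec.validate()
    seq = str(read.seq).upper()
    if set(seq) - _VALID_BASES:
        warnings.warn(f"read {read.id}: non-ACGTN characters, passed through untrimmed")
        return read, "untrimmed"
    qual = list(read.letter_annotations.get("phred_quality", [40] * len(seq)))

    new_seq, new_qual = seq, qual
    if spec.end in ("5p", "both"):
        new_seq, new_qual = _strip_runs(new_seq, new_qual, spec, "5p")
    if spec.end in ("3p", "both"):
        new_seq, new_qual = _strip_runs(new_seq, new_qual, spec, "3p")

    if new_seq == seq:
        out = read
        status = "untrimmed"
    else:
        out = SeqRecord(read.seq.__class__(new_seq), id=read.id, description=read.description)
        out.letter_annotations["phred_quality"] = new_qual
        status = "trimmed"
    if len(new_seq) < spec.min_len_after:
        status = "discarded"
    return out, status


def _open_maybe_gzip(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def trim_fastq(
    in_path: str | Path, out_path: str | Path, spec: TrimSpec | None = None
) -> dict[str, int]:
    """Trim a FASTQ file (gzip-transparent); returns a summary of counts."""
    spec = spec or TrimSpec()
    summary = {"reads_in": 0, "trimmed": 0, "untrimmed": 0, "discarded": 0}
    with _open_maybe_gzip(in_path, "r") as fin, _open_maybe_gzip(out_path, "w") as fout:
        for rec in SeqIO.parse(fin, "fastq"):
            summary["reads_in"] += 1
            out, status = trim_artifacts(rec, spec)
            summary[status] += 1
            if status != "discarded":
                SeqIO.write(out, fout, "fastq")
    return summary


def trim_records(
    records: Iterable[SeqRecord], spec: TrimSpec | None = None
) -> tuple[list[SeqRecord], dict[str, int]]:
    """In-memory counterpart of :func:`trim_fastq`; discarded reads dropped."""
    spec = spec or TrimSpec()
    kept: list[SeqRecord] = []
    summary = {"reads_in": 0, "trimmed": 0, "untrimmed": 0, "discarded": 0}
    for rec in records:
        summary["reads_in"] += 1
        out, status = trim_artifacts(rec, spec)
        summary[status] += 1
        if status != "discarded":
            kept.append(out)
    return kept, summary


# ---------------------------------------------------------------------------
# Background filter
# ---------------------------------------------------------------------------


@dataclass
class BackgroundFilter:
    """Expression filter defining the background gene universe.

    A gene is kept when its raw count is at least ``min_count`` in every
    in-scope sample (default: all samples of the experiment).
    """

    min_count: int = 1
    scope: tuple[str, ...] | None = None  # sample ids; None = every sample

    def validate(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")


def filter_background(
    counts: CountMatrix, background_filter: BackgroundFilter | None = None
) -> CountMatrix:
    """Restrict a count matrix to its background genes, preserving row order."""
    background_filter = background_filter or BackgroundFilter()
    background_filter.validate()
    sample_ids = (
        list(background_filter.scope)
        if background_filter.scope is not None
        else list(counts.counts.columns)
    )
    if not sample_ids:
        raise ValueError("background filter needs at least one sample in scope")
    missing = set(sample_ids) - set(counts.counts.columns)
    if missing:
        raise ValueError(f"scope samples not in matrix: {sorted(missing)}")
    keep = (counts.counts[sample_ids] >= background_filter.min_count).all(axis=1)
    return CountMatrix(counts.counts.loc[keep].copy(), counts.samples.copy())
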