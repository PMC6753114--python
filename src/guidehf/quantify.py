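"""Per-guide indel quantification from pooled guide-target amplicon reads.

Pipeline (per read): quality masking → exact scaffold match → whole-read N
budget → N-free barcode and target → exact-barcode demultiplexing. Reads from
the unedited plasmid library define a per-guide catalog of synthesis/PCR
error sequences; in the edited library those sequences are removed before
anything is counted, the remaining reads that differ from the designed target
are edited, and

    indel frequency = edited reads / total reads (after error removal).

A guide is valid when its post-removal read count exceeds ``min_reads``
(default 100). Rejected reads are tallied in a QC report, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import LibraryManifest, iter_fastq

__all__ = [
    "ProcessedRead",
    "ErrorCatalog",
    "IndelTable",
    "preprocess_read",
    "demultiplex",
    "build_error_catalog",
    "compute_indel_table",
    "replicate_correlation",
    "quantify_screen",
]

STATUSES = ("ok", "no_scaffold", "too_many_N", "N_in_key_regions", "unmatched_barcode")
MAX_N = 4  # reads must contain fewer than this many masked bases


@dataclass
class ProcessedRead:
    """One read after masking, scaffold anchoring and the filter cascade."""

    read_id: str
    status: str
    barcode: str = ""
    target_seq: str = ""
    n_count: int = 0
    guide_match: str | None = None


def _mask_low_quality(seq: str, qual: str, threshold: int) -> str:
    cutoff = chr(33 + threshold)
    if min(qual) >= cutoff:
        return seq
    return "".join(
        "N" if q < cutoff else b for b, q in zip(seq, qual)
    )


def preprocess_read(
    read: tuple[str, str, str],
    scaffold: str,
    quality_threshold: int = 10,
) -> ProcessedRead:
    """Mask low-quality bases and locate barcode/target around the scaffold.

    Bases below ``quality_threshold`` become N. The read must contain the
    scaffold exactly (a masked base inside the scaffold window breaks the
    exact match, so the anchor is automatically N-free). The 20 nt
    immediately 5' of the scaffold are the barcode; everything 3' of it is
    the target region. Rejections are statuses, not exceptions.
    """
    read_id, seq, qual = read
    if not seq:
        raise ValueError(f"read {read_id!r} has an empty sequence")
    masked = _mask_low_quality(seq, qual, quality_threshold)
    idx = masked.find(scaffold)
    if idx < 20:  # absent, or too close to the 5' end to carry a barcode
        return ProcessedRead(read_id, "no_scaffold")
    n_count = masked.count("N")
    if n_count >= MAX_N:
        return ProcessedRead(read_id, "too_many_N", n_count=n_count)
    barcode = masked[idx - 20 : idx]
    target = masked[idx + len(scaffold) :]
    if "N" in barcode or "N" in target:
        return ProcessedRead(read_id, "N_in_key_regions", n_count=n_count)
    return ProcessedRead(read_id, "ok", barcode, target, n_count)


def demultiplex(
    reads: Iterable[ProcessedRead],
    manifest: LibraryManifest,
    qc: dict[str, int] | None = None,
) -> dict[str, list[str]]:
    """Group ok reads by exact spacer (barcode) match.

    Reads whose barcode matches no manifest spacer get status
    ``unmatched_barcode``. ``qc``, when given, accumulates status counts.
    """
    by_spacer = {r.spacer: r.guide_id for r in manifest}
    groups: dict[str, list[str]] = {}
    for read in reads:
        if read.status == "ok":
            gid = by_spacer.get(read.barcode)
            if gid is None:
                read.status = "unmatched_barcode"
            else:
                read.guide_match = gid
                groups.setdefault(gid, []).append(read.target_seq)
        if qc is not None:
            qc[read.status] = qc.get(read.status, 0) + 1
    return groups


@dataclass(frozen=True)
class ErrorCatalog:
    """Per-guide target variants attributed to oligo synthesis / PCR error."""

    errors: Mapping[str, frozenset[str]]

    def __getitem__(self, guide_id: str) -> frozenset[str]:
        return self.errors.get(guide_id, frozenset())

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self.errors.values())


def build_error_catalog(
    plasmid_groups: Mapping[str, list[str]], manifest: LibraryManifest
) -> ErrorCatalog:
    """Record every plasmid-library target differing from its design.

    A plasmid read carrying any mutation relative to the designed target is a
    synthesis/PCR error; the designed target never enters its own error set.
    """
    by_id = manifest.by_id
    errors: dict[str, frozenset[str]] = {}
    for gid, targets in plasmid_groups.items():
        if gid not in by_id:
            raise LookupError(f"guide {gid!r} not in manifest")
        design = by_id[gid].target_context
        variants = frozenset(t for t in targets if t != design)
        if variants:
            errors[gid] = variants
    return ErrorCatalog(errors)


@dataclass
class IndelTable:
    """Per-guide read counts and indel frequencies."""

    frame: pd.DataFrame  # columns: guide_id, total_reads, edited_reads,
    #                      indel_frequency, valid

    COLUMNS = ("guide_id", "total_reads", "edited_reads", "indel_frequency", "valid")

    def __post_init__(self) -> None:
        f = self.frame
        if tuple(f.columns) != self.COLUMNS:
            raise ValueError(f"IndelTable columns must be {self.COLUMNS}")
        if (f.edited_reads > f.total_reads).any():
            raise ValueError("edited_reads cannot exceed total_reads")

    def __len__(self) -> int:
        return len(self.frame)

    def frequencies(self, valid_only: bool = True) -> pd.Series:
        f = self.frame[self.frame.valid] if valid_only else self.frame
        return f.set_index("guide_id").indel_frequency

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IndelTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        frame["valid"] = frame["valid"].astype(bool)
        return cls(frame)


def compute_indel_table(
    edited_groups: Mapping[str, list[str]],
    catalog: ErrorCatalog,
    manifest: LibraryManifest,
    min_reads: int = 100,
) -> IndelTable:
    """Apply error removal then classify the remainder, per guide.

    Every manifest guide gets a row; guides with no post-removal reads report
    frequency 0.0 and valid=False.
    """
    rows = []
    for rec in manifest:
        targets = edited_groups.get(rec.guide_id, [])
        errs = catalog[rec.guide_id]
        kept = [t for t in targets if t not in errs]
        total = len(kept)
        edited = sum(1 for t in kept if t != rec.target_context)
        freq = edited / total if total > 0 else 0.0
        rows.append((rec.guide_id, total, edited, freq, total > min_reads))
    frame = pd.DataFrame(rows, columns=list(IndelTable.COLUMNS))
    return IndelTable(frame)


def replicate_correlation(
    table_a: IndelTable, table_b: IndelTable, method: str = "pearson"
) -> float:
    """Correlation of indel frequency over the shared valid guides."""
    fa = table_a.frequencies()
    fb = table_b.frequencies()
    shared = fa.index.intersection(fb.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >=3 shared valid guides, found {len(shared)}"
        )
    x, y = fa.loc[shared].to_numpy(), fb.loc[shared].to_numpy()
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def quantify_screen(
    manifest: LibraryManifest,
    plasmid_fastq: str | Path,
    edited_fastq: str | Path,
    min_reads: int = 100,
    quality_threshold: int = 10,
) -> tuple[IndelTable, dict]:
    """End-to-end quantification from FASTQ pair to indel table + QC report."""
    qc: dict = {"plasmid": {}, "edited": {}}

    def _stream(path):
        for rec in iter_fastq(path):
            yield preprocess_read(rec, manifest.scaffold, quality_threshold)

    plasmid_groups = demultiplex(_stream(plasmid_fastq), manifest, qc["plasmid"])
    catalog = build_error_catalog(plasmid_groups, manifest)
    edited_groups = demultiplex(_stream(edited_fastq), manifest, qc["edited"])
    table = compute_indel_table(edited_groups, catalog, manifest, min_reads)
    qc["error_catalog_sequences"] = catalog.n_sequences
    qc["guides_valid"] = int(table.frame.valid.sum())
    qc["guides_total"] = len(table)
    return table, qc
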