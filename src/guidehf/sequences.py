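"""Library manifests, FASTQ handling and the sequence conventions shared package-wide.

Coordinates are 0-based half-open internally; positions reported to users are
1..20 with position 20 immediately PAM-proximal.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SGRNA_SCAFFOLD",
    "GuideRecord",
    "LibraryManifest",
    "ReadBatch",
    "ManifestError",
    "FastqError",
    "reverse_complement",
    "read_manifest",
    "write_manifest",
    "parse_fastq",
    "iter_fastq",
    "write_fastq",
]

#: Constant 3' scaffold of the single-guide RNA, written as DNA. Used as the
#: anchor when parsing amplicon reads (barcode sits immediately 5' of it, the
#: synthesized target region immediately 3').
SGRNA_SCAFFOLD = (
    "gttttagagctagaaatagcaagttaaaataaggctagtccgttatcaacttgaaaaagtggcaccgagtcggtgcttttt"
).upper()

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Printed size of the designed library: four top-ranked guides per coding gene
#: plus up to three per microRNA.
DESIGN_N_CODING = 75_312
DESIGN_N_MIRNA = 4_951


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ManifestError(ValueError):
    """Raised for malformed or inconsistent library manifests."""


class FastqError(ValueError):
    """Raised for malformed FASTQ input."""


_VALID_SOURCES = ("coding", "microRNA", "synthetic")


@dataclass(frozen=True)
class GuideRecord:
    """One designed guide: 20-nt spacer plus its synthesized target context.

    ``target_context`` holds spacer + NGG PAM (optionally flanked) in the
    orientation where spacer+PAM read left to right.
    """

    guide_id: str
    gene: str
    spacer: str
    target_context: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.spacer) != 20 or set(self.spacer) - set("ACGT"):
            raise ManifestError(
                f"guide {self.guide_id!r}: spacer must be 20 nt over ACGT, "
                f"got {self.spacer!r}"
            )
        if self.source not in _VALID_SOURCES:
            raise ManifestError(
                f"guide {self.guide_id!r}: unknown source {self.source!r}"
            )
        off = self.spacer_offset
        if self.target_context.count(self.spacer) != 1:
            raise ManifestError(
                f"guide {self.guide_id!r}: spacer must occur exactly once in "
                "target_context"
            )
        pam = self.target_context[off + 20 : off + 23]
        if len(pam) != 3 or pam[1:] != "GG" or pam[0] not in "ACGT":
            raise ManifestError(
                f"guide {self.guide_id!r}: 3 nt after spacer must be an NGG PAM, "
                f"got {pam!r}"
            )
        if self.source in ("coding", "microRNA") and self.spacer[0] not in "AG":
            raise ManifestError(
                f"guide {self.guide_id!r}: library design requires an A/G first "
                f"base for {self.source} guides"
            )

    @property
    def spacer_offset(self) -> int:
        """0-based offset of the spacer within target_context."""
        off = self.target_context.find(self.spacer)
        if off < 0:
            raise ManifestError(
                f"guide {self.guide_id!r}: spacer absent from target_context"
            )
        return off

    @property
    def pam(self) -> str:
        off = self.spacer_offset
        return self.target_context[off + 20 : off + 23]


@dataclass
class LibraryManifest:
    """The designed guide library. Spacers double as demultiplexing barcodes."""

    records: list[GuideRecord]
    scaffold: str = SGRNA_SCAFFOLD

    def __post_init__(self) -> None:
        ids = [r.guide_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate guide_id values: {dup[:5]}")
        spacers = [r.spacer for r in self.records]
        if len(set(spacers)) != len(spacers):
            seen: set[str] = set()
            dup = sorted({s for s in spacers if s in seen or seen.add(s)})
            raise ManifestError(
                "duplicate spacers (spacers are demultiplexing barcodes): "
                f"{dup[:3]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GuideRecord]:
        return iter(self.records)

    @property
    def by_spacer(self) -> dict[str, GuideRecord]:
        return {r.spacer: r for r in self.records}

    @property
    def by_id(self) -> dict[str, GuideRecord]:
        return {r.guide_id: r for r in self.records}


_MANIFEST_COLUMNS = ("guide_id", "gene", "spacer", "target_context", "source")


def read_manifest(path: str | Path) -> LibraryManifest:
    """Read a tab-separated guide library manifest.

    Expects a header line ``guide_id  gene  spacer  target_context  source``.
    Raises :class:`ManifestError` naming the offending line on malformed rows
    and on duplicate spacers.
    """
    path = Path(path)
    records: list[GuideRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _MANIFEST_COLUMNS:
            raise ManifestError(
                f"{path}: expected header {list(_MANIFEST_COLUMNS)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_MANIFEST_COLUMNS):
                raise ManifestError(
                    f"{path}:{lineno}: expected {len(_MANIFEST_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                records.append(GuideRecord(*parts))
            except ManifestError as exc:
                raise ManifestError(f"{path}:{lineno}: {exc}") from None
    return LibraryManifest(records)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for r in manifest.records:
            fh.write(
                f"{r.guide_id}\t{r.gene}\t{r.spacer}\t{r.target_context}\t{r.source}\n"
            )


@dataclass
class ReadBatch:
    """Materialized sequencing reads: (read_id, sequence, quality string).

    Qualities are kept Phred+33 encoded; :meth:`phred` decodes one record.
    """

    reads: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(self.reads)

    @staticmethod
    def decode_quality(qual: str) -> list[int]:
        return [ord(c) - 33 for c in qual]

    def phred(self, i: int) -> list[int]:
        return self.decode_quality(self.reads[i][2])


def _open_text(path: Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream 4-line FASTQ records as (read_id, sequence, quality string)."""
    path = Path(path)
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus:
                raise FastqError(f"{path}: truncated FASTQ record {head!r}")
            if not head.startswith("@") or not plus.startswith("+"):
                raise FastqError(f"{path}: malformed FASTQ record {head!r}")
            if len(seq) != len(qual):
                raise FastqError(
                    f"{path}: sequence/quality length mismatch for {head!r}"
                )
            yield head[1:].split()[0], seq, qual


def parse_fastq(path: str | Path) -> ReadBatch:
    """Read an entire (plain or gzipped) FASTQ file into memory."""
    return ReadBatch(list(iter_fastq(path)))


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path, gzipped: bool | None = None
) -> None:
    path = Path(path)
    if gzipped is None:
        gzipped = str(path).endswith(".gz")
    opener = gzip.open if gzipped else open
    with opener(path, "wt") as fh:
        chunk: list[str] = []
        for rid, seq, qual in records:
            chunk.append(f"@{rid}\n{seq}\n+\n{qual}\n")
            if len(chunk) >= 10_000:
                fh.write("".join(chunk))
                chunk.clear()
        fh.write("".join(chunk))
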