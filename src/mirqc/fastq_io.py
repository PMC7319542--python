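"""Streaming FASTQ/FASTA input-output and Phred quality decoding.

All sequencing input is single-end FASTQ (plain or gzip) with Phred+33
quality encoding, the de-facto standard for post-2011 Illumina small-RNA
libraries.  Reference collections (genome, miRNA, rRNA, ...) are plain
FASTA; RNA alphabets are normalised to DNA (U -> T) on load.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33
MAX_PHRED = 93

#: Canonical reference-set names used throughout the pipeline.
REFERENCE_SET_NAMES = (
    "genome",
    "mirna_mature",
    "mirna_hairpin",
    "rrna",
    "trna",
    "other_ncrna",
    "mrna",
    "contaminant_bacterial",
    "contaminant_viral",
)


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records; message names the record index."""


class FastaFormatError(ValueError):
    """Raised for malformed or duplicated FASTA records."""


@dataclass
class ReadRecord:
    """One sequencing read: identifier, sequence and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def decode_qualities(quality_string: str) -> list[int]:
    """Decode a Phred+33 quality string to integer scores."""
    scores = [ord(c) - PHRED_OFFSET for c in quality_string]
    for q in scores:
        if q < 0 or q > MAX_PHRED:
            raise FastqFormatError(
                f"quality character outside Phred+33 range: score {q}"
            )
    return scores


def encode_qualities(scores: Iterable[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in scores)


def read_fastq(path: str | Path, limit: int | None = None) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped FASTQ file.

    Records are yielded in file order; iteration stops after ``limit``
    records when given.  A malformed record (sequence/quality length
    mismatch, missing '@' header) raises :class:`FastqFormatError` naming
    the 0-based record index.
    """
    count = 0
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            if limit is not None and count >= limit:
                return
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(f"record {count}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"record {count}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            read_id = title.split()[0] if title else f"read{count}"
            yield ReadRecord(read_id, seq.upper(), decode_qualities(qual))
            count += 1
    if count == 0:
        logger.warning("FASTQ file %s contained no reads", path)


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write ReadRecords as 4-line FASTQ (gzipped if path ends in .gz)."""
    n = 0
    path = Path(path)
    handle: IO[str]
    if path.suffix == ".gz":
        handle = gzip.open(path, "wt")
    else:
        handle = open(path, "wt")
    with handle:
        for rec in records:
            handle.write(
                f"@{rec.read_id}\n{rec.sequence}\n+\n"
                f"{encode_qualities(rec.qualities)}\n"
            )
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an id -> sequence map.

    Ids are the header token up to the first whitespace.  Sequences are
    uppercased with U converted to T.  Duplicate ids and empty sequences
    are hard errors.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise FastaFormatError(f"empty sequence for id {rec.id!r}")
            if rec.id in entries:
                raise FastaFormatError(f"duplicate FASTA id {rec.id!r}")
            entries[rec.id] = seq
    return entries


def write_fasta(entries: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as handle:
        for rid, seq in entries.items():
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


@dataclass
class ReferenceSet:
    """A named collection of reference sequences (genome, miRNA, ...)."""

    name: str
    entries: dict[str, str]

    @classmethod
    def from_fasta(cls, name: str, path: str | Path) -> "ReferenceSet":
        if name not in REFERENCE_SET_NAMES:
            raise ValueError(f"unknown reference set name {name!r}")
        return cls(name, read_fasta(path))
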