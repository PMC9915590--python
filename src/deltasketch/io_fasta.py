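"""FASTA input handling.

Genomes arrive as plain or gzip-compressed FASTA files, possibly
multi-record (one record per contig/chromosome). Records are kept
separate so that downstream k-mer extraction never crosses a contig
junction, and every genome carries a content digest that identifies its
sequence regardless of line wrapping or compression.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence

__all__ = [
    "SequenceRecord",
    "GenomeInput",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "genome_from_records",
]

_GZIP_MAGIC = b"\x1f\x8b"


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: header token and uppercased sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class GenomeInput:
    """A genome: an ordered list of records plus a content digest.

    The digest is a BLAKE2b-256 checksum of ``id + "\\n" + seq`` over all
    records in file order, so it depends only on sequence content, never
    on line wrapping or compression.
    """

    records: tuple[SequenceRecord, ...]
    digest: str
    path: Optional[Path] = None
    label: str = field(default="", compare=False)

    @property
    def max_record_length(self) -> int:
        return max(len(r.seq) for r in self.records)

    @property
    def total_length(self) -> int:
        return sum(len(r.seq) for r in self.records)


def _content_digest(records: Iterable[SequenceRecord]) -> str:
    h = hashlib.blake2b(digest_size=32)
    for rec in records:
        h.update(rec.id.encode())
        h.update(b"\n")
        h.update(rec.seq.encode())
    return h.hexdigest()


def genome_from_records(
    records: Sequence[SequenceRecord],
    path: Optional[Path] = None,
    label: str = "",
) -> GenomeInput:
    """Assemble a :class:`GenomeInput`, enforcing unique record ids."""
    if not records:
        raise FastaParseError("no records")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
    if not label and path is not None:
        label = _label_from_path(path)
    return GenomeInput(
        records=tuple(records),
        digest=_content_digest(records),
        path=path,
        label=label,
    )


def _label_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".fasta", ".fa", ".fna"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name or path.name


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_fasta(handle: IO[str]) -> list[SequenceRecord]:
    # A line-tracking parser so malformed input can be reported with its
    # line number (which streaming library parsers silently swallow).
    records: list[SequenceRecord] = []
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"line {header_line}: record {header!r} has an empty sequence"
            )
        records.append(SequenceRecord(id=header, seq=seq.upper()))

    lineno = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            header = line[1:].split()[0] if len(line) > 1 else ""
            if not header:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError(
                    f"line {lineno}: expected '>' header before sequence data"
                )
            chunks.append(line)
    if header is None:
        raise FastaParseError("line 1: no FASTA records found")
    flush(lineno + 1)
    return records


def read_fasta(path: str | Path) -> GenomeInput:
    """Read a FASTA file (plain or gzipped, detected by magic bytes).

    Sequences are uppercased; record boundaries are preserved. Raises
    :class:`FastaParseError` on malformed input or duplicate record ids.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as handle:
        records = _parse_fasta(handle)
    return genome_from_records(records, path=path)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as (optionally gzipped, by '.gz' suffix) FASTA."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:  # type: ignore[operator]
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                out.write(rec.seq[i : i + wrap] + "\n")
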