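"""FASTA with FAI indexing and region fetch; FASTQ with Phred+33 quality.

The FAI index records, per sequence: name (header token up to the first
whitespace), length in bases, byte offset of the first sequence byte,
bases per full line, and bytes per full line including the terminator —
enough to compute any base's file position and fetch a region without
reading the whole file.  CRLF files are supported (the 2-byte terminator
is captured by linewidth).  Lowercase (soft-masked) bases survive fetch.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from .errors import FormatError, LookupMiss, ParseError, RangeError


@dataclass(frozen=True)
class FaiRecord:
    name: str
    length: int
    offset: int
    linebases: int
    linewidth: int

    def to_line(self) -> str:
        return (
            f"{self.name}\t{self.length}\t{self.offset}"
            f"\t{self.linebases}\t{self.linewidth}"
        )


@dataclass(frozen=True)
class FastqRecord:
    name: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ParseError(
                f"record {self.name!r}: seq length {len(self.seq)}"
                f" != qual length {len(self.qual)}"
            )

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


# ---------------------------------------------------------------------------
# FAI
# ---------------------------------------------------------------------------

def build_fai(fasta_path) -> list[FaiRecord]:
    """Index a FASTA file; all full lines of a record must share a width."""
    records: list[FaiRecord] = []
    seen: set[str] = set()
    name = None
    length = 0
    offset = 0
    linebases = linewidth = 0
    pending_short = False  # a shorter-than-first line must be the last

    def finish() -> None:
        nonlocal name
        if name is None:
            return
        if name in seen:
            raise FormatError(f"duplicate sequence name {name!r}")
        seen.add(name)
        records.append(FaiRecord(name, length, offset, linebases, linewidth))
        name = None

    with open(fasta_path, "rb") as fh:
        pos = 0
        for raw in fh:
            line_start = pos
            pos += len(raw)
            stripped = raw.rstrip(b"\r\n")
            if stripped.startswith(b">"):
                finish()
                name = stripped[1:].split(None, 1)[0].decode("ascii") if len(stripped) > 1 else ""
                if not name:
                    raise FormatError("FASTA header with empty name")
                length = 0
                linebases = linewidth = 0
                offset = pos
                pending_short = False
                continue
            if name is None:
                if stripped:
                    raise FormatError("sequence data before any FASTA header")
                continue
            if not stripped:
                pending_short = True
                continue
            if pending_short:
                raise FormatError(
                    f"ragged line widths inside sequence {name!r}"
                )
            if linebases == 0:
                linebases = len(stripped)
                linewidth = len(raw)
                offset = line_start
            elif len(stripped) != linebases:
                if len(stripped) > linebases:
                    raise FormatError(
                        f"ragged line widths inside sequence {name!r}"
                    )
                pending_short = True
            length += len(stripped)
        finish()
    return records


def write_fai(records: Iterable[FaiRecord], sink: IO[str] | str | os.PathLike) -> None:
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w") if own else sink
    try:
        for rec in records:
            fh.write(rec.to_line() + "\n")
    finally:
        if own:
            fh.close()


def read_fai(source: IO[str] | str | os.PathLike) -> list[FaiRecord]:
    own = isinstance(source, (str, os.PathLike))
    fh = open(source, "r") if own else source
    try:
        out = []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"FAI line with {len(fields)} columns")
            out.append(FaiRecord(fields[0], *(int(x) for x in fields[1:])))
        return out
    finally:
        if own:
            fh.close()


def load_fai(fasta_path) -> list[FaiRecord]:
    """Read ``<fasta>.fai`` if present, else index the FASTA in memory."""
    fai_path = str(fasta_path) + ".fai"
    if os.path.exists(fai_path):
        return read_fai(fai_path)
    return build_fai(fasta_path)


def fetch_region(
    fasta_path, fai: list[FaiRecord], name: str, start1: int, end1: int
) -> str:
    """Fetch bases ``start1..end1`` (1-based inclusive) via offset arithmetic."""
    rec = next((r for r in fai if r.name == name), None)
    if rec is None:
        raise LookupMiss(f"sequence {name!r} not in FAI index")
    if not 1 <= start1 <= end1 <= rec.length:
        raise RangeError(
            f"range {start1}-{end1} invalid for {name!r} of length {rec.length}"
        )
    first = start1 - 1
    last = end1 - 1
    byte_lo = rec.offset + (first // rec.linebases) * rec.linewidth + first % rec.linebases
    byte_hi = rec.offset + (last // rec.linebases) * rec.linewidth + last % rec.linebases
    with open(fasta_path, "rb") as fh:
        fh.seek(byte_lo)
        raw = fh.read(byte_hi - byte_lo + 1)
    seq = raw.replace(b"\r", b"").replace(b"\n", b"").decode("ascii")
    assert len(seq) == end1 - start1 + 1
    return seq


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(source: IO[str] | str | os.PathLike) -> Iterator[FastqRecord]:
    """Lazily parse 4-line FASTQ records."""
    own = isinstance(source, (str, os.PathLike))
    fh = open(source, "r") if own else source

    def gen() -> Iterator[FastqRecord]:
        try:
            lineno = 0
            while True:
                lines = []
                for _ in range(4):
                    line = fh.readline()
                    if not line:
                        break
                    lineno += 1
                    lines.append(line.rstrip("\r\n"))
                if not lines:
                    return
                if len(lines) < 4:
                    raise ParseError("truncated FASTQ record", lineno)
                head, seq, plus, qual = lines
                if not head.startswith("@"):
                    raise ParseError(f"FASTQ header must start with '@': {head!r}", lineno - 3)
                if not plus.startswith("+"):
                    raise ParseError(f"FASTQ separator must start with '+': {plus!r}", lineno - 1)
                if any(ord(c) < 33 or ord(c) > 126 for c in qual):
                    raise ParseError("quality characters outside Phred+33 range", lineno)
                yield FastqRecord(head[1:], seq, qual)
        finally:
            if own:
                fh.close()

    return gen()


def write_fastq(records: Iterable[FastqRecord], sink: IO[str] | str | os.PathLike) -> None:
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w") if own else sink
    try:
        for rec in records:
            fh.write(f"@{rec.name}\n{rec.seq}\n+\n{rec.qual}\n")
    finally:
        if own:
            fh.close()
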