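"""Core SAM domain model: headers, alignment records, flags, CIGAR.

Coordinates are 1-based inclusive throughout this module (the SAM text
convention); the BAM binary layer and the BAI binning code convert to
0-based half-open at their boundaries, so the conversion lives in exactly
one place per format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import AlnkitError, ParseError, RangeError

# ---------------------------------------------------------------------------
# FLAG bits
# ---------------------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_OF_PAIR = 0x40
FLAG_SECOND_OF_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_QC_FAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

_FLAG_NAMES = (
    (FLAG_PAIRED, "paired"),
    (FLAG_PROPER_PAIR, "proper_pair"),
    (FLAG_UNMAPPED, "unmapped"),
    (FLAG_MATE_UNMAPPED, "mate_unmapped"),
    (FLAG_REVERSE, "reverse"),
    (FLAG_MATE_REVERSE, "mate_reverse"),
    (FLAG_FIRST_OF_PAIR, "first_of_pair"),
    (FLAG_SECOND_OF_PAIR, "second_of_pair"),
    (FLAG_SECONDARY, "secondary"),
    (FLAG_QC_FAIL, "qc_fail"),
    (FLAG_DUPLICATE, "duplicate"),
    (FLAG_SUPPLEMENTARY, "supplementary"),
)


def decode_flag(flag: int) -> frozenset[str]:
    """Decode a bitwise FLAG into the set of predicate names it asserts."""
    if not 0 <= flag <= 0xFFFF:
        raise RangeError(f"flag {flag} outside [0, 65535]")
    return frozenset(name for bit, name in _FLAG_NAMES if flag & bit)


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------

CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = frozenset("MIS=X")
REF_CONSUMING = frozenset("MDN=X")

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class CigarOp:
    length: int
    op: str  # one of MIDNSHP=X

    def __str__(self) -> str:
        return f"{self.length}{self.op}"


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse a CIGAR string; ``"*"`` maps to the empty op list.

    Zero-length ops are accepted here (lenient read path) but rejected by
    :func:`serialize_cigar` (strict write path).
    """
    if text == "*":
        return []
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise ParseError(f"malformed CIGAR {text!r} at offset {pos}")
        ops.append(CigarOp(int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(text) or not ops:
        raise ParseError(f"malformed CIGAR {text!r}")
    return ops


def serialize_cigar(ops: Iterable[CigarOp]) -> str:
    parts = []
    for op in ops:
        if op.length <= 0:
            raise ParseError(f"zero/negative-length CIGAR op {op!r} on write path")
        if op.op not in CIGAR_OPS:
            raise ParseError(f"unknown CIGAR op {op.op!r}")
        parts.append(f"{op.length}{op.op}")
    return "".join(parts) if parts else "*"


def cigar_lengths(ops: Iterable[CigarOp]) -> tuple[int, int]:
    """Return (query length, reference length) consumed by an op list."""
    qlen = rlen = 0
    for op in ops:
        if op.op in QUERY_CONSUMING:
            qlen += op.length
        if op.op in REF_CONSUMING:
            rlen += op.length
    return qlen, rlen


# ---------------------------------------------------------------------------
# header
# ---------------------------------------------------------------------------

@dataclass
class HeaderRecord:
    """One header line: @HD/@SQ/@RG/@PG with tag fields, or @CO free text."""

    record_type: str                       # HD, SQ, RG, PG or CO
    fields: list[tuple[str, str]] = field(default_factory=list)
    comment: str | None = None             # CO only

    def get(self, tag: str) -> str | None:
        for k, v in self.fields:
            if k == tag:
                return v
        return None


class SamHeader:
    """Ordered header records; the @SQ order defines the reference-id space."""

    def __init__(self, records: Iterable[HeaderRecord] = ()):
        self.records: list[HeaderRecord] = list(records)
        self._check_sq()

    def _check_sq(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_type != "SQ":
                continue
            name, ln = rec.get("SN"), rec.get("LN")
            if name is None or ln is None:
                raise ParseError("@SQ record missing SN or LN")
            if int(ln) <= 0:
                raise ParseError(f"@SQ {name} has non-positive LN {ln}")
            if name in seen:
                raise ParseError(f"duplicate @SQ name {name!r}")
            seen.add(name)

    @property
    def references(self) -> list[tuple[str, int]]:
        """(name, length) pairs in file order; index == reference id."""
        return [
            (rec.get("SN"), int(rec.get("LN")))
            for rec in self.records
            if rec.record_type == "SQ"
        ]

    def reference_id(self, name: str) -> int:
        for i, (sn, _) in enumerate(self.references):
            if sn == name:
                return i
        return -1

    def reference_length(self, name: str) -> int | None:
        for sn, ln in self.references:
            if sn == name:
                return ln
        return None

    def set_sort_order(self, order: str) -> None:
        """Set or update the @HD SO tag, creating @HD if absent."""
        for rec in self.records:
            if rec.record_type == "HD":
                rec.fields = [(k, v) for k, v in rec.fields if k != "SO"]
                rec.fields.append(("SO", order))
                return
        hd = HeaderRecord("HD", [("VN", "1.6"), ("SO", order)])
        self.records.insert(0, hd)

    def copy(self) -> "SamHeader":
        return SamHeader(
            HeaderRecord(r.record_type, list(r.fields), r.comment)
            for r in self.records
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SamHeader):
            return NotImplemented
        return [
            (r.record_type, r.fields, r.comment) for r in self.records
        ] == [(r.record_type, r.fields, r.comment) for r in other.records]

    def __repr__(self) -> str:
        return f"SamHeader({len(self.records)} records, {len(self.references)} refs)"


# ---------------------------------------------------------------------------
# alignment records
# ---------------------------------------------------------------------------

#: Optional-tag value: (two-char tag, one-char type, value).  For type B
#: the value is a (subtype_char, list-of-numbers) pair.
Tag = tuple[str, str, object]


@dataclass
class AlignmentRecord:
    """One SAM/BAM alignment row (SAM text conventions, 1-based pos)."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[Tag] = field(default_factory=list)
    #: Starting virtual offset within the source BAM, when read from one.
    voffset: int | None = None

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    def cigar_ops(self) -> list[CigarOp]:
        return parse_cigar(self.cigar)

    def reference_length(self) -> int:
        """Reference bases consumed by the alignment (0 for '*' CIGAR)."""
        return cigar_lengths(self.cigar_ops())[1]

    def get_tag(self, tag: str):
        for name, _, value in self.tags:
            if name == tag:
                return value
        return None

    def key_fields(self) -> tuple:
        """All semantically meaningful fields, for equality in tests/oracles."""
        return (
            self.qname, self.flag, self.rname, self.pos, self.mapq,
            self.cigar, self.rnext, self.pnext, self.tlen, self.seq,
            self.qual, tuple((t, y, _freeze(v)) for t, y, v in self.tags),
        )


def _freeze(v):
    if isinstance(v, tuple) and len(v) == 2 and isinstance(v[1], list):
        return (v[0], tuple(v[1]))
    return v


def alignment_end(record: AlignmentRecord) -> int:
    """1-based inclusive rightmost reference position of a mapped record."""
    if not record.is_mapped or record.cigar == "*":
        raise AlnkitError(
            "alignment end undefined for unmapped record or '*' CIGAR"
        )
    return record.pos + record.reference_length() - 1


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_record(record: AlignmentRecord, header: SamHeader | None = None) -> list[str]:
    """Return the list of invariant violations (empty when consistent).

    Violations are data, not exceptions: readers may surface them,
    writers refuse records that carry any.
    """
    v: list[str] = []
    if not 0 <= record.flag <= 0xFFFF:
        v.append(f"flag {record.flag} outside [0, 65535]")
    if not 0 <= record.mapq <= 255:
        v.append(f"mapq {record.mapq} outside [0, 255]")
    if record.pos < 0:
        v.append(f"pos {record.pos} negative")
    if record.seq != "*" and record.qual != "*" and len(record.seq) != len(record.qual):
        v.append(
            f"seq length {len(record.seq)} != qual length {len(record.qual)}"
        )
    if record.cigar != "*":
        try:
            ops = record.cigar_ops()
        except ParseError as exc:
            v.append(str(exc))
            ops = []
        if ops and record.seq != "*":
            qlen = cigar_lengths(ops)[0]
            if qlen != len(record.seq):
                v.append(
                    f"CIGAR query length {qlen} != seq length {len(record.seq)}"
                )
    if record.is_mapped:
        if record.rname == "*":
            v.append("mapped record has rname '*'")
        if record.pos < 1:
            v.append(f"mapped record has pos {record.pos} < 1")
    if header is not None:
        names = {sn for sn, _ in header.references}
        if record.rname != "*" and record.rname not in names:
            v.append(f"rname {record.rname!r} not in header @SQ set")
        elif record.rname != "*":
            ln = header.reference_length(record.rname)
            if record.pos > ln:
                v.append(f"pos {record.pos} beyond {record.rname} length {ln}")
        if record.rnext not in ("*", "=") and record.rnext not in names:
            v.append(f"rnext {record.rnext!r} not in header @SQ set")
    return v


# ---------------------------------------------------------------------------
# reference-name normalization
# ---------------------------------------------------------------------------

def default_name_map() -> dict[str, str]:
    """Canonicalization map: bare chromosome tokens gain the ``chr`` prefix."""
    mapping = {str(i): f"chr{i}" for i in range(1, 23)}
    mapping.update({"X": "chrX", "Y": "chrY", "M": "chrM", "MT": "chrM"})
    return mapping


def normalize_reference_names(
    header: SamHeader,
    records: Iterable[AlignmentRecord],
    name_map: dict[str, str] | None = None,
) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    """Canonicalize reference names in the header and every record.

    Names already canonical pass through unchanged; @SQ order is
    preserved.  Two distinct input names mapping to the same canonical
    name is a collision and raises immediately (before any records are
    consumed) so no partially-renamed output can escape.
    """
    mapping = default_name_map() if name_map is None else dict(name_map)

    def canon(name: str) -> str:
        return mapping.get(name, name)

    new_header = header.copy()
    seen: dict[str, str] = {}
    for rec in new_header.records:
        if rec.record_type != "SQ":
            continue
        new_fields = []
        for k, val in rec.fields:
            if k == "SN":
                new = canon(val)
                if new in seen and seen[new] != val:
                    raise AlnkitError(
                        f"name collision: {seen[new]!r} and {val!r} both map to {new!r}"
                    )
                seen[new] = val
                val = new
            new_fields.append((k, val))
        rec.fields = new_fields

    def gen() -> Iterator[AlignmentRecord]:
        for r in records:
            rname = canon(r.rname) if r.rname != "*" else "*"
            rnext = r.rnext if r.rnext in ("*", "=") else canon(r.rnext)
            yield AlignmentRecord(
                r.qname, r.flag, rname, r.pos, r.mapq, r.cigar,
                rnext, r.pnext, r.tlen, r.seq, r.qual, list(r.tags),
            )

    return new_header, gen()
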