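"""BAM binary encoder/decoder layered on the BGZF codec.

Covers the uncompressed BAM payload format: the ``BAM\\1`` magic, the
embedded SAM header text plus binary reference directory, and the
per-record layout (4-bit packed sequence, 28+4-bit CIGAR words, typed
binary tags).  All multi-byte integers are little-endian.

The domain model upstairs is 1-based inclusive; this module owns the
conversion to BAM's 0-based coordinates and back.
"""

from __future__ import annotations

import os
import struct
from typing import IO, Iterable, Iterator

from . import bgzf
from .bai import reg2bin
from .errors import FormatError, TruncationError, ValidationError
from .model import (
    AlignmentRecord,
    CigarOp,
    HeaderRecord,
    SamHeader,
    Tag,
    cigar_lengths,
    parse_cigar,
    serialize_cigar,
    validate_record,
)
from .samio import parse_header_line, serialize_header

BAM_MAGIC = b"BAM\x01"

SEQ_SYMBOLS = "=ACMGRSVTWYHKDBN"
_SEQ_CODE = {ch: i for i, ch in enumerate(SEQ_SYMBOLS)}
_SEQ_CODE.update({ch.lower(): i for i, ch in enumerate(SEQ_SYMBOLS) if ch.isalpha()})

CIGAR_OPS = "MIDNSHP=X"
_CIGAR_CODE = {op: i for i, op in enumerate(CIGAR_OPS)}


# ---------------------------------------------------------------------------
# field codecs
# ---------------------------------------------------------------------------

def encode_seq(seq: str) -> bytes:
    """Pack bases two-per-byte, high nibble first; odd length pads with 0."""
    out = bytearray((len(seq) + 1) // 2)
    for i, base in enumerate(seq):
        code = _SEQ_CODE.get(base)
        if code is None:
            raise ValidationError(f"base {base!r} not encodable in BAM 4-bit alphabet")
        if i % 2 == 0:
            out[i // 2] = code << 4
        else:
            out[i // 2] |= code
    return bytes(out)


def decode_seq(data: bytes, length: int) -> str:
    bases = []
    for i in range(length):
        byte = data[i // 2]
        code = (byte >> 4) if i % 2 == 0 else (byte & 0xF)
        bases.append(SEQ_SYMBOLS[code])
    return "".join(bases)


def encode_cigar(ops: Iterable[CigarOp]) -> list[int]:
    """Encode ops as 32-bit words: (length << 4) | opcode, MIDNSHP=X order."""
    words = []
    for op in ops:
        if op.length >= 1 << 28:
            raise ValidationError(f"CIGAR length {op.length} overflows 28 bits")
        words.append((op.length << 4) | _CIGAR_CODE[op.op])
    return words


def decode_cigar(words: Iterable[int]) -> list[CigarOp]:
    return [CigarOp(w >> 4, CIGAR_OPS[w & 0xF]) for w in words]


_INT_TAG_FORMATS = {"c": "<b", "C": "<B", "s": "<h", "S": "<H", "i": "<i", "I": "<I"}
_B_ELEMENT = {"c": "b", "C": "B", "s": "h", "S": "H", "i": "i", "I": "I", "f": "f"}


def _smallest_int_subtype(value: int) -> str:
    """Pick the smallest BAM integer subtype that holds ``value``."""
    if value >= 0:
        if value <= 0xFF:
            return "C"
        if value <= 0xFFFF:
            return "S"
        if value <= 0xFFFFFFFF:
            return "I"
    else:
        if value >= -0x80:
            return "c"
        if value >= -0x8000:
            return "s"
        if value >= -0x80000000:
            return "i"
    raise ValidationError(f"integer tag value {value} does not fit any BAM subtype")


def encode_tags(tags: Iterable[Tag]) -> bytes:
    out = bytearray()
    for name, typ, value in tags:
        out += name.encode("ascii")
        if typ == "A":
            out += b"A" + value.encode("ascii")
        elif typ == "i":
            sub = _smallest_int_subtype(int(value))
            out += sub.encode("ascii") + struct.pack(_INT_TAG_FORMATS[sub], int(value))
        elif typ == "f":
            out += b"f" + struct.pack("<f", float(value))
        elif typ in ("Z", "H"):
            out += typ.encode("ascii") + str(value).encode("ascii") + b"\x00"
        elif typ == "B":
            sub, values = value
            elem = _B_ELEMENT[sub]
            out += b"B" + sub.encode("ascii") + struct.pack("<i", len(values))
            out += struct.pack(f"<{len(values)}{elem}", *values)
        else:
            raise ValidationError(f"unknown tag type {typ!r}")
    return bytes(out)


def decode_tags(data: bytes) -> list[Tag]:
    """Decode binary tags; integer subtypes all surface as text type 'i'."""
    tags: list[Tag] = []
    pos = 0
    n = len(data)
    while pos < n:
        if pos + 3 > n:
            raise TruncationError("truncated tag block")
        name = data[pos:pos + 2].decode("ascii")
        typ = chr(data[pos + 2])
        pos += 3
        if typ == "A":
            tags.append((name, "A", chr(data[pos])))
            pos += 1
        elif typ in _INT_TAG_FORMATS:
            fmt = _INT_TAG_FORMATS[typ]
            size = struct.calcsize(fmt)
            tags.append((name, "i", struct.unpack_from(fmt, data, pos)[0]))
            pos += size
        elif typ == "f":
            tags.append((name, "f", struct.unpack_from("<f", data, pos)[0]))
            pos += 4
        elif typ in ("Z", "H"):
            end = data.index(b"\x00", pos)
            tags.append((name, typ, data[pos:end].decode("ascii")))
            pos = end + 1
        elif typ == "B":
            sub = chr(data[pos])
            count = struct.unpack_from("<i", data, pos + 1)[0]
            elem = _B_ELEMENT[sub]
            values = list(struct.unpack_from(f"<{count}{elem}", data, pos + 5))
            tags.append((name, "B", (sub, values)))
            pos += 5 + count * struct.calcsize(elem)
        else:
            raise FormatError(f"unknown binary tag type {typ!r}")
    return tags


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

def _record_bin(pos0: int, ref_len: int) -> int:
    if pos0 < 0:
        return 0
    return reg2bin(pos0, pos0 + max(ref_len, 1))


def encode_record(rec: AlignmentRecord, header: SamHeader) -> bytes:
    """Encode one record as a BAM block (including its block_size prefix)."""
    refid = header.reference_id(rec.rname) if rec.rname != "*" else -1
    if rec.rname != "*" and refid < 0:
        raise ValidationError(f"rname {rec.rname!r} absent from header")
    if rec.rnext == "=":
        next_refid = refid
    elif rec.rnext == "*":
        next_refid = -1
    else:
        next_refid = header.reference_id(rec.rnext)
        if next_refid < 0:
            raise ValidationError(f"rnext {rec.rnext!r} absent from header")
    pos0 = rec.pos - 1
    next_pos0 = rec.pnext - 1
    # Unmapped read with a placed mate adopts the mate's coordinates so it
    # stays adjacent under coordinate sort (samtools placement convention).
    if not rec.is_mapped and rec.rname == "*" and next_refid >= 0:
        refid = next_refid
        pos0 = next_pos0
    ops = parse_cigar(rec.cigar)
    ref_len = cigar_lengths(ops)[1]
    cigar_words = encode_cigar(ops)
    name = rec.qname.encode("ascii") + b"\x00"
    seq = "" if rec.seq == "*" else rec.seq
    packed_seq = encode_seq(seq)
    if rec.qual == "*" or not seq:
        quals = b"\xff" * len(seq)
    else:
        quals = bytes(ord(c) - 33 for c in rec.qual)
    tags = encode_tags(rec.tags)
    body = struct.pack(
        "<iiBBHHHiiii",
        refid,
        pos0,
        len(name),
        rec.mapq,
        _record_bin(pos0, ref_len),
        len(cigar_words),
        rec.flag,
        len(seq),
        next_refid,
        next_pos0,
        rec.tlen,
    )
    body += name
    body += struct.pack(f"<{len(cigar_words)}I", *cigar_words)
    body += packed_seq + quals + tags
    return struct.pack("<i", len(body)) + body


def decode_record(body: bytes, references: list[tuple[str, int]]) -> AlignmentRecord:
    """Decode one record body (the bytes after its block_size prefix)."""
    (refid, pos0, l_name, mapq, _bin, n_cigar, flag,
     l_seq, next_refid, next_pos0, tlen) = struct.unpack_from("<iiBBHHHiiii", body, 0)
    pos = 32
    qname = body[pos:pos + l_name - 1].decode("ascii")
    pos += l_name
    cigar_words = struct.unpack_from(f"<{n_cigar}I", body, pos)
    pos += 4 * n_cigar
    seq_bytes = body[pos:pos + (l_seq + 1) // 2]
    pos += (l_seq + 1) // 2
    qual_bytes = body[pos:pos + l_seq]
    pos += l_seq
    tags = decode_tags(body[pos:])

    def ref_name(i: int) -> str:
        if i < 0:
            return "*"
        if i >= len(references):
            raise FormatError(f"reference id {i} beyond directory of {len(references)}")
        return references[i][0]

    rname = ref_name(refid)
    if next_refid == -1:
        rnext = "*"
    elif next_refid == refid:
        rnext = "="
    else:
        rnext = ref_name(next_refid)
    seq = decode_seq(seq_bytes, l_seq) if l_seq else "*"
    if l_seq and all(q == 0xFF for q in qual_bytes):
        qual = "*"
    elif l_seq:
        qual = "".join(chr(q + 33) for q in qual_bytes)
    else:
        qual = "*"
    cigar = serialize_cigar(decode_cigar(cigar_words)) if n_cigar else "*"
    flag = int(flag)
    # Unmapped-but-placed records keep their mate-derived rname/pos in SAM
    # text too (samtools convention); truly unplaced records decode from
    # refid -1 back to '*'/0 naturally.
    return AlignmentRecord(
        qname=qname, flag=flag, rname=rname, pos=pos0 + 1, mapq=mapq,
        cigar=cigar, rnext=rnext, pnext=next_pos0 + 1, tlen=tlen,
        seq=seq, qual=qual, tags=tags,
    )


# ---------------------------------------------------------------------------
# file-level API
# ---------------------------------------------------------------------------

def _encode_header(header: SamHeader) -> bytes:
    text = serialize_header(header).encode("ascii")
    refs = header.references
    out = bytearray(BAM_MAGIC)
    out += struct.pack("<i", len(text)) + text
    out += struct.pack("<i", len(refs))
    for name, length in refs:
        bname = name.encode("ascii") + b"\x00"
        out += struct.pack("<i", len(bname)) + bname + struct.pack("<i", length)
    return bytes(out)


def _decode_header(reader: bgzf.BgzfReader) -> SamHeader:
    magic = reader.read_exact(4)
    if magic != BAM_MAGIC:
        raise FormatError(f"bad BAM magic {magic!r}")
    (l_text,) = struct.unpack("<i", reader.read_exact(4))
    text = reader.read_exact(l_text).decode("ascii").rstrip("\x00")
    (n_ref,) = struct.unpack("<i", reader.read_exact(4))
    references: list[tuple[str, int]] = []
    for _ in range(n_ref):
        (l_name,) = struct.unpack("<i", reader.read_exact(4))
        name = reader.read_exact(l_name)[:-1].decode("ascii")
        (l_ref,) = struct.unpack("<i", reader.read_exact(4))
        references.append((name, l_ref))
    records = [
        parse_header_line(line)
        for line in text.splitlines()
        if line.strip()
    ]
    header = SamHeader(records)
    header_sq = header.references
    if header_sq:
        if [(n, l) for n, l in header_sq] != references:
            raise FormatError(
                "binary reference directory disagrees with header @SQ records"
            )
    else:
        # Header text without @SQ lines: synthesize them from the directory.
        for name, length in references:
            header.records.append(
                HeaderRecord("SQ", [("SN", name), ("LN", str(length))])
            )
    return header


class BamReader:
    """Lazy BAM reader exposing each record's starting virtual offset."""

    def __init__(self, source: IO[bytes] | str | os.PathLike):
        if isinstance(source, (str, os.PathLike)):
            self._bgzf = bgzf.BgzfReader.open(source)
        else:
            self._bgzf = bgzf.BgzfReader(source)
        self.header = _decode_header(self._bgzf)
        self.references = self.header.references

    def __iter__(self) -> Iterator[AlignmentRecord]:
        while True:
            voffset = self._bgzf.tell()
            size_bytes = self._bgzf.read(4)
            if not size_bytes:
                return
            if len(size_bytes) < 4:
                raise TruncationError("truncated record length field")
            (block_size,) = struct.unpack("<i", size_bytes)
            body = self._bgzf.read_exact(block_size)
            rec = decode_record(body, self.references)
            rec.voffset = voffset
            yield rec

    def seek(self, voffset: int) -> None:
        self._bgzf.seek(voffset)

    def tell(self) -> int:
        return self._bgzf.tell()

    def close(self) -> None:
        self._bgzf.close()

    def __enter__(self) -> "BamReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_bam(source) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    """Open a BAM file: (header, lazy record stream with virtual offsets)."""
    reader = BamReader(source)

    def gen() -> Iterator[AlignmentRecord]:
        try:
            yield from reader
        finally:
            reader.close()

    return reader.header, gen()


def write_bam(
    sink: IO[bytes] | str | os.PathLike,
    header: SamHeader,
    records: Iterable[AlignmentRecord],
    level: int = 6,
    workers: int = 1,
    validate: bool = True,
) -> None:
    """Write a complete BAM file, terminated by the BGZF sentinel block."""
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "wb") if own else sink
    try:
        with bgzf.BgzfWriter(fh, level=level, workers=workers) as w:
            w.write(_encode_header(header))
            for rec in records:
                if validate:
                    violations = validate_record(rec, header)
                    if violations:
                        raise ValidationError(
                            f"refusing to write record {rec.qname!r}: "
                            + "; ".join(violations)
                        )
                w.write(encode_record(rec, header))
    finally:
        if own and not fh.closed:
            fh.close()


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

def sam_to_bam(sam_path, bam_path, level: int = 6, workers: int = 1) -> None:
    from .samio import read_sam

    header, records = read_sam(sam_path)
    write_bam(bam_path, header, records, level=level, workers=workers)


def bam_to_sam(bam_path, sam_path) -> None:
    from .samio import write_sam

    header, records = read_bam(bam_path)
    write_sam(sam_path, header, records)
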