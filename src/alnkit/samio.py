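"""Streaming reader/writer for the SAM text format.

Records are yielded lazily so memory use is independent of file length.
Optional tags are preserved in input order, giving byte-stable round
trips for files that already use canonical tag serialization.  CR/LF is
tolerated on read; LF is emitted on write.
"""

from __future__ import annotations

import os
from typing import IO, Iterable, Iterator

from .errors import ParseError, ValidationError
from .model import AlignmentRecord, HeaderRecord, SamHeader, Tag, validate_record

_TAG_TYPES = set("AifZHB")


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

def parse_tag(token: str, line: int | None = None) -> Tag:
    parts = token.split(":", 2)
    if len(parts) != 3 or len(parts[0]) != 2:
        raise ParseError(f"malformed tag {token!r}", line)
    name, typ, raw = parts
    if typ not in _TAG_TYPES:
        raise ParseError(f"unknown tag type {typ!r} in {token!r}", line)
    if typ == "i":
        try:
            return (name, typ, int(raw))
        except ValueError:
            raise ParseError(f"non-integer value in {token!r}", line) from None
    if typ == "f":
        try:
            return (name, typ, float(raw))
        except ValueError:
            raise ParseError(f"non-float value in {token!r}", line) from None
    if typ == "A":
        if len(raw) != 1:
            raise ParseError(f"type A tag needs one character: {token!r}", line)
        return (name, typ, raw)
    if typ == "B":
        fields = raw.split(",")
        sub = fields[0]
        if sub not in set("cCsSiIf"):
            raise ParseError(f"unknown B-array subtype {sub!r}", line)
        conv = float if sub == "f" else int
        try:
            values = [conv(x) for x in fields[1:]]
        except ValueError:
            raise ParseError(f"bad B-array value in {token!r}", line) from None
        return (name, typ, (sub, values))
    return (name, typ, raw)  # Z and H stay as text


def serialize_tag(tag: Tag) -> str:
    name, typ, value = tag
    if typ == "B":
        sub, values = value
        if sub == "f":
            body = ",".join(_fmt_float(v) for v in values)
        else:
            body = ",".join(str(int(v)) for v in values)
        return f"{name}:B:{sub},{body}" if values else f"{name}:B:{sub}"
    if typ == "f":
        return f"{name}:f:{_fmt_float(value)}"
    return f"{name}:{typ}:{value}"


def _fmt_float(v: float) -> str:
    # repr gives shortest round-tripping form; ints-as-floats print bare.
    return repr(float(v)).removesuffix(".0") if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# header lines
# ---------------------------------------------------------------------------

def parse_header_line(line: str, lineno: int | None = None) -> HeaderRecord:
    if not line.startswith("@") or len(line) < 3:
        raise ParseError(f"not a header line: {line!r}", lineno)
    rtype = line[1:3]
    if rtype == "CO":
        return HeaderRecord("CO", comment=line[4:] if len(line) > 3 else "")
    if rtype not in ("HD", "SQ", "RG", "PG"):
        raise ParseError(f"unknown header record type @{rtype}", lineno)
    fields: list[tuple[str, str]] = []
    for token in line.split("\t")[1:]:
        if len(token) < 3 or token[2] != ":":
            raise ParseError(f"malformed header field {token!r}", lineno)
        fields.append((token[:2], token[3:]))
    return HeaderRecord(rtype, fields)


def serialize_header(header: SamHeader) -> str:
    lines = []
    for rec in header.records:
        if rec.record_type == "CO":
            lines.append(f"@CO\t{rec.comment}")
        else:
            body = "\t".join(f"{k}:{v}" for k, v in rec.fields)
            lines.append(f"@{rec.record_type}\t{body}")
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

def parse_record_line(line: str, lineno: int | None = None) -> AlignmentRecord:
    fields = line.split("\t")
    if len(fields) < 11:
        raise ParseError(
            f"alignment line has {len(fields)} fields; 11 required", lineno
        )
    try:
        rec = AlignmentRecord(
            qname=fields[0],
            flag=int(fields[1]),
            rname=fields[2],
            pos=int(fields[3]),
            mapq=int(fields[4]),
            cigar=fields[5],
            rnext=fields[6],
            pnext=int(fields[7]),
            tlen=int(fields[8]),
            seq=fields[9],
            qual=fields[10],
            tags=[parse_tag(t, lineno) for t in fields[11:]],
        )
    except ValueError as exc:
        raise ParseError(f"bad numeric field: {exc}", lineno) from None
    return rec


def serialize_record(rec: AlignmentRecord) -> str:
    fields = [
        rec.qname, str(rec.flag), rec.rname, str(rec.pos), str(rec.mapq),
        rec.cigar, rec.rnext, str(rec.pnext), str(rec.tlen), rec.seq, rec.qual,
    ]
    fields.extend(serialize_tag(t) for t in rec.tags)
    return "\t".join(fields)


# ---------------------------------------------------------------------------
# file-level API
# ---------------------------------------------------------------------------

def read_sam(source: IO[str] | str | os.PathLike) -> tuple[SamHeader, Iterator[AlignmentRecord]]:
    """Parse a SAM stream into (header, lazy record iterator).

    The header prefix is consumed eagerly; records stream lazily.  When
    given a path the file is opened and closed by the record iterator.
    """
    own = isinstance(source, (str, os.PathLike))
    fh = open(source, "r", newline="") if own else source

    header_records: list[HeaderRecord] = []
    first_body: str | None = None
    lineno = 0
    for raw in fh:
        lineno += 1
        line = raw.rstrip("\r\n")
        if not line:
            continue
        if line.startswith("@"):
            header_records.append(parse_header_line(line, lineno))
        else:
            first_body = line
            break
    header = SamHeader(header_records)
    first_lineno = lineno

    def gen() -> Iterator[AlignmentRecord]:
        try:
            n = first_lineno
            if first_body is not None:
                yield parse_record_line(first_body, n)
            for raw in fh:
                n += 1
                line = raw.rstrip("\r\n")
                if not line:
                    continue
                if line.startswith("@"):
                    raise ParseError("header line after records began", n)
                yield parse_record_line(line, n)
        finally:
            if own:
                fh.close()

    return header, gen()


def write_sam(
    sink: IO[str] | str | os.PathLike,
    header: SamHeader,
    records: Iterable[AlignmentRecord],
    validate: bool = True,
) -> None:
    """Write header then records as SAM text.

    With ``validate`` (the default) any record carrying violations is
    refused with the violation list, before it reaches the output.
    """
    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "w", newline="") if own else sink
    try:
        fh.write(serialize_header(header))
        for rec in records:
            if validate:
                violations = validate_record(rec, header)
                if violations:
                    raise ValidationError(
                        f"refusing to write record {rec.qname!r}: " + "; ".join(violations)
                    )
            fh.write(serialize_record(rec) + "\n")
    finally:
        if own:
            fh.close()
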