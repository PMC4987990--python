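"""Per-position coverage and samtools-style mpileup text generation.

A pileup walks coordinate-sorted alignments and accounts, for every
reference position, which read bases cover it.  The default filter mask
drops unmapped (0x4), secondary (0x100), QC-fail (0x200) and duplicate
(0x400) records — the samtools default.  Deleted positions count toward
depth; skipped (N) positions do not.

mpileup columns are rname, pos, ref base, depth, base string, quality
string, with the samtools token alphabet: ``.``/``,`` for forward/
reverse matches, upper/lowercase letters for mismatches, ``*`` for a
deleted position, ``^`` + mapq char at read start, ``$`` at read end,
and ``+n<seq>``/``-n<seq>`` insertion/deletion annotations attached to
the preceding position.  Without a reference FASTA the ref base column
is ``N`` and every aligned base is reported as its letter.

Quality characters are emitted for non-deletion tokens only.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import AlnkitError, LookupMiss, RangeError
from .model import AlignmentRecord

DEFAULT_FILTER_MASK = 0x4 | 0x100 | 0x200 | 0x400


@dataclass
class PileupColumn:
    rname: str
    pos: int          # 1-based
    ref_base: str
    depth: int
    bases: str
    quals: str

    def to_line(self) -> str:
        return (
            f"{self.rname}\t{self.pos}\t{self.ref_base}\t{self.depth}"
            f"\t{self.bases}\t{self.quals}"
        )


@dataclass(frozen=True)
class Region:
    rname: str
    start1: int  # 1-based inclusive
    end1: int

    def __str__(self) -> str:
        return f"{self.rname}:{self.start1}-{self.end1}"


def parse_region(text: str) -> Region:
    """Parse ``name:start-end`` (1-based inclusive)."""
    if ":" not in text:
        raise RangeError(f"region {text!r} must look like name:start-end")
    name, _, span = text.rpartition(":")
    try:
        start, end = (int(x.replace(",", "")) for x in span.split("-", 1))
    except ValueError:
        raise RangeError(f"cannot parse region span in {text!r}") from None
    return Region(name, start, end)


# ---------------------------------------------------------------------------
# record retrieval
# ---------------------------------------------------------------------------

def _overlapping_records(
    bam_path, region: Region, filter_mask: int
) -> tuple[list[AlignmentRecord], str]:
    """Fetch filter-passing records overlapping a region.

    Uses a BAI sitting next to the BAM (``<bam>.bai``) when present,
    otherwise falls back to a linear scan; the access path never changes
    the result set.
    """
    from .bai import fetch_records, read_bai
    from .bamio import read_bam

    beg0, end0 = region.start1 - 1, region.end1
    if region.start1 > region.end1:
        raise RangeError(f"region start {region.start1} > end {region.end1}")
    bai_path = str(bam_path) + ".bai"
    out = []
    if os.path.exists(bai_path):
        index = read_bai(bai_path)
        recs = fetch_records(bam_path, index, region.rname, beg0, end0)
        for rec in recs:
            if not rec.flag & filter_mask:
                out.append(rec)
        return out, region.rname
    header, records = read_bam(bam_path)
    if header.reference_id(region.rname) < 0:
        raise LookupMiss(f"reference {region.rname!r} not in BAM header")
    for rec in records:
        if rec.rname != region.rname or rec.flag & filter_mask:
            continue
        pos0 = rec.pos - 1
        ref_len = max(rec.reference_length() if rec.cigar != "*" else 0, 1)
        if pos0 < end0 and pos0 + ref_len > beg0:
            out.append(rec)
    return out, region.rname


def _bam_references(bam_path) -> list[tuple[str, int]]:
    from .bamio import BamReader

    with BamReader(bam_path) as reader:
        return reader.references


# ---------------------------------------------------------------------------
# simple pileup
# ---------------------------------------------------------------------------

def simple_pileup(
    bam_path,
    region: Region | str,
    filter_mask: int = DEFAULT_FILTER_MASK,
) -> Iterator[tuple[int, int]]:
    """Yield (1-based position, depth) for every position in the region.

    Depth counts reads whose reference-consuming CIGAR ops (M, D, =, X)
    cover the position after flag filtering; N-skipped stretches do not
    cover.  Zero-depth positions are included — this is the "first N
    genomic positions" view.
    """
    if isinstance(region, str):
        region = parse_region(region)
    records, _ = _overlapping_records(bam_path, region, filter_mask)
    depth = [0] * (region.end1 - region.start1 + 1)
    for rec in records:
        if rec.cigar == "*":
            continue
        rpos = rec.pos
        for op in rec.cigar_ops():
            if op.op in "MDX=":
                lo = max(rpos, region.start1)
                hi = min(rpos + op.length - 1, region.end1)
                for p in range(lo, hi + 1):
                    depth[p - region.start1] += 1
                rpos += op.length
            elif op.op == "N":
                rpos += op.length
    for i, d in enumerate(depth):
        yield region.start1 + i, d


# ---------------------------------------------------------------------------
# mpileup
# ---------------------------------------------------------------------------

def _read_events(
    rec: AlignmentRecord, ref_seq: str | None, ref_offset: int
) -> dict[int, tuple[str, str | None]]:
    """Expand one read into {ref pos (1-based): (base token, qual char)}.

    ``ref_seq``, when given, starts at 1-based position ``ref_offset``.
    A deletion's token is '*' with no quality character.
    """
    reverse = rec.is_reverse
    seq = rec.seq
    qual = rec.qual
    events: dict[int, tuple[str, str | None]] = {}
    covered: list[int] = []  # reference positions this read covers, in order
    qpos = 0
    rpos = rec.pos

    def ref_base(p: int) -> str | None:
        if ref_seq is None:
            return None
        i = p - ref_offset
        if 0 <= i < len(ref_seq):
            return ref_seq[i]
        return None

    def case(s: str) -> str:
        return s.lower() if reverse else s.upper()

    for op in rec.cigar_ops():
        if op.op in "M=X":
            for i in range(op.length):
                base = seq[qpos + i] if seq != "*" else "N"
                rb = ref_base(rpos + i)
                if rb is not None and base.upper() == rb.upper():
                    token = "," if reverse else "."
                else:
                    token = case(base)
                qc = qual[qpos + i] if qual != "*" else "!"
                events[rpos + i] = (token, qc)
                covered.append(rpos + i)
            qpos += op.length
            rpos += op.length
        elif op.op == "I":
            if covered:
                ins = seq[qpos:qpos + op.length] if seq != "*" else "N" * op.length
                p = covered[-1]
                tok, qc = events[p]
                events[p] = (tok + f"+{op.length}{case(ins)}", qc)
            qpos += op.length
        elif op.op == "D":
            if covered:
                del_seq = "".join(
                    (ref_base(rpos + i) or "N") for i in range(op.length)
                )
                p = covered[-1]
                tok, qc = events[p]
                events[p] = (tok + f"-{op.length}{case(del_seq)}", qc)
            for i in range(op.length):
                events[rpos + i] = ("*", None)
                covered.append(rpos + i)
            rpos += op.length
        elif op.op == "N":
            rpos += op.length
        elif op.op == "S":
            qpos += op.length
        # H and P consume nothing.

    if covered:
        first, last = covered[0], covered[-1]
        tok, qc = events[first]
        mapq_char = chr(min(rec.mapq, 93) + 33)
        events[first] = (f"^{mapq_char}{tok}", qc)
        tok, qc = events[last]
        events[last] = (tok + "$", qc)
    return events


def mpileup(
    bam_path,
    region: Region | str | None = None,
    fasta_path=None,
    filter_mask: int = DEFAULT_FILTER_MASK,
    all_positions: bool = False,
) -> Iterator[PileupColumn]:
    """Yield samtools-style pileup columns for a region (or whole file).

    With a FASTA (FAI built on demand) the reference base column is
    filled and matching bases render as '.'/','; without one, ref base
    is 'N' and bases render as letters.  Zero-coverage positions are
    omitted unless ``all_positions`` is set.
    """
    if region is None:
        for rname, length in _bam_references(bam_path):
            yield from mpileup(
                bam_path, Region(rname, 1, length), fasta_path,
                filter_mask, all_positions,
            )
        return
    if isinstance(region, str):
        region = parse_region(region)
    records, rname = _overlapping_records(bam_path, region, filter_mask)

    ref_seq = None
    ref_offset = region.start1
    if fasta_path is not None:
        from .fastx import load_fai, fetch_region

        fai = load_fai(fasta_path)
        names = {r.name for r in fai}
        if rname not in names:
            raise LookupMiss(f"reference {rname!r} not in FASTA")
        length = next(r.length for r in fai if r.name == rname)
        lo = region.start1
        hi = min(region.end1, length)
        # Extend to cover read tails that run past the region edge, so
        # mismatch calls near the boundary see real reference bases.
        for rec in records:
            if rec.cigar != "*":
                hi = max(hi, min(rec.pos + rec.reference_length() - 1, length))
                lo = min(lo, rec.pos)
        ref_seq = fetch_region(fasta_path, fai, rname, lo, hi)
        ref_offset = lo

    columns: dict[int, list[tuple[str, str | None]]] = {}
    for rec in records:
        if rec.cigar == "*":
            continue
        for pos, ev in _read_events(rec, ref_seq, ref_offset).items():
            if region.start1 <= pos <= region.end1:
                columns.setdefault(pos, []).append(ev)

    for pos in range(region.start1, region.end1 + 1):
        events = columns.get(pos, [])
        if not events and not all_positions:
            continue
        if ref_seq is not None:
            i = pos - ref_offset
            rb = ref_seq[i] if 0 <= i < len(ref_seq) else "N"
        else:
            rb = "N"
        bases = "".join(tok for tok, _ in events)
        quals = "".join(qc for _, qc in events if qc is not None)
        yield PileupColumn(region.rname, pos, rb, len(events), bases, quals)


def mpileup_text(columns: Iterable[PileupColumn]) -> str:
    return "".join(col.to_line() + "\n" for col in columns)


# ---------------------------------------------------------------------------
# region-parallel execution
# ---------------------------------------------------------------------------

def parallel_pileup(
    bam_path,
    regions: list[Region | str],
    workers: int = 1,
    fasta_path=None,
    filter_mask: int = DEFAULT_FILTER_MASK,
    all_positions: bool = False,
) -> str:
    """mpileup text over non-overlapping sorted regions, region-parallel.

    Workers each render whole regions; results concatenate in region
    order, so the output is byte-identical for every worker count.
    """
    regs = [parse_region(r) if isinstance(r, str) else r for r in regions]
    for a, b in zip(regs, regs[1:]):
        if a.rname == b.rname and b.start1 <= a.end1:
            raise AlnkitError(f"regions {a} and {b} overlap or are unsorted")

    def render(region: Region) -> str:
        return mpileup_text(
            mpileup(bam_path, region, fasta_path, filter_mask, all_positions)
        )

    workers = max(1, int(workers))
    if workers == 1 or len(regs) <= 1:
        return "".join(render(r) for r in regs)
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return "".join(pool.map(render, regs))
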