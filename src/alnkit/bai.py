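"""BAI index: hierarchical binning, construction, file I/O, region query.

The BAI scheme covers reference coordinates up to 2^29 with a 6-level
bin hierarchy (bin sizes 512 Mb, 64 Mb, 8 Mb, 1 Mb, 128 kb, 16 kb; level
offsets 0, 1, 9, 73, 585, 4681 — 37449 bins in all), plus a linear index
with one virtual offset per 16 kb window giving a lower bound on where
records overlapping that window can start.  Each mapped record is filed
under the smallest bin that fully contains its reference span, as a
*chunk* — a half-open interval of virtual offsets from the record's
start to the next record's start.

Construction may fan out across worker threads (one partial index per
reference, merged in reference order), and is deep-equal for every
worker count by construction.
"""

from __future__ import annotations

import struct
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import IO, Iterator

from .errors import FormatError, LookupMiss, RangeError, SortOrderError

MAX_COORD = 1 << 29
N_BINS = 37449          # real bins 0..37448 across the 6 levels
PSEUDO_BIN = 37450      # metadata pseudo-bin id
WINDOW_SHIFT = 14       # 16384-base linear-index windows
_LEVEL_OFFSETS = (0, 1, 9, 73, 585, 4681)
_LEVEL_SHIFTS = (29, 26, 23, 20, 17, 14)

BAI_MAGIC = b"BAI\x01"


def reg2bin(beg0: int, end0: int) -> int:
    """Smallest bin fully containing the 0-based half-open [beg0, end0)."""
    if not 0 <= beg0 < end0 <= MAX_COORD:
        raise RangeError(f"bad interval [{beg0}, {end0})")
    end = end0 - 1
    for off, shift in zip(reversed(_LEVEL_OFFSETS), reversed(_LEVEL_SHIFTS)):
        if beg0 >> shift == end >> shift:
            return off + (beg0 >> shift)
    return 0


def reg2bins(beg0: int, end0: int) -> list[int]:
    """All bin ids whose interval overlaps [beg0, end0), ascending."""
    if not 0 <= beg0 < end0 <= MAX_COORD:
        raise RangeError(f"bad interval [{beg0}, {end0})")
    end = end0 - 1
    bins = [0]
    for off, shift in zip(_LEVEL_OFFSETS[1:], _LEVEL_SHIFTS[1:]):
        bins.extend(range(off + (beg0 >> shift), off + (end >> shift) + 1))
    return bins


# ---------------------------------------------------------------------------
# index data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Chunk:
    """Half-open interval of packed virtual offsets."""

    beg: int
    end: int


@dataclass
class RefIndex:
    """Per-reference index: bin → chunk list plus the 16 kb linear index."""

    bins: dict[int, list[Chunk]] = field(default_factory=dict)
    linear: list[int] = field(default_factory=list)
    n_mapped: int = 0
    n_unmapped: int = 0
    off_beg: int = 0
    off_end: int = 0

    def is_empty(self) -> bool:
        return not self.bins and not self.linear


@dataclass
class BaiIndex:
    refs: list[RefIndex] = field(default_factory=list)
    n_no_coor: int = 0


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _merge_chunks(chunks: list[Chunk]) -> list[Chunk]:
    """Sort by beg and coalesce overlapping or adjacent chunks."""
    if not chunks:
        return []
    chunks = sorted(chunks)
    merged = [chunks[0]]
    for c in chunks[1:]:
        last = merged[-1]
        if c.beg <= last.end:
            if c.end > last.end:
                merged[-1] = Chunk(last.beg, c.end)
        else:
            merged.append(c)
    return merged


def _build_ref(entries: list[tuple[int, int, int, int, bool]], n_windows: int) -> RefIndex:
    """Index one reference from (pos0, end0, vbeg, vend, mapped) entries."""
    ref = RefIndex()
    bins: dict[int, list[Chunk]] = {}
    linear = [0] * n_windows
    for pos0, end0, vbeg, vend, mapped in entries:
        b = reg2bin(pos0, end0)
        bins.setdefault(b, []).append(Chunk(vbeg, vend))
        for w in range(pos0 >> WINDOW_SHIFT, (end0 - 1 >> WINDOW_SHIFT) + 1):
            if w >= len(linear):
                linear.extend([0] * (w + 1 - len(linear)))
            if linear[w] == 0 or vbeg < linear[w]:
                linear[w] = vbeg
        if mapped:
            ref.n_mapped += 1
        else:
            ref.n_unmapped += 1
    ref.bins = {b: _merge_chunks(cs) for b, cs in sorted(bins.items())}
    # Trim trailing empty windows, then fill interior gaps forward so the
    # array is non-decreasing (a gap window cannot start earlier than the
    # window before it).
    last = -1
    for i, v in enumerate(linear):
        if v:
            last = i
    linear = linear[: last + 1]
    for i in range(1, len(linear)):
        if linear[i] == 0:
            linear[i] = linear[i - 1]
    ref.linear = linear
    if entries:
        ref.off_beg = min(e[2] for e in entries)
        ref.off_end = max(e[3] for e in entries)
    return ref


def build_index(bam_path, workers: int = 1) -> BaiIndex:
    """Build a BAI for a coordinate-sorted BAM.

    A single sequential pass collects each record's span and chunk
    boundaries (a record's chunk ends where the next record begins);
    per-reference binning then runs on up to ``workers`` threads.  The
    result is deep-equal for every worker count.
    """
    from .bamio import BamReader
    from .model import FLAG_UNMAPPED

    with BamReader(bam_path) as reader:
        n_ref = len(reader.references)
        per_ref: list[list[tuple[int, int, int, int, bool]]] = [[] for _ in range(n_ref)]
        n_no_coor = 0
        prev_refid = -2
        prev_pos0 = -1
        seen_refids: set[int] = set()
        pending: tuple[int, int, int, bool, int] | None = None  # refid,pos0,end0,mapped,vbeg
        idx = -1
        for idx, rec in enumerate(reader):
            refid = reader.header.reference_id(rec.rname) if rec.rname != "*" else -1
            mapped = not rec.flag & FLAG_UNMAPPED
            if refid < 0:
                n_no_coor += 1
                pos0 = -1
            else:
                pos0 = rec.pos - 1
                if refid != prev_refid:
                    if refid in seen_refids:
                        raise SortOrderError(
                            f"record {idx}: reference id {refid} reappears; input not sorted"
                        )
                    seen_refids.add(refid)
                    prev_refid = refid
                    prev_pos0 = -1
                if pos0 < prev_pos0:
                    raise SortOrderError(
                        f"record {idx}: position decreases within reference {rec.rname}"
                    )
                prev_pos0 = pos0
            if pending is not None:
                p_refid, p_pos0, p_end0, p_mapped, p_vbeg = pending
                per_ref[p_refid].append((p_pos0, p_end0, p_vbeg, rec.voffset, p_mapped))
            pending = None
            if refid >= 0:
                # '*'-CIGAR placed records get span 1 so they stay indexable.
                ref_len = max(rec.reference_length() if rec.cigar != "*" else 0, 1)
                pending = (refid, pos0, pos0 + ref_len, mapped, rec.voffset)
        if pending is not None:
            end_voffset = reader.tell()
            p_refid, p_pos0, p_end0, p_mapped, p_vbeg = pending
            per_ref[p_refid].append((p_pos0, p_end0, p_vbeg, end_voffset, p_mapped))

    workers = max(1, int(workers))
    if workers == 1:
        refs = [_build_ref(entries, 0) for entries in per_ref]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            refs = list(pool.map(lambda e: _build_ref(e, 0), per_ref))
    return BaiIndex(refs=refs, n_no_coor=n_no_coor)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_bai(index: BaiIndex, sink: IO[bytes] | str) -> None:
    import os

    own = isinstance(sink, (str, os.PathLike))
    fh = open(sink, "wb") if own else sink
    try:
        fh.write(BAI_MAGIC)
        fh.write(struct.pack("<i", len(index.refs)))
        for ref in index.refs:
            n_bin = len(ref.bins) + (0 if ref.is_empty() else 1)
            fh.write(struct.pack("<i", n_bin))
            for b, chunks in ref.bins.items():
                fh.write(struct.pack("<Ii", b, len(chunks)))
                for c in chunks:
                    fh.write(struct.pack("<QQ", c.beg, c.end))
            if not ref.is_empty():
                # Metadata pseudo-bin: offsets chunk + counts chunk.
                fh.write(struct.pack("<Ii", PSEUDO_BIN, 2))
                fh.write(struct.pack("<QQ", ref.off_beg, ref.off_end))
                fh.write(struct.pack("<QQ", ref.n_mapped, ref.n_unmapped))
            fh.write(struct.pack("<i", len(ref.linear)))
            for v in ref.linear:
                fh.write(struct.pack("<Q", v))
        if index.n_no_coor:
            fh.write(struct.pack("<Q", index.n_no_coor))
    finally:
        if own:
            fh.close()


def read_bai(source: IO[bytes] | str) -> BaiIndex:
    import os

    own = isinstance(source, (str, os.PathLike))
    fh = open(source, "rb") if own else source
    try:
        data = fh.read()
    finally:
        if own:
            fh.close()
    if data[:4] != BAI_MAGIC:
        raise FormatError(f"bad BAI magic {data[:4]!r}")
    pos = 4
    (n_ref,) = struct.unpack_from("<i", data, pos)
    pos += 4
    refs = []
    for _ in range(n_ref):
        ref = RefIndex()
        (n_bin,) = struct.unpack_from("<i", data, pos)
        pos += 4
        for _ in range(n_bin):
            b, n_chunk = struct.unpack_from("<Ii", data, pos)
            pos += 8
            chunks = []
            for _ in range(n_chunk):
                beg, end = struct.unpack_from("<QQ", data, pos)
                pos += 16
                chunks.append(Chunk(beg, end))
            if b == PSEUDO_BIN:
                if len(chunks) == 2:
                    ref.off_beg, ref.off_end = chunks[0].beg, chunks[0].end
                    ref.n_mapped, ref.n_unmapped = chunks[1].beg, chunks[1].end
            else:
                ref.bins[b] = chunks
        (n_intv,) = struct.unpack_from("<i", data, pos)
        pos += 4
        ref.linear = list(struct.unpack_from(f"<{n_intv}Q", data, pos))
        pos += 8 * n_intv
        refs.append(ref)
    n_no_coor = 0
    if pos + 8 <= len(data):
        (n_no_coor,) = struct.unpack_from("<Q", data, pos)
    return BaiIndex(refs=refs, n_no_coor=n_no_coor)


# ---------------------------------------------------------------------------
# query
# ---------------------------------------------------------------------------

def query_chunks(index: BaiIndex, refid: int, beg0: int, end0: int) -> list[Chunk]:
    """Chunks that may contain records overlapping [beg0, end0).

    Union of the chunk lists of every overlapping bin, pruned by the
    linear-index lower bound for the query start's window, then merged.
    """
    if not 0 <= refid < len(index.refs):
        raise LookupMiss(f"reference id {refid} not in index")
    ref = index.refs[refid]
    if not ref.bins:
        return []
    min_off = 0
    w = beg0 >> WINDOW_SHIFT
    if ref.linear:
        min_off = ref.linear[min(w, len(ref.linear) - 1)] if w < len(ref.linear) else ref.linear[-1]
    candidates: list[Chunk] = []
    for b in reg2bins(beg0, end0):
        for c in ref.bins.get(b, ()):
            if c.end > min_off:
                candidates.append(c)
    return _merge_chunks(candidates)


def fetch_records(bam_path, index: BaiIndex, rname: str, beg0: int, end0: int) -> Iterator:
    """Yield alignments overlapping [beg0, end0) on ``rname`` via the index.

    Records are overlap-filtered after retrieval; a '*'-CIGAR placed
    record counts as spanning one base.
    """
    from .bamio import BamReader

    with BamReader(bam_path) as reader:
        refid = reader.header.reference_id(rname)
        if refid < 0:
            raise LookupMiss(f"reference {rname!r} not in BAM header")
        for chunk in query_chunks(index, refid, beg0, end0):
            reader.seek(chunk.beg)
            for rec in reader:
                if rec.voffset >= chunk.end:
                    break
                if rec.rname != rname:
                    continue
                pos0 = rec.pos - 1
                if pos0 >= end0:
                    break
                ref_len = max(rec.reference_length() if rec.cigar != "*" else 0, 1)
                if pos0 + ref_len > beg0:
                    yield rec
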