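"""Independent brute-force oracles shared by the acceptance checks.

These deliberately avoid the code paths they validate: binning is done
by scanning an explicit table of all bin intervals, region retrieval by
a full linear scan with the interval-overlap predicate, and depth by
expanding every CIGAR into the exact set of positions it covers.
"""

from __future__ import annotations

import numpy as np

from alnkit.bamio import read_bam
from alnkit.pileup import DEFAULT_FILTER_MASK, Region

_LEVELS = [(0, 29), (1, 26), (9, 23), (73, 20), (585, 17), (4681, 14)]


def bin_table():
    """(lo, hi-exclusive, size) arrays for every real bin id 0..37448."""
    lo = np.empty(37449, dtype=np.int64)
    hi = np.empty(37449, dtype=np.int64)
    size = np.empty(37449, dtype=np.int64)
    for offset, shift in _LEVELS:
        n = 1 << (29 - shift)
        i = np.arange(n)
        lo[offset:offset + n] = i << shift
        hi[offset:offset + n] = (i + 1) << shift
        size[offset:offset + n] = 1 << shift
    return lo, hi, size


_LO, _HI, _SIZE = bin_table()


def oracle_reg2bin(beg: int, end: int) -> int:
    """Smallest containing bin, by scanning every bin interval."""
    containing = np.flatnonzero((_LO <= beg) & (end <= _HI))
    return int(containing[np.argmin(_SIZE[containing])])


def record_spans(bam_path):
    """[(key_fields, rname, pos0, end0)] for overlap arithmetic."""
    _, records = read_bam(bam_path)
    out = []
    for rec in records:
        if rec.rname == "*":
            continue
        pos0 = rec.pos - 1
        ref_len = max(rec.reference_length() if rec.cigar != "*" else 0, 1)
        out.append((rec.key_fields(), rec.rname, pos0, pos0 + ref_len))
    return out


def overlaps_by_scan(spans, rname, beg0, end0):
    return [k for k, rn, p0, e0 in spans if rn == rname and p0 < end0 and e0 > beg0]


def depths_by_cigar_expansion(bam_path, region: Region, mask=DEFAULT_FILTER_MASK):
    """Per-position depth by expanding every record's CIGAR."""
    _, records = read_bam(bam_path)
    depth = [0] * (region.end1 - region.start1 + 1)
    for r in records:
        if r.rname != region.rname or r.flag & mask or r.cigar == "*":
            continue
        pos = r.pos
        for op in r.cigar_ops():
            if op.op in "MDX=":
                for p in range(max(pos, region.start1),
                               min(pos + op.length - 1, region.end1) + 1):
                    depth[p - region.start1] += 1
                pos += op.length
            elif op.op == "N":
                pos += op.length
    return [(region.start1 + i, d) for i, d in enumerate(depth)]
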