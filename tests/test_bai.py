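"""BAI binning, index construction, file I/O and region queries.

The binning oracle enumerates all 37,449 bins as explicit intervals and
scans them, independently of the closed-form bit arithmetic under test.
"""

import random
import subprocess

import numpy as np
import pysam
import pytest

from alnkit.bai import (
    BaiIndex,
    RefIndex,
    build_index,
    fetch_records,
    query_chunks,
    read_bai,
    reg2bin,
    reg2bins,
    write_bai,
)
from alnkit.bamio import read_bam, write_bam
from alnkit.errors import FormatError, LookupMiss, RangeError, SortOrderError
from alnkit.fixtures import FixtureSpec, generate_alignments, generate_reference

_LEVELS = [(0, 29), (1, 26), (9, 23), (73, 20), (585, 17), (4681, 14)]


def _bin_table():
    """(lo, hi-exclusive, size) arrays for every bin id 0..37448."""
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


_LO, _HI, _SIZE = _bin_table()


def oracle_reg2bin(beg: int, end: int) -> int:
    containing = np.flatnonzero((_LO <= beg) & (end <= _HI))
    return int(containing[np.argmin(_SIZE[containing])])


def oracle_reg2bins(beg: int, end: int) -> list[int]:
    return np.flatnonzero((_LO < end) & (_HI > beg)).tolist()


class TestBinning:
    @pytest.mark.parametrize("beg,end,expected", [
        (0, 536870912, 0),
    ])
    def test_root_bin(self, beg, end, expected):
        assert reg2bin(beg, end) == expected

    def test_window_examples_against_oracle(self):
        assert reg2bin(0, 16384) == oracle_reg2bin(0, 16384) == 4681
        assert reg2bin(16384, 32768) == oracle_reg2bin(16384, 32768) == 4682

    def test_reg2bin_matches_brute_force(self):
        rng = random.Random(41)
        for _ in range(10_000):
            beg = rng.randrange(0, 1 << 29)
            end = min(beg + rng.choice([1, 5, 100, 16384, 1 << 20, 1 << 27]), 1 << 29)
            assert reg2bin(beg, end) == oracle_reg2bin(beg, end)

    def test_reg2bins_single_base(self):
        assert reg2bins(0, 1) == [0, 1, 9, 73, 585, 4681]

    def test_reg2bins_full_range_is_all_bins(self):
        # 1 + 8 + 64 + 512 + 4096 + 32768 real bins across the six levels.
        assert reg2bins(0, 1 << 29) == list(range(37449))

    def test_reg2bins_matches_overlap_scan(self):
        rng = random.Random(43)
        for _ in range(300):
            beg = rng.randrange(0, 1 << 29)
            end = min(beg + rng.choice([1, 1000, 1 << 18, 1 << 25]), 1 << 29)
            got = reg2bins(beg, end)
            assert got == oracle_reg2bins(beg, end)
            assert reg2bin(beg, end) in got

    @pytest.mark.parametrize("beg,end", [(-1, 5), (5, 5), (0, (1 << 29) + 1)])
    def test_range_errors(self, beg, end):
        with pytest.raises(RangeError):
            reg2bin(beg, end)
        with pytest.raises(RangeError):
            reg2bins(beg, end)


def brute_force_overlaps(bam_path, rname, beg0, end0):
    """Oracle: full linear scan with the interval-overlap predicate."""
    _, records = read_bam(bam_path)
    out = []
    for rec in records:
        if rec.rname != rname:
            continue
        pos0 = rec.pos - 1
        ref_len = max(rec.reference_length() if rec.cigar != "*" else 0, 1)
        if pos0 < end0 and pos0 + ref_len > beg0:
            out.append(rec.key_fields())
    return out


class TestBuildIndex:
    def test_empty_bam_gives_empty_refs(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=50, n_reads=0))
        index = build_index(fx.bam)
        assert len(index.refs) == 2
        assert all(r.is_empty() for r in index.refs)

    def test_worker_count_invariance(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=51, n_reads=1000))
        indexes = [build_index(fx.bam, workers=w) for w in (1, 2, 4)]
        assert indexes[0] == indexes[1] == indexes[2]

    def test_unsorted_input_rejected_with_record_index(self, tmp_path):
        spec = FixtureSpec(seed=52, n_reads=50, sorted=False)
        header, records = generate_alignments(spec, generate_reference(spec))
        path = tmp_path / "u.bam"
        write_bam(path, header, records)
        with pytest.raises(SortOrderError, match=r"record \d+"):
            build_index(path)

    def test_query_equals_brute_force_scan(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=53, n_reads=400))
        index = build_index(fx.bam)
        rng = random.Random(99)
        for _ in range(200):
            rname, length = ("chr1", 50_000) if rng.random() < 0.5 else ("chr2", 30_000)
            beg = rng.randrange(0, length)
            end = min(beg + rng.choice([1, 50, 500, 20_000]), length)
            got = [r.key_fields() for r in fetch_records(fx.bam, index, rname, beg, end)]
            assert got == brute_force_overlaps(fx.bam, rname, beg, end)

    def test_linear_index_is_non_decreasing(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=54, n_reads=800))
        index = build_index(fx.bam)
        for ref in index.refs:
            assert all(a <= b for a, b in zip(ref.linear, ref.linear[1:]))

    def test_chunks_sorted_and_disjoint(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=55, n_reads=800))
        index = build_index(fx.bam)
        for ref in index.refs:
            for chunks in ref.bins.values():
                assert all(c.beg < c.end for c in chunks)
                assert all(a.end < b.beg for a, b in zip(chunks, chunks[1:]))


class TestBaiFile:
    def test_round_trip_deep_equality(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=56, n_reads=500))
        index = build_index(fx.bam)
        path = str(fx.bam) + ".bai"
        write_bai(index, path)
        assert read_bai(path) == index

    def test_bad_magic(self, tmp_path):
        path = tmp_path / "x.bai"
        path.write_bytes(b"BAM\x01" + b"\x00" * 8)
        with pytest.raises(FormatError):
            read_bai(path)

    def test_empty_two_reference_skeleton_size(self, tmp_path):
        index = BaiIndex(refs=[RefIndex()
                               for _ in range(2)])
        path = tmp_path / "e.bai"
        write_bai(index, path)
        # magic + n_ref, then per reference n_bin + n_intv, all 4 bytes.
        assert path.stat().st_size == 8 + 2 * 8

    def test_query_chunks_empty_index(self):
        index = BaiIndex(refs=[RefIndex()])
        assert query_chunks(index, 0, 0, 1000) == []
        with pytest.raises(LookupMiss):
            query_chunks(index, 3, 0, 1000)


class TestQuerySemantics:
    def test_single_record_chunk_arithmetic(self, tmp_path):
        spec = FixtureSpec(seed=57, n_reads=0)
        header, _ = generate_alignments(spec, generate_reference(spec))
        from alnkit.model import AlignmentRecord

        rec = AlignmentRecord("r1", 0, "chr1", 101, 60, "50M", "*", 0, 0,
                              "A" * 50, "I" * 50)
        path = tmp_path / "one.bam"
        write_bam(path, header, [rec])
        index = build_index(path)
        hits = list(fetch_records(path, index, "chr1", 120, 130))
        assert [r.qname for r in hits] == ["r1"]
        assert list(fetch_records(path, index, "chr1", 200, 300)) == []


class TestExternalTools:
    def test_samtools_accepts_our_bam_and_bai(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=58, n_reads=400))
        index = build_index(fx.bam)
        write_bai(index, str(fx.bam) + ".bai")
        out = subprocess.run(
            ["samtools", "view", str(fx.bam), "chr1:10000-20000"],
            capture_output=True, text=True,
        )
        assert out.returncode == 0, out.stderr
        theirs = [line.split("\t")[0] for line in out.stdout.splitlines()]
        ours = [r.qname for r in fetch_records(fx.bam, index, "chr1", 9999, 20000)]
        assert ours == theirs

    def test_matches_pysam_region_query(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=59, n_reads=400))
        write_bai(build_index(fx.bam), str(fx.bam) + ".bai")
        index = read_bai(str(fx.bam) + ".bai")
        with pysam.AlignmentFile(str(fx.bam), "rb") as bam:
            rng = random.Random(7)
            for _ in range(25):
                beg = rng.randrange(0, 49_000)
                end = beg + rng.choice([10, 1000, 5000])
                theirs = [a.query_name for a in bam.fetch("chr1", beg, end)]
                ours = [r.qname for r in fetch_records(fx.bam, index, "chr1", beg, end)]
                assert ours == theirs
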