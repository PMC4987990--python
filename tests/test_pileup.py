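"""Pileup depths and mpileup token generation.

Depth assertions run against a brute-force oracle that expands every
record's CIGAR into the set of reference positions it covers; mpileup
token output is checked against hand-built expectations on one-read
fixtures and against samtools on a full fixture.
"""

import subprocess

import pytest

from alnkit.bai import build_index, write_bai
from alnkit.bamio import read_bam, write_bam
from alnkit.errors import AlnkitError, LookupMiss, RangeError
from alnkit.fixtures import FixtureSpec, generate_alignments, generate_reference
from alnkit.model import AlignmentRecord, HeaderRecord, SamHeader
from alnkit.pileup import (
    DEFAULT_FILTER_MASK,
    Region,
    mpileup,
    mpileup_text,
    parallel_pileup,
    parse_region,
    simple_pileup,
)


def brute_force_depths(bam_path, region: Region, mask=DEFAULT_FILTER_MASK):
    """Oracle: expand every CIGAR into covered positions and count."""
    _, records = read_bam(bam_path)
    depth = dict.fromkeys(range(region.start1, region.end1 + 1), 0)
    for r in records:
        if r.rname != region.rname or r.flag & mask or r.cigar == "*":
            continue
        pos = r.pos
        for op in r.cigar_ops():
            if op.op in "MDX=":
                for p in range(pos, pos + op.length):
                    if p in depth:
                        depth[p] += 1
                pos += op.length
            elif op.op == "N":
                pos += op.length
    return [(p, depth[p]) for p in sorted(depth)]


def one_read_bam(tmp_path, rec, ref_len=2000, name="t.bam"):
    header = SamHeader([HeaderRecord("SQ", [("SN", "chr1"), ("LN", str(ref_len))])])
    path = tmp_path / name
    write_bam(path, header, [rec])
    return path


class TestRegionParsing:
    def test_basic(self):
        assert parse_region("chr1:100-200") == Region("chr1", 100, 200)

    def test_commas_and_colon_in_name(self):
        assert parse_region("HLA-A:1,000-2,000") == Region("HLA-A", 1000, 2000)

    def test_malformed(self):
        with pytest.raises(RangeError):
            parse_region("chr1")


class TestSimplePileup:
    def test_two_overlapping_reads(self, tmp_path):
        header = SamHeader([HeaderRecord("SQ", [("SN", "chr1"), ("LN", "2000")])])
        reads = [
            AlignmentRecord("a", 0, "chr1", 100, 60, "10M", "*", 0, 0, "A" * 10, "I" * 10),
            AlignmentRecord("b", 0, "chr1", 105, 60, "10M", "*", 0, 0, "A" * 10, "I" * 10),
        ]
        path = tmp_path / "two.bam"
        write_bam(path, header, reads)
        got = dict(simple_pileup(path, "chr1:100-114"))
        for p in range(100, 105):
            assert got[p] == 1
        for p in range(105, 110):
            assert got[p] == 2
        for p in range(110, 115):
            assert got[p] == 1

    def test_empty_bam_gives_zero_depths(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=71, n_reads=0))
        got = list(simple_pileup(fx.bam, "chr1:1-10"))
        assert got == [(p, 0) for p in range(1, 11)]

    def test_unmapped_read_contributes_nothing(self, tmp_path):
        rec = AlignmentRecord("u", 4, "*", 0, 0, "*", "*", 0, 0, "ACGT", "IIII")
        header = SamHeader([HeaderRecord("SQ", [("SN", "chr1"), ("LN", "2000")])])
        path = tmp_path / "u.bam"
        write_bam(path, header, [rec])
        assert all(d == 0 for _, d in simple_pileup(path, "chr1:1-100"))

    def test_filter_mask_excludes_secondary_and_duplicates(self, tmp_path):
        header = SamHeader([HeaderRecord("SQ", [("SN", "chr1"), ("LN", "2000")])])
        reads = [
            AlignmentRecord("p", 0, "chr1", 10, 60, "5M", "*", 0, 0, "A" * 5, "I" * 5),
            AlignmentRecord("s", 0x100, "chr1", 10, 60, "5M", "*", 0, 0, "A" * 5, "I" * 5),
            AlignmentRecord("d", 0x400, "chr1", 10, 60, "5M", "*", 0, 0, "A" * 5, "I" * 5),
        ]
        path = tmp_path / "f.bam"
        write_bam(path, header, reads)
        assert dict(simple_pileup(path, "chr1:10-10"))[10] == 1

    @pytest.mark.parametrize("seed", range(110, 120))
    def test_depths_match_brute_force(self, fixture_factory, seed):
        fx = fixture_factory(FixtureSpec(seed=seed, n_reads=150,
                                         ref_lengths=(20_000, 20_000)))
        region = Region("chr1", 1, 20_000)
        assert list(simple_pileup(fx.bam, region)) == brute_force_depths(fx.bam, region)

    def test_depth_conservation(self, tmp_path):
        """Σ depths == Σ reference-consuming lengths for fully-inside reads."""
        spec = FixtureSpec(seed=72, n_reads=300)
        header, records = generate_alignments(spec, generate_reference(spec))
        path = tmp_path / "c.bam"
        write_bam(path, header, records)
        region = Region("chr1", 1, 50_000)
        total = sum(d for _, d in simple_pileup(path, region))
        expect = sum(
            r.reference_length() for r in records
            if r.rname == "chr1" and not r.flag & DEFAULT_FILTER_MASK
        )
        assert total == expect

    def test_unknown_reference(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=73, n_reads=10))
        with pytest.raises(LookupMiss):
            list(simple_pileup(fx.bam, "chrZ:1-10"))

    def test_inverted_range(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=74, n_reads=10))
        with pytest.raises(RangeError):
            list(simple_pileup(fx.bam, Region("chr1", 50, 10)))


def write_ref(tmp_path, seq, name="chr1"):
    path = tmp_path / "ref.fa"
    lines = [seq[i:i + 60] for i in range(0, len(seq), 60)]
    path.write_text(f">{name}\n" + "".join(l + "\n" for l in lines))
    return path


class TestMpileupTokens:
    def test_perfect_forward_match_renders_dots(self, tmp_path):
        ref = "ACGTACGTACGTACGTACGT" * 10
        fasta = write_ref(tmp_path, ref)
        rec = AlignmentRecord("r", 0, "chr1", 11, 40, "5M", "*", 0, 0,
                              ref[10:15], "IIIII")
        bam = one_read_bam(tmp_path, rec, ref_len=len(ref))
        cols = list(mpileup(bam, Region("chr1", 11, 15), fasta_path=fasta))
        assert [c.bases for c in cols] == ["^I.", ".", ".", ".", ".$"]
        assert [c.ref_base for c in cols] == list(ref[10:15])
        assert all(c.depth == 1 for c in cols)
        assert [c.quals for c in cols] == ["I"] * 5

    def test_reverse_match_renders_commas(self, tmp_path):
        ref = "A" * 100
        fasta = write_ref(tmp_path, ref)
        rec = AlignmentRecord("r", 16, "chr1", 1, 40, "4M", "*", 0, 0, "AAAA", "IIII")
        bam = one_read_bam(tmp_path, rec, ref_len=100)
        cols = list(mpileup(bam, Region("chr1", 1, 4), fasta_path=fasta))
        assert [c.bases for c in cols] == ["^I,", ",", ",", ",$"]

    def test_mismatch_case_follows_strand(self, tmp_path):
        ref = "AAAA" + "C" * 96
        fasta = write_ref(tmp_path, ref)
        fwd = AlignmentRecord("f", 0, "chr1", 1, 40, "2M", "*", 0, 0, "AG", "II")
        rev = AlignmentRecord("v", 16, "chr1", 3, 40, "2M", "*", 0, 0, "GA", "II")
        header = SamHeader([HeaderRecord("SQ", [("SN", "chr1"), ("LN", "100")])])
        bam = tmp_path / "mm.bam"
        write_bam(bam, header, [fwd, rev])
        cols = {c.pos: c.bases for c in mpileup(bam, Region("chr1", 1, 4), fasta_path=fasta)}
        assert cols[2] == "G$"      # forward mismatch: uppercase, read ends here
        assert cols[3] == "^Ig"     # reverse mismatch: lowercase
        assert cols[4] == ",$"      # reverse match

    def test_deletion_tokens(self, tmp_path):
        ref = "ACGTACGTAC" + "G" * 90
        fasta = write_ref(tmp_path, ref)
        rec = AlignmentRecord("r", 0, "chr1", 1, 40, "2M1D2M", "*", 0, 0,
                              ref[0:2] + ref[3:5], "IIII")
        bam = one_read_bam(tmp_path, rec, ref_len=100)
        cols = {c.pos: c for c in mpileup(bam, Region("chr1", 1, 5), fasta_path=fasta)}
        assert cols[2].bases == ".-1" + ref[2]  # deletion annotation on prior position
        assert cols[3].bases == "*"             # the deleted position itself
        assert cols[3].depth == 1               # deletions count toward depth
        assert cols[3].quals == ""              # no quality for a deletion token
        assert cols[4].bases == "."

    def test_insertion_tokens(self, tmp_path):
        ref = "ACGTACGTAC" + "G" * 90
        fasta = write_ref(tmp_path, ref)
        rec = AlignmentRecord("r", 0, "chr1", 1, 40, "2M2I2M", "*", 0, 0,
                              ref[0:2] + "TT" + ref[2:4], "IIIIII")
        bam = one_read_bam(tmp_path, rec, ref_len=100)
        cols = {c.pos: c.bases for c in mpileup(bam, Region("chr1", 1, 4), fasta_path=fasta)}
        assert cols[2] == ".+2TT"

    def test_without_fasta_letters_and_N(self, tmp_path):
        rec = AlignmentRecord("r", 0, "chr1", 5, 40, "3M", "*", 0, 0, "ACG", "III")
        bam = one_read_bam(tmp_path, rec)
        cols = list(mpileup(bam, Region("chr1", 5, 7)))
        assert [c.ref_base for c in cols] == ["N", "N", "N"]
        assert [c.bases for c in cols] == ["^IA", "C", "G$"]

    def test_zero_coverage_positions_omitted_by_default(self, tmp_path):
        rec = AlignmentRecord("r", 0, "chr1", 50, 40, "3M", "*", 0, 0, "ACG", "III")
        bam = one_read_bam(tmp_path, rec)
        cols = list(mpileup(bam, Region("chr1", 1, 100)))
        assert [c.pos for c in cols] == [50, 51, 52]
        all_cols = list(mpileup(bam, Region("chr1", 1, 100), all_positions=True))
        assert [c.pos for c in all_cols] == list(range(1, 101))

    def test_skipped_region_not_covered(self, tmp_path):
        rec = AlignmentRecord("r", 0, "chr1", 1, 40, "2M3N2M", "*", 0, 0, "ACAC", "IIII")
        bam = one_read_bam(tmp_path, rec)
        got = dict(simple_pileup(bam, "chr1:1-7"))
        assert [got[p] for p in range(1, 8)] == [1, 1, 0, 0, 0, 1, 1]


class TestAgainstSamtools:
    def test_mpileup_matches_samtools(self, fixture_factory):
        """Token-for-token agreement with samtools on a fixture.

        The quality column is compared only on deletion-free columns,
        where both emit one char per base token.
        """
        fx = fixture_factory(FixtureSpec(seed=75, n_reads=250))
        write_bai(build_index(fx.bam), str(fx.bam) + ".bai")
        subprocess.run(["samtools", "faidx", fx.fasta], check=True)
        ours = mpileup_text(mpileup(fx.bam, fasta_path=fx.fasta)).splitlines()
        theirs = subprocess.run(
            ["samtools", "mpileup", "-f", fx.fasta, "-B", "-Q", "0", "-x", fx.bam],
            capture_output=True, text=True,
        ).stdout.splitlines()
        assert len(ours) == len(theirs)
        for a, b in zip(ours, theirs):
            fa, fb = a.split("\t"), b.split("\t")
            assert fa[:5] == fb[:5]
            if "*" not in fa[4]:
                assert fa[5] == fb[5]


class TestParallel:
    def _regions(self):
        return [Region("chr1", 1, 20_000), Region("chr1", 20_001, 50_000),
                Region("chr2", 1, 30_000)]

    def test_worker_count_invariance(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=76, n_reads=400))
        outs = {
            w: parallel_pileup(fx.bam, self._regions(), workers=w, fasta_path=fx.fasta)
            for w in (1, 2, 4)
        }
        assert outs[1] == outs[2] == outs[4]

    def test_single_region_equals_mpileup(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=77, n_reads=100))
        region = Region("chr1", 1, 50_000)
        assert parallel_pileup(fx.bam, [region], workers=3) == \
            mpileup_text(mpileup(fx.bam, region))

    def test_empty_region_list(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=78, n_reads=10))
        assert parallel_pileup(fx.bam, [], workers=4) == ""

    def test_overlapping_regions_rejected(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=79, n_reads=10))
        with pytest.raises(AlnkitError):
            parallel_pileup(fx.bam, [Region("chr1", 1, 100), Region("chr1", 50, 200)])


class TestAccessPathInvariance:
    def test_with_and_without_index_agree(self, fixture_factory):
        fx = fixture_factory(FixtureSpec(seed=80, n_reads=300))
        region = Region("chr1", 5_000, 25_000)
        no_index = mpileup_text(mpileup(fx.bam, region, fasta_path=fx.fasta))
        write_bai(build_index(fx.bam), str(fx.bam) + ".bai")
        with_index = mpileup_text(mpileup(fx.bam, region, fasta_path=fx.fasta))
        assert no_index == with_index
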