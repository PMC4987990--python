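# Methods

This note records how alnkit's pieces work, the conventions and
numerical choices behind them, and what the synthetic-data generator
does and does not emulate.

## Coordinate conventions

The in-memory domain model (`alnkit.model`) is 1-based inclusive
throughout, matching SAM text. Exactly two places convert: the BAM
binary codec (`bamio`) maps to/from BAM's 0-based fields, and the BAI
binning code (`bai`) works on 0-based half-open intervals. Region
strings (`name:start-end`) are 1-based inclusive, as users of samtools
expect.

## BGZF layer

Every block is an independent gzip member with the `BC` extra subfield
carrying the on-disk block length minus one. Choices:

* **Write-side payload cap, 65,280 bytes.** The on-disk bound is 65,536
  (16-bit BSIZE); 256 bytes of headroom guarantees that even
  incompressible payloads deflate into the bound, so the writer never
  has to split a block after compressing.
* **Compression level 6** (zlib default), configurable per writer.
  Correctness tests use round-trip equality, never byte-identity of
  compressed output, so the level is a pure speed/size knob.
* **EOF sentinel.** Writers always terminate with the canonical
  28-byte empty block. The reader treats an empty block at
  end-of-stream as EOF, and tolerates a missing sentinel with a logged
  warning, because truncated-but-complete files circulate in practice.
* **Parallel compression** (`BgzfWriter(workers=n)`) deflates queued
  payloads on a thread pool but writes blocks strictly in payload
  order; the output bytes depend only on the payload partition, never
  on the worker count. zlib releases the GIL while deflating, so
  threads are effective here.
* `tell()` at a block boundary reports the *next* block's start
  (uoffset 0) rather than (previous block, payload length). Both
  address the same byte; normalizing keeps virtual offsets recorded
  while streaming strictly increasing, which the index build relies
  on.

## BAM records

* Sequences use the standard 16-symbol nibble code `=ACMGRSVTWYHKDBN`;
  lowercase input is accepted and uppercased (4 bits cannot carry
  case). Missing quality (`*`) is stored as 0xFF bytes.
* Integer optional tags are written as the smallest signed/unsigned
  subtype that fits (`C`, `c`, `S`, `s`, `I`, `i`); on reading they all
  surface as text type `i`, since SAM text has a single integer type.
  Round trips through BAM therefore canonicalize the subtype but never
  the value.
* `rnext` equal to the record's own reference decodes as `=`; -1
  decodes as `*`.
* An unmapped record whose mate is placed is written with the mate's
  refid/pos (the samtools placement convention), so it stays adjacent
  to its mate under coordinate sort.
* Each record's `bin` field is computed as `reg2bin(pos0, pos0 +
  max(ref_len, 1))`; a `*`-CIGAR record is treated as spanning one base
  so it remains indexable.

## BAI construction and query

A single sequential pass records, per mapped-or-placed record, its
reference span and its chunk `[start voffset, next record's start
voffset)`. Binning the collected entries is embarrassingly parallel by
reference: with `workers > 1` each reference's bins and linear index
are built in a thread-pool task and reassembled in reference order, so
the index is deep-equal for every worker count by construction — the
determinism contract the tests pin down.

* The bin hierarchy has six levels (sizes 2^29 … 2^14, offsets 0, 1, 9,
  73, 585, 4681), i.e. 37,449 real bins with ids 0–37448. Bin id 37450
  is the conventional metadata pseudo-bin; it is written (record-offset
  chunk plus mapped/unmapped counts) because mainstream readers expect
  it, and tolerated when absent on read.
* The linear index holds, per 16 kb window, the smallest start voffset
  of any record overlapping the window; interior gaps are filled
  forward so the array is non-decreasing, and trailing empty windows
  are trimmed.
* Chunks within a bin are merged when overlapping or exactly adjacent.
* Queries union the chunk lists of `reg2bins(beg, end)`, drop chunks
  that end at or before the linear-index lower bound for `beg`'s
  window, merge, then overlap-filter the records read from the
  surviving chunks.
* Sortedness is enforced during the scan: a position decrease within a
  reference, or a reference id reappearing after another intervened,
  aborts the build naming the offending record index.
* The trailing count of unplaced reads is written only when nonzero;
  readers treat its absence as zero.

## External merge sort

Input is consumed in chunks of `chunk_records` (default 500,000 — a
memory bound, not a tuning claim), each sorted in memory and spilled as
a temporary BAM run; runs are k-way merged with a heap keyed by
`(sort key, run ordinal, position in run)`, which makes the sort stable
and the output independent of the chunk size. If everything fits in one
chunk no run is spilled at all. Coordinate keys follow samtools:
reference id in header order, then leftmost position; an unmapped read
with a placed mate adopts the mate's coordinate; fully unplaced reads
keep input order at the tail. Queryname order is plain byte order —
the simplest well-defined total order; no numeric-aware splitting.
The output file appears atomically (written to a scratch name, renamed
on success) and temporary runs are removed on any exit path.

## Pileup

Depth counts reads whose reference-consuming CIGAR ops (`M`, `D`, `=`,
`X`) cover the position after the default filter mask 0x704 (unmapped,
secondary, QC-fail, duplicate) — the samtools default, configurable.
Deleted positions (`*`) count toward depth; `N`-skipped stretches do
not. No base-quality floor is applied and BAQ is out of scope.

mpileup token rules: `.`/`,` for strand-wise matches against the
reference, upper/lowercase letters for mismatches, `^` + (MAPQ+33)
character at a read's first covering position, `$` after its last,
`+n<seq>` / `-n<seq>` attached to the position preceding an
insertion/deletion, `*` at each deleted position. Without a FASTA the
reference column is `N` and every aligned base prints as its letter.
Zero-coverage positions are omitted unless `all_positions` is set; the
depth-only `simple_pileup` always reports every position of its region,
zeros included. One deliberate divergence from samtools: quality
characters are emitted only for non-deletion tokens, so the quality
string can be shorter than the depth at columns containing `*`
(samtools repeats a quality there). Everything else matches samtools
token-for-token, which the test suite verifies by direct comparison
against `samtools mpileup -B -Q 0 -x`.

Parallelism is region-level only: each worker renders whole regions and
results concatenate in region order, so output is byte-identical for
any worker count. Regions must be non-overlapping and sorted; overlap
is rejected up front rather than deduplicated.

When a `<bam>.bai` exists next to the input it is used for retrieval,
otherwise a linear scan runs; the access path is checked to never
change the result.

## FASTA / FAI / FASTQ

FAI records `(name, length, offset, linebases, linewidth)` permit
fetching `start..end` via pure offset arithmetic; CRLF files work
because `linewidth` captures the terminator width, and soft-masked
lowercase bases survive fetch. All full lines within a record must
share one width; a short line is only legal as the last line of its
record. Sequence names are the header token up to the first whitespace
(faidx convention). FASTQ is strict 4-line Phred+33; out-of-range
quality characters (e.g. Phred+64-style spaces) are rejected, not
converted.

## Synthetic-data generator

`alnkit.fixtures` emulates the *structure* of single-end short-read
data, not a sequencing platform:

* reads place uniformly over references, positions and strands;
* sequences copy the reference with i.i.d. substitutions
  (default rate 0.01) and at most one short (1–3 bp) insertion or
  deletion per read (default per-read rate 0.02);
* a fraction of reads (default 0.05) is fully unmapped;
* qualities are uniform random Phred 0–40; flags are coherent with
  strand and mapping state; default geometry is two references
  (50 kb + 30 kb), 500 reads of 100 bp.

Defaults were chosen once as small-but-representative values for
exercising CIGAR handling, multi-window binning (references span
several 16 kb windows) and pileup; they are not fitted to any dataset.
All randomness flows from one explicitly seeded generator, so a given
`FixtureSpec` yields byte-identical files on every run. Consequences
for interpretation: passing tests demonstrate format and algorithmic
correctness on valid, single-end, moderately erroneous data; they say
nothing about mate-pair semantics beyond flag decoding, degraded/corrupt
real-world files beyond the explicit error-path tests, or
platform-specific quality structure.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` run 50 seeded fixtures of
150 reads for the round-trip, indexing, pileup and determinism
batteries, 100–200 random region queries per indexed fixture, 10,000
random intervals for the binning oracle, BGZF payloads up to 10 MB,
and one 10,000-record fixture for the external-sort battery (chunk
sizes 10 / 100 / 100,000). These sizes were picked so the whole
verification cycle stays fast enough to run on every change while
still covering multi-block BGZF streams, multi-window bins and
many-run merges.

## Known limitations

* No CRAM, CSI indexes, bgzipped FASTA, or long-CIGAR (`>65535` ops)
  records.
* No mate-pair fixing, duplicate marking, BAQ, or variant calling.
* Queryname sort order is byte-wise, which differs from samtools'
  "natural" ordering of embedded numbers.
* The pileup quality-string convention at deletion columns differs
  from samtools as described above.
* Pure-Python throughput is adequate for the library's intended
  prototyping/testing scale, not for production-scale whole-genome
  BAMs.
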