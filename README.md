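# alnkit

A self-contained, pure-Python toolkit for short-read alignment data in
the SAM/BAM ecosystem. It implements the formats and operations a
sequence-analysis pipeline leans on every day — reading, writing,
converting, normalizing, sorting, indexing and piling up alignments —
from the byte level up, without wrapping samtools, htslib or any other
SAM/BAM API. Index construction and pileup can fan out across worker
threads, with the guarantee that the result is *identical* for every
worker count.

It is aimed at people who need SAM/BAM machinery they can read, hack
and trust in a plain Python environment: method developers prototyping
alignment-level algorithms, teachers walking through how BAM/BAI
actually work, and test engineers who want deterministic synthetic
SAM/BAM data and an independent implementation to cross-check against.

## What is inside

| Layer | What it does |
|---|---|
| `alnkit.bgzf` | BGZF block compression: ≤64 KiB independent gzip members, 64-bit virtual offsets `(coffset << 16) \| uoffset`, random-access reader/writer |
| `alnkit.model` | SAM domain model: headers, alignment records, FLAG predicates, CIGAR algebra, validation, reference-name normalization (`1` → `chr1`) |
| `alnkit.samio` / `alnkit.bamio` | Streaming SAM text and BAM binary I/O (4-bit sequence packing, binary CIGAR words, typed tags) and SAM↔BAM conversion |
| `alnkit.bai` | BAI index: the 6-level binning scheme (`reg2bin`/`reg2bins` over bin sizes 2^29 … 2^14), 16 kb linear index, parallel construction, region→chunk queries |
| `alnkit.sorter` | External merge sort by coordinate or query name with bounded memory |
| `alnkit.pileup` | Per-position depth and samtools-style mpileup text (`.`/`,`, mismatch letters, `*`, `^`/`$`, `+n`/`-n` indel annotations), region-parallel |
| `alnkit.fastx` | FASTA + FAI indexing with O(1) region fetch; FASTQ (Phred+33) |
| `alnkit.fixtures` | Deterministic synthetic reference/read/alignment generator feeding every test |
| `alnkit.cli` | `alnkit view / convert / normalize / sort / index / pileup / faidx / fixtures` |

The two format primitives at the core, in the field's usual notation:

* **Virtual offsets.** A BGZF stream position is addressed by
  `voffset = coffset * 2^16 + uoffset`, where `coffset` is the file
  offset of a compressed block and `uoffset` the offset inside its
  uncompressed payload. Packed values compare exactly like
  `(coffset, uoffset)` pairs, which is what makes a BAI index work.
* **Binning.** A record spanning 0-based half-open `[beg, end)` is filed
  under the smallest bin of the 6-level hierarchy that contains it:
  the familiar `reg2bin` cascade
  `beg>>14 == (end-1)>>14 → 4681 + (beg>>14)`, then `>>17`, `>>20`,
  `>>23`, `>>26`, else bin 0. A region query unions the chunk lists of
  every overlapping bin (`reg2bins`) and prunes with the 16 kb linear
  index before touching the BAM.

## Worked example

Generate a deterministic synthetic dataset, index it, and pile it up:

```bash
$ alnkit fixtures --seed 7 --n-reads 300 demo
demo/ref.fa
demo/reads.sam
demo/reads.bam

$ alnkit faidx demo/ref.fa           # writes demo/ref.fa.fai
$ alnkit index demo/reads.bam        # writes demo/reads.bam.bai

$ alnkit view demo/reads.bam | head -4
@HD	VN:1.6	SO:coordinate
@SQ	SN:chr1	LN:50000
@SQ	SN:chr2	LN:30000
@RG	ID:grp0	SM:sample0

$ alnkit pileup --region chr1:75-75 --fasta demo/ref.fa demo/reads.bam
chr1	75	T	2	,^;.	EA
```

The pileup line reads: on `chr1` position 75 (reference base `T`) two
reads pass the default filter; one reverse-strand read matches the
reference (`,`), and a second read starts here (`^` followed by its
mapping quality `;`, i.e. MAPQ 26) and matches on the forward strand
(`.`); `EA` are the two Phred+33 base qualities. The depth-only view of
the first ten positions of `chr1` (`alnkit pileup --simple --region
chr1:1-10 demo/reads.bam`) prints ten `pos<TAB>depth` lines, zeros
included.

Because the BAM and BAI are written to the published formats, external
tools interoperate directly — `samtools view demo/reads.bam
chr1:75-75` uses our index and returns the same two reads.

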