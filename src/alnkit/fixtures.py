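"""Deterministic synthetic-data generator for references, reads, alignments.

Every test surface in the toolkit is fed by this module: it emits valid
FASTA references, FASTQ reads and SAM/BAM alignment sets from a single
explicitly seeded pseudo-random generator, so the same ``FixtureSpec``
always produces byte-identical files.  The generator emulates the
*structure* of short-read data — uniform read placement, substitution
and short-indel errors, a fraction of unmapped reads, coherent flags —
not platform-realistic error profiles (no quality-by-cycle, no GC bias).
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field as dc_field

from .errors import RangeError
from .model import (
    AlignmentRecord,
    HeaderRecord,
    SamHeader,
)

_BASES = "ACGT"
_FASTA_WIDTH = 60
_MAX_INDEL = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults give a small two-reference genome with 1 % substitution and
    2 % per-read indel rates and 5 % unmapped reads — enough structure to
    exercise CIGAR handling, binning and pileup without bulk.
    """

    seed: int = 0
    n_refs: int = 2
    ref_lengths: tuple[int, ...] = (50_000, 30_000)
    n_reads: int = 500
    read_length: int = 100
    indel_rate: float = 0.02
    mismatch_rate: float = 0.01
    unmapped_fraction: float = 0.05
    sorted: bool = True
    tags: bool = True

    def __post_init__(self):
        for p in (self.indel_rate, self.mismatch_rate, self.unmapped_fraction):
            if not 0.0 <= p <= 1.0:
                raise RangeError(f"probability {p} outside [0, 1]")
        if len(self.ref_lengths) != self.n_refs:
            raise RangeError("ref_lengths must have n_refs entries")
        if any(l <= 0 for l in self.ref_lengths):
            raise RangeError("reference lengths must be positive")
        if self.read_length <= 0:
            raise RangeError("read_length must be positive")


def _ref_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_reference(spec: FixtureSpec) -> str:
    """FASTA text with ``n_refs`` random A/C/G/T sequences, 60 bases/line."""
    rng = random.Random(f"{spec.seed}:ref")
    out = []
    for i in range(spec.n_refs):
        out.append(f">{_ref_name(i)}\n")
        seq = "".join(rng.choice(_BASES) for _ in range(spec.ref_lengths[i]))
        for j in range(0, len(seq), _FASTA_WIDTH):
            out.append(seq[j:j + _FASTA_WIDTH] + "\n")
    return "".join(out)


def _parse_fasta(content: str) -> list[tuple[str, str]]:
    seqs: list[tuple[str, list[str]]] = []
    for line in content.splitlines():
        if line.startswith(">"):
            seqs.append((line[1:].split()[0], []))
        elif line and seqs:
            seqs[-1][1].append(line)
    return [(name, "".join(parts)) for name, parts in seqs]


def _mutate(rng: random.Random, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return rng.choice(choices)


def _random_qual(rng: random.Random, n: int) -> str:
    return "".join(chr(rng.randint(33, 73)) for _ in range(n))


def _make_mapped(
    rng: random.Random, spec: FixtureSpec, rname: str, ref_seq: str, qname: str
) -> AlignmentRecord:
    read_len = spec.read_length
    # Build the CIGAR event list first: mostly one M run, sometimes split
    # by a single short insertion or deletion.
    has_indel = rng.random() < spec.indel_rate and read_len >= 10
    if has_indel:
        is_ins = rng.random() < 0.5
        indel_len = rng.randint(1, _MAX_INDEL)
        split = rng.randint(2, read_len - indel_len - 2) if is_ins else rng.randint(2, read_len - 2)
    max_ref_span = read_len + _MAX_INDEL
    pos = rng.randint(1, len(ref_seq) - max_ref_span + 1)
    seq_parts: list[str] = []
    cigar_parts: list[str] = []
    rpos = pos - 1  # 0-based cursor into ref_seq

    def take_match(n: int) -> None:
        if n <= 0:
            return
        chunk = []
        for b in ref_seq[rpos:rpos + n]:
            if rng.random() < spec.mismatch_rate:
                chunk.append(_mutate(rng, b))
            else:
                chunk.append(b)
        seq_parts.append("".join(chunk))
        cigar_parts.append(f"{n}M")

    if not has_indel:
        take_match(read_len)
        rpos += read_len
    elif is_ins:
        take_match(split)
        rpos += split
        seq_parts.append("".join(rng.choice(_BASES) for _ in range(indel_len)))
        cigar_parts.append(f"{indel_len}I")
        rest = read_len - split - indel_len
        take_match(rest)
        rpos += rest
    else:
        take_match(split)
        rpos += split
        cigar_parts.append(f"{indel_len}D")
        rpos += indel_len
        rest = read_len - split
        take_match(rest)
        rpos += rest

    flag = 16 if rng.random() < 0.5 else 0
    seq = "".join(seq_parts)
    tags = []
    if spec.tags:
        tags = [("RG", "Z", "grp0"), ("XS", "i", rng.randint(-5, 100))]
    return AlignmentRecord(
        qname=qname, flag=flag, rname=rname, pos=pos,
        mapq=rng.randint(20, 60), cigar="".join(cigar_parts),
        rnext="*", pnext=0, tlen=0, seq=seq,
        qual=_random_qual(rng, len(seq)), tags=tags,
    )


def generate_alignments(spec: FixtureSpec, reference: str) -> tuple[SamHeader, list[AlignmentRecord]]:
    """Sample reads from a reference into coherent alignment records.

    Mapped reads place uniformly over references, positions and strands;
    sequences copy the reference with substitutions at ``mismatch_rate``
    and at most one short indel per read at ``indel_rate``.  Every record
    passes validation against the emitted header.
    """
    refs = _parse_fasta(reference)
    if spec.n_reads and not refs:
        raise RangeError("cannot generate reads without references")
    min_len = min((len(s) for _, s in refs), default=0)
    if refs and spec.read_length + _MAX_INDEL > min_len:
        raise RangeError(
            f"read_length {spec.read_length} too long for shortest reference ({min_len})"
        )
    rng = random.Random(f"{spec.seed}:aln")
    records = []
    for i in range(spec.n_reads):
        qname = f"read{i:06d}"
        if rng.random() < spec.unmapped_fraction:
            seq = "".join(rng.choice(_BASES) for _ in range(spec.read_length))
            records.append(AlignmentRecord(
                qname=qname, flag=4, rname="*", pos=0, mapq=0, cigar="*",
                rnext="*", pnext=0, tlen=0, seq=seq,
                qual=_random_qual(rng, spec.read_length), tags=[],
            ))
        else:
            ref_i = rng.randrange(len(refs))
            rname, ref_seq = refs[ref_i]
            records.append(_make_mapped(rng, spec, rname, ref_seq, qname))

    header_records = [HeaderRecord("HD", [("VN", "1.6"), ("SO", "coordinate" if spec.sorted else "unsorted")])]
    for name, seq in refs:
        header_records.append(HeaderRecord("SQ", [("SN", name), ("LN", str(len(seq)))]))
    if spec.tags:
        header_records.append(HeaderRecord("RG", [("ID", "grp0"), ("SM", "sample0")]))
    header = SamHeader(header_records)

    if spec.sorted:
        ref_ids = {name: i for i, (name, _) in enumerate(refs)}
        mapped = [r for r in records if r.rname != "*"]
        unmapped = [r for r in records if r.rname == "*"]
        mapped.sort(key=lambda r: (ref_ids[r.rname], r.pos))
        records = mapped + unmapped
    return header, records


def generate_fastq(spec: FixtureSpec) -> str:
    """FASTQ text of ``n_reads`` random reads (independent of any reference)."""
    rng = random.Random(f"{spec.seed}:fastq")
    out = []
    for i in range(spec.n_reads):
        seq = "".join(rng.choice(_BASES) for _ in range(spec.read_length))
        out.append(f"@read{i:06d}\n{seq}\n+\n{_random_qual(rng, spec.read_length)}\n")
    return "".join(out)


@dataclass
class FixtureFiles:
    fasta: str
    sam: str
    bam: str
    spec: FixtureSpec = dc_field(default_factory=FixtureSpec)


def write_fixture(directory, spec: FixtureSpec) -> FixtureFiles:
    """Materialize a fixture on disk: ref.fa, reads.sam and reads.bam."""
    from .bamio import write_bam
    from .samio import write_sam

    os.makedirs(directory, exist_ok=True)
    fasta_path = os.path.join(directory, "ref.fa")
    sam_path = os.path.join(directory, "reads.sam")
    bam_path = os.path.join(directory, "reads.bam")
    reference = generate_reference(spec)
    with open(fasta_path, "w") as fh:
        fh.write(reference)
    header, records = generate_alignments(spec, reference)
    write_sam(sam_path, header, records)
    write_bam(bam_path, header, records)
    return FixtureFiles(fasta=fasta_path, sam=sam_path, bam=bam_path, spec=spec)
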