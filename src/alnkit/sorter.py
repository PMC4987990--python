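"""External merge sort of SAM/BAM by coordinate or query name.

Input is read in chunks of ``chunk_records`` records; each chunk is
sorted in memory and spilled to a temporary BAM run, then the runs are
k-way merged.  The sort is stable (input ordinal is the final tiebreak)
and the output is independent of the chunk size.

Coordinate order follows samtools conventions: reference id in header
@SQ order, then leftmost position; an unmapped read with a placed mate
sorts at the mate's coordinate; fully unplaced reads go to the tail in
their original order.  Queryname order is plain byte order.
"""

from __future__ import annotations

import heapq
import os
import shutil
import tempfile
from typing import Callable, Iterable, Iterator

from .errors import SortOrderError
from .model import (
    FLAG_FIRST_OF_PAIR,
    FLAG_SECOND_OF_PAIR,
    AlignmentRecord,
    SamHeader,
)

DEFAULT_CHUNK_RECORDS = 500_000

_UNPLACED = float("inf")


def coordinate_key(header: SamHeader) -> Callable[[AlignmentRecord], tuple]:
    ref_ids = {name: i for i, (name, _) in enumerate(header.references)}

    def key(rec: AlignmentRecord) -> tuple:
        if rec.rname != "*":
            return (ref_ids.get(rec.rname, _UNPLACED), rec.pos - 1)
        if rec.rnext not in ("*", "=") and rec.rnext in ref_ids:
            # Unmapped read placed at its mate's coordinate.
            return (ref_ids[rec.rnext], rec.pnext - 1)
        return (_UNPLACED, 0)

    return key


def queryname_key(_header: SamHeader) -> Callable[[AlignmentRecord], tuple]:
    def key(rec: AlignmentRecord) -> tuple:
        # Segment ordinal keeps read-1 before read-2 within a name group.
        ordinal = (
            1 if rec.flag & FLAG_FIRST_OF_PAIR else
            2 if rec.flag & FLAG_SECOND_OF_PAIR else 0
        )
        return (rec.qname.encode("ascii", "surrogateescape"), ordinal)

    return key


_KEYS = {"coordinate": coordinate_key, "queryname": queryname_key}


# ---------------------------------------------------------------------------
# run handling
# ---------------------------------------------------------------------------

def _open_any(path):
    from .bamio import read_bam
    from .samio import read_sam

    if str(path).endswith(".bam"):
        return read_bam(path)
    return read_sam(path)


def _write_any(path, header, records) -> None:
    from .bamio import write_bam
    from .samio import write_sam

    if str(path).endswith(".bam"):
        # Sorting does not validate content; pass records through as-is.
        write_bam(path, header, records, validate=False)
    else:
        write_sam(path, header, records, validate=False)


def merge_sorted_runs(
    runs: list[Iterable[AlignmentRecord]],
    key: Callable[[AlignmentRecord], tuple],
) -> Iterator[AlignmentRecord]:
    """K-way merge of internally sorted record streams.

    Ties break by run ordinal, then within-run order; an out-of-order
    record inside a run is detected mid-merge and raises.
    """
    heap: list[tuple] = []
    iters = [iter(r) for r in runs]
    counters = [0] * len(runs)
    last_key: list[tuple | None] = [None] * len(runs)

    def push(i: int) -> None:
        try:
            rec = next(iters[i])
        except StopIteration:
            return
        k = key(rec)
        if last_key[i] is not None and k < last_key[i]:
            raise SortOrderError(f"run {i} is not sorted (record {counters[i]})")
        last_key[i] = k
        heapq.heappush(heap, (k, i, counters[i], rec))
        counters[i] += 1

    for i in range(len(runs)):
        push(i)
    while heap:
        _, i, _, rec = heapq.heappop(heap)
        yield rec
        push(i)


def _sorted_stream(
    records: Iterable[AlignmentRecord],
    header: SamHeader,
    key: Callable[[AlignmentRecord], tuple],
    chunk_records: int,
    tmp_dir: str,
) -> Iterator[AlignmentRecord]:
    """Spill sorted runs of ``chunk_records`` records, then merge them."""
    from .bamio import read_bam

    run_paths: list[str] = []
    chunk: list[AlignmentRecord] = []

    def spill() -> None:
        chunk.sort(key=key)
        path = os.path.join(tmp_dir, f"run{len(run_paths):05d}.bam")
        _write_any(path, header, chunk)
        run_paths.append(path)
        chunk.clear()

    for rec in records:
        chunk.append(rec)
        if len(chunk) >= chunk_records:
            spill()

    if not run_paths:  # everything fit in memory: no merge needed
        chunk.sort(key=key)
        yield from chunk
        return
    if chunk:
        spill()
    streams = [read_bam(p)[1] for p in run_paths]
    yield from merge_sorted_runs(streams, key)


def sort_file(
    input_path,
    output_path,
    order: str = "coordinate",
    chunk_records: int = DEFAULT_CHUNK_RECORDS,
    tmp_dir: str | None = None,
) -> None:
    """Sort a SAM/BAM file into a SAM/BAM file (formats by extension).

    The output appears atomically: it is written to a scratch name in
    the destination directory and renamed only on success, and the
    temporary runs are removed either way.
    """
    if order not in _KEYS:
        raise ValueError(f"unknown sort order {order!r}")
    if chunk_records < 1:
        raise ValueError("chunk_records must be positive")
    header, records = _open_any(input_path)
    out_header = header.copy()
    out_header.set_sort_order(order)
    key = _KEYS[order](header)
    work = tempfile.mkdtemp(prefix="alnkit-sort-", dir=tmp_dir)
    out_dir = os.path.dirname(os.path.abspath(output_path))
    fd, staging = tempfile.mkstemp(
        prefix=".alnkit-", suffix=os.path.splitext(str(output_path))[1], dir=out_dir
    )
    os.close(fd)
    try:
        stream = _sorted_stream(records, header, key, chunk_records, work)
        _write_any(staging, out_header, stream)
        os.replace(staging, output_path)
    except BaseException:
        if os.path.exists(staging):
            os.unlink(staging)
        raise
    finally:
        shutil.rmtree(work, ignore_errors=True)


def sort_by_coordinate(input_path, output_path,
                       chunk_records: int = DEFAULT_CHUNK_RECORDS,
                       tmp_dir: str | None = None) -> None:
    sort_file(input_path, output_path, "coordinate", chunk_records, tmp_dir)


def sort_by_queryname(input_path, output_path,
                      chunk_records: int = DEFAULT_CHUNK_RECORDS,
                      tmp_dir: str | None = None) -> None:
    sort_file(input_path, output_path, "queryname", chunk_records, tmp_dir)
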