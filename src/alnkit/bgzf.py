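"""BGZF (Blocked GNU Zip Format) codec with virtual-offset random access.

BGZF is the container format underneath BAM: a concatenation of
independent gzip members, each at most 64 KiB on disk, each carrying the
member's total length in a ``BC`` extra subfield so a reader can hop from
block to block without inflating anything.  Because every block is
self-contained, any point in the uncompressed stream can be addressed by
a 64-bit *virtual offset*::

    voffset = (compressed_block_start << 16) | offset_within_uncompressed_block

Virtual offsets are what a BAI index stores; comparing packed values is
the same as comparing (block start, intra-block offset) pairs.

The writer caps payloads at 65280 bytes so that even incompressible data
fits the 65536-byte on-disk bound, and terminates streams with the
canonical 28-byte empty-payload sentinel block.  The reader tolerates a
missing sentinel (it logs a warning) because truncated-but-complete
files occur in the wild.
"""

from __future__ import annotations

import io
import logging
import struct
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import BinaryIO, Iterator

from .errors import CorruptionError, FormatError, RangeError, TruncationError

log = logging.getLogger(__name__)

#: Maximum payload accepted by the write side; leaves 256 bytes of
#: headroom below the 65536 on-disk block bound for header/footer and
#: deflate expansion of incompressible input.
MAX_PAYLOAD = 65280

#: Hard on-disk bound for one block, from the 16-bit BSIZE field.
MAX_BLOCK = 65536

_HEADER = struct.Struct("<4BI2B2B2cH")  # 18 bytes up to and including BSIZE
_HEADER_LEN = 18
_FOOTER_LEN = 8

#: The canonical BGZF end-of-file sentinel: an empty-payload block.
EOF_SENTINEL = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)


@dataclass(frozen=True)
class BgzfBlock:
    """One decoded BGZF block: inflated payload plus its on-disk length."""

    payload: bytes
    bsize: int


# ---------------------------------------------------------------------------
# virtual offsets
# ---------------------------------------------------------------------------

def pack_voffset(coffset: int, uoffset: int) -> int:
    """Pack (compressed block start, intra-block offset) into a 64-bit voffset."""
    if not 0 <= coffset < 1 << 48:
        raise RangeError(f"coffset {coffset} outside [0, 2^48)")
    if not 0 <= uoffset < 1 << 16:
        raise RangeError(f"uoffset {uoffset} outside [0, 2^16)")
    return (coffset << 16) | uoffset


def unpack_voffset(v: int) -> tuple[int, int]:
    """Inverse of :func:`pack_voffset`."""
    if not 0 <= v < 1 << 64:
        raise RangeError(f"virtual offset {v} outside [0, 2^64)")
    return v >> 16, v & 0xFFFF


# ---------------------------------------------------------------------------
# block codec
# ---------------------------------------------------------------------------

def encode_block(payload: bytes, level: int = 6) -> bytes:
    """Compress one payload into a complete BGZF block.

    The result is a gzip member with FEXTRA set and the two-byte BSIZE
    subfield (SI1='B', SI2='C') recording the total block length minus 1.
    """
    if len(payload) > MAX_PAYLOAD:
        raise RangeError(
            f"payload of {len(payload)} bytes exceeds the {MAX_PAYLOAD}-byte cap"
        )
    compressor = zlib.compressobj(level, zlib.DEFLATED, -15)
    deflated = compressor.compress(payload) + compressor.flush()
    bsize = _HEADER_LEN + len(deflated) + _FOOTER_LEN
    if bsize > MAX_BLOCK:  # pragma: no cover - cap makes this unreachable
        raise RangeError(f"compressed block of {bsize} bytes exceeds {MAX_BLOCK}")
    header = _HEADER.pack(
        0x1F, 0x8B, 8, 4,  # magic, deflate, FEXTRA
        0,                 # mtime
        0, 0xFF,           # XFL, OS=unknown
        6, 0,              # XLEN = 6
        b"B", b"C", 2,     # subfield id + SLEN
    ) + struct.pack("<H", bsize - 1)
    footer = struct.pack("<II", zlib.crc32(payload), len(payload) & 0xFFFFFFFF)
    return header + deflated + footer


def decode_block(stream_octets: bytes | memoryview) -> BgzfBlock:
    """Decode the BGZF block starting at offset 0 of ``stream_octets``.

    Returns the inflated payload and the on-disk length, so a caller can
    resume at ``stream_octets[block.bsize:]``.  CRC32 and ISIZE footer
    fields are verified.
    """
    buf = memoryview(stream_octets)
    if len(buf) < _HEADER_LEN:
        raise TruncationError("stream shorter than a BGZF block header")
    if buf[0] != 0x1F or buf[1] != 0x8B:
        raise FormatError("not a gzip member: bad magic bytes")
    if buf[3] & 4 == 0:
        raise FormatError("gzip member lacks FEXTRA; not BGZF")
    xlen = struct.unpack_from("<H", buf, 10)[0]
    if len(buf) < 12 + xlen:
        raise TruncationError("truncated gzip extra field")
    # Scan extra subfields for the BC (BSIZE) entry.
    bsize = None
    pos = 12
    end = 12 + xlen
    while pos + 4 <= end:
        si1, si2, slen = buf[pos], buf[pos + 1], struct.unpack_from("<H", buf, pos + 2)[0]
        if si1 == 0x42 and si2 == 0x43 and slen == 2:
            bsize = struct.unpack_from("<H", buf, pos + 4)[0] + 1
        pos += 4 + slen
    if bsize is None:
        raise FormatError("gzip member has no BC subfield; not BGZF")
    if len(buf) < bsize:
        raise TruncationError(f"block claims {bsize} bytes but only {len(buf)} present")
    deflated = bytes(buf[end:bsize - _FOOTER_LEN])
    crc_stored, isize = struct.unpack_from("<II", buf, bsize - _FOOTER_LEN)
    try:
        payload = zlib.decompress(deflated, -15)
    except zlib.error as exc:
        raise CorruptionError(f"deflate stream corrupt: {exc}") from exc
    if len(payload) != isize:
        raise CorruptionError(f"ISIZE {isize} != inflated length {len(payload)}")
    if zlib.crc32(payload) != crc_stored:
        raise CorruptionError("CRC32 mismatch on inflated payload")
    return BgzfBlock(payload=payload, bsize=bsize)


# ---------------------------------------------------------------------------
# streaming reader / writer
# ---------------------------------------------------------------------------

class BgzfReader:
    """Random-access reader over a BGZF stream.

    ``tell()`` returns a packed virtual offset and ``seek()`` accepts one,
    so positions obtained while scanning a BAM can be revisited after the
    fact — the access pattern a BAI index query needs.
    """

    def __init__(self, fileobj: BinaryIO):
        self._fh = fileobj
        self._block_start = 0     # compressed offset of the loaded block
        self._block: bytes = b""  # inflated payload of the loaded block
        self._block_bsize = 0
        self._within = 0          # cursor inside the inflated payload
        self._eof = False
        self._load_block(0)

    @classmethod
    def open(cls, path) -> "BgzfReader":
        return cls(open(path, "rb"))

    # -- block machinery -------------------------------------------------

    def _load_block(self, coffset: int) -> None:
        self._fh.seek(coffset)
        head = self._fh.read(12)  # fixed gzip header up to XLEN
        if not head:
            self._block_start = coffset
            self._block = b""
            self._block_bsize = 0
            self._within = 0
            self._eof = True
            log.warning("BGZF stream ends without the EOF sentinel block")
            return
        if len(head) < 12:
            raise TruncationError("truncated BGZF block header")
        if head[0] != 0x1F or head[1] != 0x8B:
            raise FormatError("not a BGZF stream: bad gzip magic")
        xlen = struct.unpack_from("<H", head, 10)[0]
        rest_len = None
        extra = self._fh.read(xlen)
        if len(extra) < xlen:
            raise TruncationError("truncated gzip extra field")
        pos = 0
        while pos + 4 <= xlen:
            si1, si2, slen = extra[pos], extra[pos + 1], struct.unpack_from("<H", extra, pos + 2)[0]
            if si1 == 0x42 and si2 == 0x43 and slen == 2:
                rest_len = struct.unpack_from("<H", extra, pos + 4)[0] + 1
            pos += 4 + slen
        if rest_len is None:
            raise FormatError("gzip member has no BC subfield; not BGZF")
        # rest_len is the total block size; 12-byte header + extra consumed.
        body_needed = rest_len - 12 - xlen
        body = self._fh.read(body_needed)
        if len(body) < body_needed:
            raise TruncationError("truncated BGZF block body")
        block = decode_block(head + extra + body)
        self._block_start = coffset
        self._block = block.payload
        self._block_bsize = block.bsize
        self._within = 0
        if not block.payload:
            # Empty payload: the EOF sentinel (or an empty interior block).
            nxt = self._fh.read(1)
            if not nxt:
                self._eof = True
            else:
                self._eof = False
        else:
            self._eof = False

    def _advance_block(self) -> bool:
        """Load the block after the current one; False at end of stream."""
        if self._block_bsize == 0:
            return False
        nxt = self._block_start + self._block_bsize
        self._load_block(nxt)
        if self._eof and not self._block:
            return False
        if not self._block:
            # Interior empty block (e.g. the sentinel mid-scan): keep going.
            return self._advance_block()
        return True

    # -- public API ------------------------------------------------------

    def tell(self) -> int:
        """Virtual offset of the next byte to be read."""
        if self._within == len(self._block) and self._block_bsize and not self._eof:
            # Normalize to the start of the next block so offsets compare
            # correctly across block boundaries.
            return pack_voffset(self._block_start + self._block_bsize, 0)
        return pack_voffset(self._block_start, self._within)

    def seek(self, voffset: int) -> None:
        coffset, uoffset = unpack_voffset(voffset)
        if coffset != self._block_start:
            self._load_block(coffset)
        if uoffset > len(self._block):
            raise RangeError(
                f"uoffset {uoffset} beyond inflated block length {len(self._block)}"
            )
        self._within = uoffset
        self._eof = self._eof and uoffset >= len(self._block)

    def read(self, n: int = -1) -> bytes:
        """Read up to ``n`` uncompressed bytes (all remaining if n < 0)."""
        out = []
        remaining = n
        while remaining != 0:
            avail = len(self._block) - self._within
            if avail == 0:
                if not self._advance_block():
                    break
                continue
            take = avail if remaining < 0 else min(avail, remaining)
            out.append(self._block[self._within:self._within + take])
            self._within += take
            if remaining > 0:
                remaining -= take
        return b"".join(out)

    def read_exact(self, n: int) -> bytes:
        data = self.read(n)
        if len(data) != n:
            raise TruncationError(f"wanted {n} bytes, stream ended after {len(data)}")
        return data

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "BgzfReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class BgzfWriter:
    """Buffered BGZF writer.

    Payload bytes accumulate until the 65280-byte cap, then flush as one
    block.  ``tell()`` reports the virtual offset the next written byte
    will have, which is exactly what BAM encoding needs to hand records'
    addresses to the indexer.

    With ``workers > 1`` pending payloads are deflated on a thread pool;
    blocks are still written strictly in payload order, so the output is
    a deterministic function of the payload partition.
    """

    def __init__(self, fileobj: BinaryIO, level: int = 6, workers: int = 1,
                 _own: bool = False):
        self._fh = fileobj
        self._own = _own
        self._level = level
        self._buf = bytearray()
        self._coffset = 0
        self._closed = False
        self._pending: list[bytes] = []
        self._workers = max(1, int(workers))

    @classmethod
    def open(cls, path, level: int = 6, workers: int = 1) -> "BgzfWriter":
        return cls(open(path, "wb"), level=level, workers=workers, _own=True)

    def tell(self) -> int:
        return pack_voffset(self._coffset, len(self._buf))

    def write(self, data: bytes) -> int:
        self._buf.extend(data)
        while len(self._buf) >= MAX_PAYLOAD:
            chunk = bytes(self._buf[:MAX_PAYLOAD])
            del self._buf[:MAX_PAYLOAD]
            self._queue_block(chunk)
        return len(data)

    def flush_block(self) -> None:
        """Force the current buffer out as a (possibly short) block."""
        if self._buf:
            chunk = bytes(self._buf)
            self._buf.clear()
            self._queue_block(chunk)
        self._drain()

    def _queue_block(self, payload: bytes) -> None:
        self._pending.append(payload)
        if self._workers == 1 or len(self._pending) >= 4 * self._workers:
            self._drain()

    def _drain(self) -> None:
        if not self._pending:
            return
        payloads, self._pending = self._pending, []
        if self._workers > 1 and len(payloads) > 1:
            with ThreadPoolExecutor(max_workers=self._workers) as pool:
                blocks = list(pool.map(lambda p: encode_block(p, self._level), payloads))
        else:
            blocks = [encode_block(p, self._level) for p in payloads]
        for block in blocks:
            self._fh.write(block)
            self._coffset += len(block)

    def close(self) -> None:
        if self._closed:
            return
        self.flush_block()
        self._fh.write(EOF_SENTINEL)
        self._fh.flush()
        if self._own:
            self._fh.close()
        self._closed = True

    def __enter__(self) -> "BgzfWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def compress(data: bytes, level: int = 6, workers: int = 1) -> bytes:
    """Compress ``data`` into a complete, sentinel-terminated BGZF stream."""
    sink = io.BytesIO()
    with BgzfWriter(sink, level=level, workers=workers) as w:
        w.write(data)
    return sink.getvalue()


def decompress(stream: bytes) -> bytes:
    """Inflate a whole BGZF stream (concatenated blocks) to bytes."""
    out = []
    pos = 0
    n = len(stream)
    while pos < n:
        block = decode_block(memoryview(stream)[pos:])
        out.append(block.payload)
        pos += block.bsize
    return b"".join(out)


def iter_blocks(stream: bytes) -> Iterator[tuple[int, BgzfBlock]]:
    """Yield (compressed start offset, block) for each block in a stream."""
    pos = 0
    while pos < len(stream):
        block = decode_block(memoryview(stream)[pos:])
        yield pos, block
        pos += block.bsize
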