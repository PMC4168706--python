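"""Archive format (BRC1), FASTA/FASTQ input, and compression backends.

Layout of an archive::

    magic "BRC1" | version u8 | read_length u16 | num_levels u8
    | genome digest 32 bytes | backend id (u8 length + ASCII)
    | rho f64 | F f64 | genome_length u64 | n_unique u64
    | per level: m u64, h u8, seed_a u64, seed_b u64, n_inserted u64
    | per block: compressed length u64
    | blocks: B1..BL bit streams, FP_L text, FN text

All integers little-endian.  Filter blocks carry the filter's own
serialization (metadata + LSB-first bit data); FP_L and FN are stored as
newline-delimited ASCII sequences.  Every block is compressed
independently by the named backend.
"""

from __future__ import annotations

import gzip
import io
import lzma
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from Bio import SeqIO

from .bloom import BloomFilter
from .containers import Genome, ReadMultiset
from .errors import CorruptArchiveError, UnknownBackendError, ValidationError

MAGIC = b"BRC1"
VERSION = 1

_FIXED = struct.Struct("<4sBHB32s")
_FLOATS = struct.Struct("<ddQQ")
_LEVEL = struct.Struct("<QBQQQ")


@dataclass(frozen=True)
class CompressorBackend:
    """Byte-level compressor contract: decompress(compress(x)) == x."""

    name: str
    compress: Callable[[bytes], bytes]
    decompress: Callable[[bytes], bytes]


_BACKENDS: dict[str, CompressorBackend] = {}


def register_backend(backend: CompressorBackend) -> None:
    _BACKENDS[backend.name] = backend


def get_backend(name: str) -> CompressorBackend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise UnknownBackendError(f"unknown compression backend {name!r}") from None


register_backend(
    CompressorBackend(
        "xz",
        lambda b: lzma.compress(b, preset=6),
        lzma.decompress,
    )
)
register_backend(
    CompressorBackend(
        "zlib",
        lambda b: zlib.compress(b, 9),
        zlib.decompress,
    )
)
register_backend(CompressorBackend("raw", lambda b: b, lambda b: b))

DEFAULT_BACKEND = "xz"


@dataclass
class ArchiveHeader:
    version: int
    read_length: int
    num_levels: int
    genome_digest: bytes
    backend: str
    rho: float
    f_rate: float
    genome_length: int
    n_unique: int
    levels: list[tuple[int, int, int, int, int]]  # (m, h, seed_a, seed_b, n_inserted)
    block_lengths: list[int]


@dataclass
class ArchiveParts:
    """Decompressed content of an archive (or the content about to be written)."""

    read_length: int
    genome_digest: bytes
    rho: float
    f_rate: float
    genome_length: int
    n_unique: int
    filters: list[BloomFilter] = field(default_factory=list)
    fp_last: list[str] = field(default_factory=list)
    fn: list[str] = field(default_factory=list)

    @property
    def num_levels(self) -> int:
        return len(self.filters)


def _block_names(num_levels: int) -> list[str]:
    return [f"B{j}" for j in range(1, num_levels + 1)] + ["FP", "FN"]


def write_archive(parts: ArchiveParts, backend: str = DEFAULT_BACKEND) -> bytes:
    """Serialize parts into a BRC1 byte stream, compressing each block."""
    be = get_backend(backend)
    raw_blocks = [bf.to_bytes() for bf in parts.filters]
    raw_blocks.append("\n".join(parts.fp_last).encode("ascii"))
    raw_blocks.append("\n".join(parts.fn).encode("ascii"))
    names = _block_names(parts.num_levels)
    comp = []
    for name, raw in zip(names, raw_blocks):
        try:
            comp.append(be.compress(raw))
        except Exception as exc:  # pragma: no cover - backend failure path
            raise CorruptArchiveError(f"backend failed compressing block {name}: {exc}")

    out = io.BytesIO()
    out.write(_FIXED.pack(MAGIC, VERSION, parts.read_length, parts.num_levels, parts.genome_digest))
    bid = backend.encode("ascii")
    out.write(struct.pack("<B", len(bid)))
    out.write(bid)
    out.write(_FLOATS.pack(parts.rho, parts.f_rate, parts.genome_length, parts.n_unique))
    for bf in parts.filters:
        out.write(_LEVEL.pack(bf.m, bf.h, bf.seed_a, bf.seed_b, bf.n_inserted))
    for c in comp:
        out.write(struct.pack("<Q", len(c)))
    for c in comp:
        out.write(c)
    return out.getvalue()


def read_header(data: bytes) -> tuple[ArchiveHeader, int]:
    """Parse the header only (stats mode); returns (header, header_size)."""
    if len(data) < _FIXED.size or data[:4] != MAGIC:
        raise CorruptArchiveError("not a BRC1 archive (bad magic)")
    magic, version, read_length, num_levels, digest = _FIXED.unpack_from(data, 0)
    if version != VERSION:
        raise CorruptArchiveError(f"unsupported archive version {version}")
    off = _FIXED.size
    try:
        (blen,) = struct.unpack_from("<B", data, off)
        off += 1
        backend = data[off : off + blen].decode("ascii")
        off += blen
        rho, f_rate, genome_length, n_unique = _FLOATS.unpack_from(data, off)
        off += _FLOATS.size
        levels = []
        for _ in range(num_levels):
            levels.append(_LEVEL.unpack_from(data, off))
            off += _LEVEL.size
        n_blocks = num_levels + 2
        block_lengths = list(struct.unpack_from(f"<{n_blocks}Q", data, off))
        off += 8 * n_blocks
    except struct.error:
        raise CorruptArchiveError("archive header truncated") from None
    header = ArchiveHeader(
        version, read_length, num_levels, digest, backend,
        rho, f_rate, genome_length, n_unique, levels, block_lengths,
    )
    return header, off


def read_archive(data: bytes) -> tuple[ArchiveParts, ArchiveHeader]:
    """Reconstruct filters, FP_L set and FN multiset (order preserved)."""
    header, off = read_header(data)
    be = get_backend(header.backend)
    names = _block_names(header.num_levels)
    blocks = []
    for name, length in zip(names, header.block_lengths):
        chunk = data[off : off + length]
        if len(chunk) != length:
            raise CorruptArchiveError(f"archive truncated in block {name}")
        off += length
        try:
            blocks.append(be.decompress(chunk))
        except Exception as exc:
            raise CorruptArchiveError(f"failed to decompress block {name}: {exc}")
    filters = []
    for j, raw in enumerate(blocks[: header.num_levels], start=1):
        try:
            bf = BloomFilter.from_bytes(raw)
        except ValidationError as exc:
            raise CorruptArchiveError(f"bad filter record in block B{j}: {exc}")
        m, h, sa, sb, n_ins = header.levels[j - 1]
        if (bf.m, bf.h, bf.seed_a, bf.seed_b, bf.n_inserted) != (m, h, sa, sb, n_ins):
            raise CorruptArchiveError(f"block B{j} metadata disagrees with header")
        filters.append(bf)
    fp_text = blocks[header.num_levels].decode("ascii")
    fn_text = blocks[header.num_levels + 1].decode("ascii")
    parts = ArchiveParts(
        read_length=header.read_length,
        genome_digest=header.genome_digest,
        rho=header.rho,
        f_rate=header.f_rate,
        genome_length=header.genome_length,
        n_unique=header.n_unique,
        filters=filters,
        fp_last=fp_text.split("\n") if fp_text else [],
        fn=fn_text.split("\n") if fn_text else [],
    )
    return parts, header


# ---------------------------------------------------------------------------
# Sequence file input/output


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle) -> str:
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValidationError("input is neither FASTA nor FASTQ")


def read_reads(path) -> ReadMultiset:
    """Load read sequences from FASTA or FASTQ (optionally gzipped).

    Names and qualities are ignored; sequences are upper-cased and must
    share one length over the alphabet A/C/G/T/N.
    """
    with _open_maybe_gzip(path) as fh:
        fmt = _sniff_format(fh)
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]
    return ReadMultiset(seqs)


def read_genome(path) -> Genome:
    """Load a (multi-contig) reference genome from FASTA."""
    with _open_maybe_gzip(path) as fh:
        fmt = _sniff_format(fh)
        if fmt != "fasta":
            raise ValidationError("reference genome must be FASTA")
        contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]
    if not contigs:
        raise ValidationError(f"no sequences found in {path}")
    return Genome(contigs)


def write_reads(reads: ReadMultiset, path, fmt: str = "fasta") -> None:
    """Write decoded reads with synthetic identifiers (FASTA or plain text)."""
    path = Path(path)
    with open(path, "wt") as fh:
        if fmt == "fasta":
            for i, r in enumerate(reads.reads, start=1):
                fh.write(f">read_{i}\n{r}\n")
        elif fmt == "txt":
            for r in reads.reads:
                fh.write(r + "\n")
        else:
            raise ValidationError(f"unknown output format {fmt!r}")


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads, path) -> None:
    """Reads with dummy qualities ('I' throughout)."""
    with open(path, "wt") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f"@read_{i}\n{r}\n+\n{'I' * len(r)}\n")
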