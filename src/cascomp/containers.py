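"""In-memory containers: the read multiset and the reference genome."""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

READ_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 lookup tables for vectorised work on sequences.
_RC_TABLE = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[_x] = _y
_IS_ACGT = np.zeros(256, dtype=bool)
for _x in b"ACGT":
    _IS_ACGT[_x] = True


def revcomp(seq: str) -> str:
    """Reverse complement (A<->T, C<->G, N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def revcomp_u8(arr: np.ndarray) -> np.ndarray:
    return _RC_TABLE[arr][::-1]


def acgt_mask(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of positions holding a plain A/C/G/T base."""
    return _IS_ACGT[arr]


class ReadMultiset:
    """Fixed-length reads with multiplicities.

    Exact reconstruction of this object (as a multiset: order, names and
    qualities are not part of it) is what losslessness means here.
    """

    __slots__ = ("reads", "read_length")

    def __init__(self, reads: Iterable[str], read_length: int | None = None):
        reads = [r.upper() for r in reads]
        if reads:
            length = len(reads[0])
            if length == 0:
                raise ValidationError("reads must be non-empty strings")
            for r in reads:
                if len(r) != length:
                    raise ValidationError(
                        f"mixed read lengths: {length} vs {len(r)}"
                    )
                if not READ_ALPHABET.issuperset(r):
                    bad = set(r) - READ_ALPHABET
                    raise ValidationError(f"invalid read characters: {sorted(bad)}")
        else:
            length = 0
        if read_length is not None and reads and read_length != length:
            raise ValidationError(
                f"declared read length {read_length} != observed {length}"
            )
        self.reads = reads
        self.read_length = length if reads else (read_length or 0)

    def counts(self) -> Counter:
        return Counter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def multiset_equal(self, other: "ReadMultiset") -> bool:
        return Counter(self.reads) == Counter(other.reads)

    def __repr__(self) -> str:
        return f"ReadMultiset(n={len(self.reads)}, read_length={self.read_length})"


@dataclass
class Genome:
    """Reference genome as named, upper-cased contigs.

    The SHA-256 digest covers contig names and sequences, so decode can
    refuse a mismatched reference outright.
    """

    contigs: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_string(cls, seq: str, name: str = "seq1") -> "Genome":
        return cls([(name, seq.upper())])

    @property
    def length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    @property
    def digest(self) -> bytes:
        d = hashlib.sha256()
        for name, seq in self.contigs:
            d.update(name.encode("utf-8"))
            d.update(b"\x00")
            d.update(seq.encode("ascii"))
            d.update(b"\x00")
        return d.digest()


def as_genome(obj) -> Genome:
    if isinstance(obj, Genome):
        return obj
    if isinstance(obj, str):
        return Genome.from_string(obj)
    raise ValidationError(f"cannot interpret {type(obj)!r} as a genome")


def as_read_multiset(obj) -> ReadMultiset:
    if isinstance(obj, ReadMultiset):
        return obj
    if isinstance(obj, Sequence):
        return ReadMultiset(obj)
    raise ValidationError(f"cannot interpret {type(obj)!r} as reads")
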