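"""Seeded, serializable Bloom filter and its false-positive-rate algebra.

A Bloom filter is a bit array of m bits with h hash functions.  Inserting
an element sets the h addressed bits; querying checks them.  A filter of
m bits holding n elements has false-positive rate

    F ~ (1 - exp(-h*n/m))**h,

minimised over real h at h = ln(2) * m/n, where it equals c**(m/n) with
c = 2**(-ln 2) ~ 0.6185.  These closed forms drive the sizing of every
level of the cascade.

Hashing uses double hashing over two seeded 64-bit hashes of the raw
upper-case ASCII element bytes: position_i = (h_a + i*h_b) mod m.  The
two seeds fully determine the filter's behaviour, so archives rebuild
bit-identical filters.
"""

from __future__ import annotations

import math
import struct

import numpy as np

from ._hashing import digest_matrix, mix_digest, raw_digests, strings_to_matrix
from .errors import ValidationError

__all__ = [
    "OPTIMAL_BASE",
    "MIN_FILTER_BITS",
    "BloomFilter",
    "fpr",
    "optimal_h",
    "required_bits",
]

#: c = 2**(-ln 2): per-element base of the optimal false-positive rate F = c**rho.
OPTIMAL_BASE = 2.0 ** (-math.log(2.0))

#: Filters never shrink below this, so degenerate cascade levels (n=0) still
#: serialize as a well-formed bit array.
MIN_FILTER_BITS = 64

DEFAULT_SEEDS = (0x243F6A8885A308D3, 0x13198A2E03707344)

_HEADER_STRUCT = struct.Struct("<QBQQQ")  # m, h, seed_a, seed_b, n_inserted


def fpr(m: int, n: int, h: int) -> float:
    """False-positive rate (1 - e^(-hn/m))^h of an (m, h) filter holding n."""
    if m < 1 or n < 0 or h < 1:
        raise ValidationError(f"invalid Bloom parameters m={m}, n={n}, h={h}")
    if n == 0:
        return 0.0
    return float((-math.expm1(-h * n / m)) ** h)


def optimal_h(m: int, n: int) -> float:
    """Real-valued h minimising the false-positive rate: ln(2) * m / n."""
    if m < 1 or n < 1:
        raise ValidationError(f"invalid Bloom parameters m={m}, n={n}")
    return math.log(2.0) * m / n


def required_bits(n: int, F: float, h: int) -> int:
    """Smallest m with fpr(m, n, h) <= F (floored at MIN_FILTER_BITS)."""
    if not 0.0 < F < 1.0:
        raise ValidationError(f"target false-positive rate must be in (0,1), got {F}")
    if n < 0 or h < 1:
        raise ValidationError(f"invalid Bloom parameters n={n}, h={h}")
    if n == 0:
        return MIN_FILTER_BITS
    root = F ** (1.0 / h)
    m = math.ceil(-h * n / math.log1p(-root))
    # Guard the closed form against floating-point rounding.
    while fpr(m, n, h) > F:
        m += 1
    while m > 1 and fpr(m - 1, n, h) <= F:
        m -= 1
    return max(m, MIN_FILTER_BITS)


class BloomFilter:
    """Bit-array membership structure with two stored 64-bit hash seeds.

    Elements are hashed as their raw ASCII bytes.  The vectorised
    ``*_digests`` methods operate on precomputed base digests (see
    :mod:`cascomp._hashing`) and are what the encoder and decoder use for
    bulk loads and whole-genome query sweeps.
    """

    __slots__ = ("m", "h", "seed_a", "seed_b", "bits", "n_inserted")

    def __init__(self, m: int, h: int, seeds: tuple[int, int] = DEFAULT_SEEDS):
        if m < 1:
            raise ValidationError(f"filter size must be positive, got m={m}")
        if h < 1:
            raise ValidationError(f"need at least one hash function, got h={h}")
        self.m = int(m)
        self.h = int(h)
        self.seed_a = int(seeds[0]) & (2**64 - 1)
        self.seed_b = int(seeds[1]) & (2**64 - 1)
        self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)
        self.n_inserted = 0

    # -- scalar path ---------------------------------------------------

    @staticmethod
    def _as_bytes(element) -> bytes:
        if isinstance(element, str):
            element = element.encode("ascii")
        if not isinstance(element, (bytes, bytearray)):
            raise ValidationError(f"element must be str or bytes, got {type(element)!r}")
        if len(element) == 0:
            raise ValidationError("cannot hash an empty element")
        return bytes(element)

    def _positions(self, element) -> list[int]:
        ra, rb = raw_digests(self._as_bytes(element))
        a = mix_digest(ra, self.seed_a)
        b = mix_digest(rb, self.seed_b) | 1
        return [(a + i * b) % self.m for i in range(self.h)]

    def insert(self, element) -> "BloomFilter":
        """Insert one element; returns the (mutated) filter."""
        for pos in self._positions(element):
            self.bits[pos >> 3] |= np.uint8(1 << (pos & 7))
        self.n_inserted += 1
        return self

    def query(self, element) -> bool:
        """True iff all h addressed bits are set (never false for inserted)."""
        for pos in self._positions(element):
            if not (self.bits[pos >> 3] >> (pos & 7)) & 1:
                return False
        return True

    __contains__ = query

    # -- vectorised path ------------------------------------------------

    def _hash_pairs(self, raw_a: np.ndarray, raw_b: np.ndarray):
        a = mix_digest(raw_a, self.seed_a)
        b = mix_digest(raw_b, self.seed_b) | np.uint64(1)
        return a, b

    def insert_digests(self, raw_a: np.ndarray, raw_b: np.ndarray) -> None:
        """Bulk insert elements given their precomputed base digests."""
        if raw_a.size == 0:
            return
        a, b = self._hash_pairs(raw_a, raw_b)
        m = np.uint64(self.m)
        for i in range(self.h):
            pos = (a + np.uint64(i) * b) % m
            byte_idx = (pos >> np.uint64(3)).astype(np.int64)
            masks = (np.uint64(1) << (pos & np.uint64(7))).astype(np.uint8)
            np.bitwise_or.at(self.bits, byte_idx, masks)
        self.n_inserted += int(raw_a.size)

    def query_digests(self, raw_a: np.ndarray, raw_b: np.ndarray) -> np.ndarray:
        """Bulk membership test; returns a boolean array."""
        if raw_a.size == 0:
            return np.zeros(0, dtype=bool)
        a, b = self._hash_pairs(raw_a, raw_b)
        m = np.uint64(self.m)
        ok = np.ones(raw_a.size, dtype=bool)
        for i in range(self.h):
            pos = (a + np.uint64(i) * b) % m
            byte = self.bits[(pos >> np.uint64(3)).astype(np.int64)]
            shift = (pos & np.uint64(7)).astype(np.uint8)
            ok &= ((byte >> shift) & np.uint8(1)).astype(bool)
        return ok

    def insert_strings(self, strings, length: int) -> None:
        mat = strings_to_matrix(strings, length)
        self.insert_digests(*digest_matrix(mat))

    # -- introspection / serialization ----------------------------------

    @property
    def popcount(self) -> int:
        return int(np.unpackbits(self.bits).sum())

    def to_bytes(self) -> bytes:
        """m u64, h u8, seeds 2x u64, n_inserted u64, then LSB-first bit data."""
        head = _HEADER_STRUCT.pack(self.m, self.h, self.seed_a, self.seed_b, self.n_inserted)
        return head + self.bits.tobytes()

    @classmethod
    def from_bytes(cls, data: bytes) -> "BloomFilter":
        if len(data) < _HEADER_STRUCT.size:
            raise ValidationError("Bloom filter record truncated")
        m, h, sa, sb, n_ins = _HEADER_STRUCT.unpack_from(data, 0)
        nbytes = (m + 7) // 8
        body = data[_HEADER_STRUCT.size : _HEADER_STRUCT.size + nbytes]
        if len(body) != nbytes:
            raise ValidationError("Bloom filter bit data truncated")
        bf = cls(m, h, (sa, sb))
        bf.bits = np.frombuffer(body, dtype=np.uint8).copy()
        bf.n_inserted = n_ins
        return bf

    def __eq__(self, other) -> bool:
        if not isinstance(other, BloomFilter):
            return NotImplemented
        return (
            self.m == other.m
            and self.h == other.h
            and self.seed_a == other.seed_a
            and self.seed_b == other.seed_b
            and self.n_inserted == other.n_inserted
            and bool(np.array_equal(self.bits, other.bits))
        )

    def __repr__(self) -> str:
        return f"BloomFilter(m={self.m}, h={self.h}, n_inserted={self.n_inserted})"
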