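"""Seeded 64-bit string hashing shared by every Bloom filter.

Two independent base digests of an element's bytes are computed with
multiply-add chains (distinct odd multipliers, arithmetic mod 2**64).
Each filter then derives its own pair of hash values by xoring the base
digests with its two stored seeds and applying a splitmix64 finalizer;
double hashing expands that pair into h array positions.

Splitting the work this way means the expensive part -- digesting the
element bytes -- is done once per element and is vectorisable over both
read matrices and sliding genome windows, while per-filter seeding stays
a handful of cheap word operations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

MASK64 = (1 << 64) - 1

# Odd multipliers for the two digest chains (golden-ratio and xxhash-style
# constants; any pair of large odd 64-bit numbers would do).
POLY_A = 0x9E3779B97F4A7C15
POLY_B = 0xC2B2AE3D27D4EB4F

_SM_M1 = 0xBF58476D1CE4E5B9
_SM_M2 = 0x94D049BB133111EB


def splitmix64(z: int) -> int:
    """Finalizer of the splitmix64 generator; a strong 64-bit bit mixer."""
    z &= MASK64
    z ^= z >> 30
    z = (z * _SM_M1) & MASK64
    z ^= z >> 27
    z = (z * _SM_M2) & MASK64
    return z ^ (z >> 31)


def derive_seed(master: int, index: int) -> int:
    """Deterministic stream of 64-bit seeds from one master seed."""
    return splitmix64((master + (index + 1) * POLY_A) & MASK64)


def raw_digests(data: bytes) -> tuple[int, int]:
    """Scalar base digests of a byte string (reference path)."""
    ha = hb = 0
    for b in data:
        ha = (ha * POLY_A + b) & MASK64
        hb = (hb * POLY_B + b) & MASK64
    return ha, hb


def _mix_array(z: np.ndarray, seed: int) -> np.ndarray:
    z = z ^ np.uint64(seed)
    z ^= z >> np.uint64(30)
    z *= np.uint64(_SM_M1)
    z ^= z >> np.uint64(27)
    z *= np.uint64(_SM_M2)
    return z ^ (z >> np.uint64(31))


def mix_digest(raw, seed: int):
    """splitmix64(raw ^ seed); accepts a scalar int or a uint64 ndarray."""
    if isinstance(raw, np.ndarray):
        return _mix_array(raw.astype(np.uint64, copy=True), seed)
    return splitmix64((int(raw) ^ seed) & MASK64)


def strings_to_matrix(strings: Sequence[str], length: int) -> np.ndarray:
    """Pack equal-length ASCII strings into an (n, length) uint8 matrix."""
    if not strings:
        return np.empty((0, max(length, 0)), dtype=np.uint8)
    buf = "".join(strings).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(strings), length)


def digest_matrix(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Base digests for each row of an (n, length) uint8 matrix.

    Bit-identical to :func:`raw_digests` applied row by row.
    """
    n, length = mat.shape
    ha = np.zeros(n, dtype=np.uint64)
    hb = np.zeros(n, dtype=np.uint64)
    pa, pb = np.uint64(POLY_A), np.uint64(POLY_B)
    for k in range(length):
        col = mat[:, k].astype(np.uint64)
        ha *= pa
        ha += col
        hb *= pb
        hb += col
    return ha, hb


def digest_windows(seq: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Base digests of every `length`-window of a uint8 sequence array.

    Returns arrays of length ``len(seq) - length + 1`` matching
    :func:`raw_digests` on each window's bytes.
    """
    g = seq.shape[0]
    nw = g - length + 1
    if nw <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty.copy()
    ha = np.zeros(nw, dtype=np.uint64)
    hb = np.zeros(nw, dtype=np.uint64)
    pa, pb = np.uint64(POLY_A), np.uint64(POLY_B)
    for k in range(length):
        col = seq[k : k + nw].astype(np.uint64)
        ha *= pa
        ha += col
        hb *= pb
        hb += col
    return ha, hb


def digest_strings(strings: Sequence[str], length: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised base digests for a list of equal-length strings."""
    return digest_matrix(strings_to_matrix(strings, length))
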