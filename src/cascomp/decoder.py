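"""Decoding: rebuild the read multiset from an archive and the reference.

Every read-length window of the genome (both strands) is pushed through
the filter cascade.  A window rejected first at an even level is a real
read; rejected first at an odd level, a fake.  A window accepted by all
L levels is resolved by the explicitly stored residual list: for even L
it is real iff it is in FP_L, for odd L real iff it is not.  Window
strings classified real are added once each (set semantics, mirroring
the encoder); FN is appended at its stored multiplicity.

Given the encoder's exact set constructions the classification is exact:
the genome-derived additions are precisely R' intersected with P, so the
output equals the original multiset independently of hash seeds and of
how many false positives the filters produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Genome, ReadMultiset, as_genome
from .container_io import ArchiveParts, read_archive
from .encoder import _strand_sequences, _window_sweep
from .errors import DigestMismatchError, ValidationError

__all__ = ["CascadeVerdict", "cascade_verdict", "classify", "decode", "verify"]


@dataclass(frozen=True)
class CascadeVerdict:
    """Outcome of pushing one window through the cascade."""

    first_reject_level: int | None  # 1-based; None when all levels accept
    in_fp_last: bool  # meaningful only when first_reject_level is None
    num_levels: int

    @property
    def is_real(self) -> bool:
        if self.first_reject_level is not None:
            return self.first_reject_level % 2 == 0
        if self.num_levels % 2 == 0:
            return self.in_fp_last
        return not self.in_fp_last


def cascade_verdict(q: str, filters, fp_last: set) -> CascadeVerdict:
    """Scalar classification of one window string."""
    for j, bf in enumerate(filters, start=1):
        if not bf.query(q):
            return CascadeVerdict(j, False, len(filters))
    return CascadeVerdict(None, q in fp_last, len(filters))


def classify(q: str, filters, fp_last: set) -> bool:
    """True iff the cascade classifies window q as a real read."""
    return cascade_verdict(q, filters, fp_last).is_real


def _real_windows(parts: ArchiveParts, genome: Genome) -> set:
    """Vectorised cascade sweep; returns the set of windows classified real."""
    l_read = parts.read_length
    filters = parts.filters
    L = len(filters)
    fp_last = set(parts.fp_last)
    real: set = set()
    for strand_seq in _strand_sequences(genome):
        if len(strand_seq) < l_read:
            continue
        valid, ha, hb = _window_sweep(strand_seq, l_read)
        alive = valid & filters[0].query_digests(ha, hb)
        idx = np.nonzero(alive)[0]
        sub_a, sub_b = ha[idx], hb[idx]
        for j in range(2, L + 1):
            if idx.size == 0:
                break
            acc = filters[j - 1].query_digests(sub_a, sub_b)
            if j % 2 == 0:
                for i in idx[~acc]:
                    real.add(strand_seq[i : i + l_read])
            idx = idx[acc]
            sub_a = sub_a[acc]
            sub_b = sub_b[acc]
        # Survivors of all L levels: resolved by the residual list.
        want_member = L % 2 == 0
        for i in idx:
            w = strand_seq[i : i + l_read]
            if (w in fp_last) == want_member:
                real.add(w)
    return real


def decode(archive, genome) -> ReadMultiset:
    """Reconstruct the exact read multiset from archive bytes (or parts)."""
    if isinstance(archive, (bytes, bytearray)):
        parts, _ = read_archive(bytes(archive))
    elif isinstance(archive, ArchiveParts):
        parts = archive
    else:
        raise ValidationError(f"cannot decode {type(archive)!r}")
    genome = as_genome(genome)
    if parts.genome_digest != genome.digest:
        raise DigestMismatchError(
            "archive was encoded against a different reference genome"
        )
    if parts.read_length == 0:
        return ReadMultiset([])
    real = _real_windows(parts, genome)
    reads = list(parts.fn) + sorted(real)
    return ReadMultiset(reads)


def verify(original, decoded) -> bool:
    """Multiset equality of two read collections (order-insensitive)."""
    from .containers import as_read_multiset

    a = as_read_multiset(original)
    b = as_read_multiset(decoded)
    return a.multiset_equal(b)
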