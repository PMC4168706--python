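"""Encoding: partition reads, load the cascade, emit residual sets.

The scheme stores each unique, N-free read in a first Bloom filter B1 and
recovers reads at decode time by querying B1 with every read-length window
of the reference genome, on both strands.  Whatever the filter cannot
represent exactly is carried explicitly:

* FN -- reads that the genome scan cannot produce: repeated reads (kept at
  full multiplicity), reads containing N, and unique reads lost to
  sequencing errors or donor mutations (R' \\ P);
* FP1 -- genome windows the filter wrongly accepts (P \\ R').

Deeper filters then store each other's false positives (B2 holds FP1, B3
holds FP2 = R' accepted by B2, B4 holds FP3 = FP1 accepted by B3), so only
the residual list after the last level (FP4 by default) is written out.
The subset chain FP2 within R', FP3 within FP1, FP4 within FP2 makes the
decode-time parity rule exact regardless of hash collisions.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np

from ._hashing import digest_strings, digest_windows
from .bloom import BloomFilter
from .containers import (
    Genome,
    ReadMultiset,
    acgt_mask,
    as_genome,
    as_read_multiset,
    revcomp,
    seq_to_u8,
)
from .container_io import ArchiveParts, write_archive
from .errors import ValidationError
from .params import (
    DEFAULT_MASTER_SEED,
    DEFAULT_SIZE_CAP,
    CascadeParams,
    plan_cascade,
)

__all__ = [
    "partition_reads",
    "scan_genome",
    "encode_one",
    "build_cascade",
    "encode",
]


def partition_reads(reads) -> tuple[set, list]:
    """Split reads into unique N-free reads R' and the initial FN multiset.

    FN holds every copy of every read occurring at least twice, plus every
    read containing N, in first-occurrence stream order.
    """
    rm = as_read_multiset(reads)
    if len(rm) == 0:
        raise ValidationError("cannot partition an empty read set")
    counts = rm.counts()
    r_prime = {r for r, c in counts.items() if c == 1 and "N" not in r}
    fn0 = [r for r in rm.reads if counts[r] > 1 or "N" in r]
    return r_prime, fn0


def _window_sweep(strand_seq: str, l_read: int):
    """Valid-window mask and base digests for one strand of one contig."""
    arr = seq_to_u8(strand_seq)
    nw = len(strand_seq) - l_read + 1
    good = acgt_mask(arr).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(good)))
    valid = (csum[l_read : l_read + nw] - csum[:nw]) == l_read
    ha, hb = digest_windows(arr, l_read)
    return valid, ha, hb


def _strand_sequences(genome: Genome):
    for name, seq in genome.contigs:
        yield seq
        yield revcomp(seq)


def scan_genome(genome, l_read: int, accept) -> set:
    """Distinct read-length windows of the genome (both strands) accepted.

    ``accept`` is either a BloomFilter (vectorised sweep) or any predicate
    on window strings.  Windows containing non-ACGT symbols are skipped,
    and windows never span contigs.  Set semantics: a string reachable
    from several positions or both strands counts once.
    """
    genome = as_genome(genome)
    if l_read < 1:
        raise ValidationError(f"read length must be positive, got {l_read}")
    if not any(len(seq) >= l_read for _, seq in genome.contigs):
        raise ValidationError(
            f"no contig is at least the read length ({l_read}) long"
        )
    use_filter = isinstance(accept, BloomFilter)
    P: set = set()
    for strand_seq in _strand_sequences(genome):
        if len(strand_seq) < l_read:
            continue
        valid, ha, hb = _window_sweep(strand_seq, l_read)
        if use_filter:
            hits = accept.query_digests(ha, hb)
            hits &= valid
            for i in np.nonzero(hits)[0]:
                P.add(strand_seq[i : i + l_read])
        else:
            for i in np.nonzero(valid)[0]:
                w = strand_seq[i : i + l_read]
                if accept(w):
                    P.add(w)
    return P


class EncodeOneResult(NamedTuple):
    b1: BloomFilter
    fn: list
    fp1: set
    r_prime: set
    accepted: set


def encode_one(reads, genome, params: CascadeParams | None = None) -> EncodeOneResult:
    """Single-filter encoding: load B1 with R', scan the genome, split residues.

    Returns B1, the full FN multiset (initial FN plus unique reads not
    recoverable from the scan) and FP1 = P \\ R'.
    """
    rm = as_read_multiset(reads)
    genome = as_genome(genome)
    r_prime, _ = partition_reads(rm)
    counts = rm.counts()
    if params is None:
        params = plan_cascade(genome.length, max(len(r_prime), 1))
    lvl = params.with_actual_count(1, len(r_prime))
    b1 = BloomFilter(lvl.m, lvl.h, (lvl.seed_a, lvl.seed_b))
    r_list = sorted(r_prime)
    b1.insert_strings(r_list, rm.read_length)
    P = scan_genome(genome, rm.read_length, b1)
    lost = r_prime - P
    fn = [r for r in rm.reads if counts[r] > 1 or "N" in r or r in lost]
    fp1 = P - r_prime
    return EncodeOneResult(b1, fn, fp1, r_prime, P)


def build_cascade(
    r_prime: set,
    fp1: set,
    params: CascadeParams,
    read_length: int,
) -> tuple[list, list, list]:
    """Build filters 2..L; returns (filters, fp_sets, level_params).

    Level j is loaded with FP_{j-1}; FP_j is the subset of FP_{j-2}
    accepted by B_j (with FP_0 = R').  fp_sets[k] is FP_{k+1}, so the
    residual list to store explicitly is fp_sets[-1].
    """
    level_sets: dict[int, set] = {0: set(r_prime), 1: set(fp1)}
    digest_cache: dict[int, tuple] = {}

    def digests_of(level: int):
        if level not in digest_cache:
            members = sorted(level_sets[level])
            digest_cache[level] = (members, *digest_strings(members, read_length))
        return digest_cache[level]

    filters: list[BloomFilter] = []
    level_params = []
    fp_sets: list[set] = [set(fp1)]
    for j in range(2, params.num_levels + 1):
        insert_set = level_sets[j - 1]
        lvl = params.with_actual_count(j, len(insert_set))
        level_params.append(lvl)
        bf = BloomFilter(lvl.m, lvl.h, (lvl.seed_a, lvl.seed_b))
        members, ha, hb = digests_of(j - 1)
        bf.insert_digests(ha, hb)
        cand, ca, cb = digests_of(j - 2)
        acc = bf.query_digests(ca, cb)
        fp_j = {cand[i] for i in np.nonzero(acc)[0]}
        level_sets[j] = fp_j
        fp_sets.append(fp_j)
        filters.append(bf)
    return filters, fp_sets, level_params


def encode(
    reads,
    genome,
    *,
    num_levels: int = 4,
    size_cap: int = DEFAULT_SIZE_CAP,
    master_seed: int = DEFAULT_MASTER_SEED,
    backend: str = "xz",
) -> tuple[bytes, dict]:
    """Full pipeline: reads + reference -> archive bytes + stats dict.

    Deterministic for a fixed master seed; re-encoding yields byte-identical
    archives.
    """
    rm = as_read_multiset(reads)
    genome = as_genome(genome)

    if len(rm) == 0:
        params = plan_cascade(max(genome.length, 1), 1, size_cap, num_levels, master_seed)
        filters = []
        for j in range(1, num_levels + 1):
            lvl = params.with_actual_count(j, 0)
            filters.append(BloomFilter(lvl.m, lvl.h, (lvl.seed_a, lvl.seed_b)))
        parts = ArchiveParts(
            read_length=0,
            genome_digest=genome.digest,
            rho=params.rho,
            f_rate=params.F,
            genome_length=genome.length,
            n_unique=0,
            filters=filters,
            fp_last=[],
            fn=[],
        )
        blob = write_archive(parts, backend)
        stats = _stats(parts, params, blob, n_reads=0)
        return blob, stats

    r_prime, _ = partition_reads(rm)
    params = plan_cascade(genome.length, max(len(r_prime), 1), size_cap, num_levels, master_seed)
    res = encode_one(rm, genome, params)
    filters, fp_sets, _ = build_cascade(res.r_prime, res.fp1, params, rm.read_length)
    fp_last = sorted(fp_sets[-1]) if fp_sets else sorted(res.fp1)
    if num_levels == 1:
        fp_last = sorted(res.fp1)

    parts = ArchiveParts(
        read_length=rm.read_length,
        genome_digest=genome.digest,
        rho=params.rho,
        f_rate=params.F,
        genome_length=genome.length,
        n_unique=len(res.r_prime),
        filters=[res.b1] + filters,
        fp_last=fp_last,
        fn=res.fn,
    )
    blob = write_archive(parts, backend)
    stats = _stats(parts, params, blob, n_reads=len(rm))
    return blob, stats


def _stats(parts: ArchiveParts, params: CascadeParams, blob: bytes, n_reads: int) -> dict:
    total_bases = n_reads * parts.read_length
    filter_bits = sum(bf.m for bf in parts.filters)
    return {
        "n_reads": n_reads,
        "read_length": parts.read_length,
        "genome_length": parts.genome_length,
        "n_unique": parts.n_unique,
        "fn_size": len(parts.fn),
        "fp_last_size": len(parts.fp_last),
        "rho": params.rho,
        "F": params.F,
        "levels": [
            {"n_inserted": bf.n_inserted, "h": bf.h, "m": bf.m}
            for bf in parts.filters
        ],
        "uncompressed_filter_bits": filter_bits,
        "archive_bytes": len(blob),
        "bits_per_base": (8.0 * len(blob) / total_bases) if total_bases else float("nan"),
        "bits_per_read": (8.0 * len(blob) / n_reads) if n_reads else float("nan"),
    }
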