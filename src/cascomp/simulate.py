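"""Synthetic genomes and short reads with a linear positional error ramp.

Emulates a dwgsim-style single-end simulation: a donor genome is derived
from the reference by SNP mutation only (no indels), reads of fixed
length are sampled uniformly from both strands of the donor, and each
base is substituted with probability rising linearly along the read from
``error_start`` at the 5' end to ``error_end`` at the 3' end.  Defaults
follow the study conditions: mutation rate 0.001, error ramp 0 to 0.005
(mean per-base rate 0.0025 for 100 bp reads).

Also provides the closed-form expectations used to validate encoder
statistics: the expected multiplicity-weighted repeat count among R
uniformly sampled reads, and the binomial estimate of the fraction of
reads lost to sequencing error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Genome, ReadMultiset, as_genome
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "make_genome",
    "simulate_reads",
    "simulate_dataset",
    "expected_repeats",
    "expected_error_fraction",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_LETTER = np.frombuffer(b"ACGTN", dtype=np.uint8)

#: Reads are processed in fixed-size blocks so peak memory stays flat; the
#: block size is part of the deterministic random stream layout.
_CHUNK = 65536


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset."""

    genome_length: int = 1_000_000
    coverage: float = 30.0
    read_length: int = 100
    mutation_rate: float = 0.001  # per-base SNP probability in the donor
    error_start: float = 0.0  # substitution error at the 5' read end
    error_end: float = 0.005  # substitution error at the 3' read end
    seed: int = 0
    # Indels are never introduced (donor differs from reference by SNPs only).

    def __post_init__(self):
        for name in ("mutation_rate", "error_start", "error_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.coverage <= 0:
            raise ValidationError(f"coverage must be positive, got {self.coverage}")
        if self.read_length < 1:
            raise ValidationError(f"read length must be >= 1")
        if self.read_length > self.genome_length:
            raise ValidationError("read length exceeds genome length")


def error_ramp(config: SimulationConfig) -> np.ndarray:
    """Per-position substitution probability along the read (5' to 3')."""
    L = config.read_length
    if L == 1:
        return np.array([config.error_start])
    return config.error_start + (config.error_end - config.error_start) * np.arange(L) / (L - 1)


def make_genome(length: int, seed=0, repeat_fraction: float = 0.0) -> str:
    """IID-uniform A/C/G/T genome of the given length.

    ``repeat_fraction`` > 0 copies the leading floor(f * length) bases over
    the tail, planting an exact long repeat for repeat-structure stress
    tests.
    """
    if length < 1:
        raise ValidationError(f"genome length must be >= 1, got {length}")
    if not 0.0 <= repeat_fraction <= 0.5:
        raise ValidationError("repeat fraction must be in [0, 0.5]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & (2**31 - 1), 0]))
    codes = rng.integers(0, 4, size=length)
    arr = _BASES[codes]
    k = int(repeat_fraction * length)
    if k:
        arr[length - k :] = arr[:k]
    return arr.tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """SNP-only donor: substitute each A/C/G/T base with prob rate."""
    donor = codes.copy()
    if rate <= 0:
        return donor
    mask = (rng.random(codes.shape[0]) < rate) & (codes < 4)
    n = int(mask.sum())
    if n:
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        donor[mask] = (donor[mask] + shift) % 4
    return donor


def simulate_reads(genome, config: SimulationConfig) -> tuple[ReadMultiset, pd.DataFrame]:
    """Sample reads from a donor copy of the genome; returns (reads, origins).

    Origins is a data frame with one row per read: contig, 0-based start,
    strand ('+'/'-'), and the number of substitution errors applied.
    """
    genome = as_genome(genome)
    L = config.read_length

    ss = np.random.SeedSequence([int(config.seed) & (2**31 - 1), 1])
    rng_mut, rng_pos, rng_err = (np.random.default_rng(s) for s in ss.spawn(3))

    donors = []  # (contig_name, donor_codes, valid_start_positions)
    for name, seq in genome.contigs:
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        donor = _mutate(codes, config.mutation_rate, rng_mut)
        nw = len(seq) - L + 1
        if nw <= 0:
            continue
        ok = (codes < 4).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(ok)))
        valid = np.nonzero((csum[L : L + nw] - csum[:nw]) == L)[0]
        donors.append((name, donor, valid))
    total_valid = sum(len(v) for _, _, v in donors)
    if total_valid == 0:
        raise ValidationError("no contig admits a full read-length window")

    n_reads = int(round(config.coverage * genome.length / L))
    choice = rng_pos.integers(0, total_valid, size=n_reads)
    strands = rng_pos.integers(0, 2, size=n_reads).astype(np.int8)
    ramp = error_ramp(config)
    ramp_rc = ramp  # ramp applies along the read as sequenced, after orientation

    bounds = np.cumsum([0] + [len(v) for _, _, v in donors])
    reads: list[str] = []
    contig_col = np.empty(n_reads, dtype=object)
    start_col = np.empty(n_reads, dtype=np.int64)
    nerr_col = np.empty(n_reads, dtype=np.int64)

    offsets = np.arange(L)
    for lo in range(0, n_reads, _CHUNK):
        hi = min(lo + _CHUNK, n_reads)
        sel = choice[lo:hi]
        sub_strand = strands[lo:hi]
        block = np.empty((hi - lo, L), dtype=np.uint8)
        for ci, (name, donor, valid) in enumerate(donors):
            in_ci = (sel >= bounds[ci]) & (sel < bounds[ci + 1])
            if not in_ci.any():
                continue
            starts = valid[sel[in_ci] - bounds[ci]]
            win = donor[starts[:, None] + offsets]
            rc_rows = sub_strand[in_ci] == 1
            if rc_rows.any():
                w = win[rc_rows]
                w = np.where(w < 4, 3 - w, w)[:, ::-1]
                win[rc_rows] = w
            block[in_ci] = win
            contig_col[lo:hi][in_ci] = name
            start_col[lo:hi][in_ci] = starts
        err = rng_err.random((hi - lo, L)) < ramp_rc[None, :]
        err &= block < 4
        n_err_pos = int(err.sum())
        if n_err_pos:
            shift = rng_err.integers(1, 4, size=n_err_pos).astype(np.uint8)
            block[err] = (block[err] + shift) % 4
        nerr_col[lo:hi] = err.sum(axis=1)
        letters = _LETTER[block]
        flat = letters.tobytes().decode("ascii")
        reads.extend(flat[i * L : (i + 1) * L] for i in range(hi - lo))

    origins = pd.DataFrame(
        {
            "contig": contig_col,
            "start": start_col,
            "strand": np.where(strands == 1, "-", "+"),
            "n_errors": nerr_col,
        }
    )
    return ReadMultiset(reads), origins


def simulate_dataset(config: SimulationConfig) -> tuple[Genome, ReadMultiset, pd.DataFrame]:
    """Convenience wrapper: fresh IID genome plus reads sampled from it."""
    genome = Genome.from_string(make_genome(config.genome_length, config.seed), "sim1")
    reads, origins = simulate_reads(genome, config)
    return genome, reads, origins


def expected_repeats(R_count: int, G_length: int, prefactor: float = 1.0) -> float:
    """Expected multiplicity-weighted repeat count among R uniform reads.

    Reads land on one of ~2G (position, strand) slots; a read is a repeat
    if any of the other R-1 reads hits the same slot:

        k * R * (1 - (1 - 1/(2G))**(R-1))

    The default prefactor k=1 matches the observed repeat counts; k=2 (the
    variant that double-counts the strand correction) is selectable.
    """
    if R_count < 1 or G_length < 1:
        raise ValidationError("need R_count >= 1 and G_length >= 1")
    if R_count == 1:
        return 0.0
    p_repeat = -math.expm1((R_count - 1) * math.log1p(-1.0 / (2.0 * G_length)))
    return prefactor * R_count * p_repeat


def expected_error_fraction(read_length: int, p: float, terms: str = "two") -> float:
    """Binomial estimate of the fraction of reads carrying sequencing error.

    With per-base error p (the ramp's mean), the number of errors per read
    is Binom(L, p).  ``terms="two"`` returns the one- and two-error terms

        C(L,1) p (1-p)^(L-1) + C(L,2) p^2 (1-p)^(L-2)

    which carry most of the mass; ``terms="all"`` returns the full
    1 - (1-p)^L.  Either way the value is coverage-independent.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must be a probability, got {p}")
    L = read_length
    if terms == "all":
        return -math.expm1(L * math.log1p(-p)) if p < 1 else 1.0
    if terms != "two":
        raise ValidationError(f"terms must be 'two' or 'all', got {terms!r}")
    if p == 0.0:
        return 0.0
    one = L * p * (1 - p) ** (L - 1)
    two = (L * (L - 1) / 2) * p**2 * (1 - p) ** (L - 2)
    return one + two
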