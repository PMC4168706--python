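"""Encoder: read partitioning, genome scanning, cascade construction."""

from collections import Counter

import numpy as np
import pytest

from cascomp.bloom import BloomFilter
from cascomp.containers import Genome, ReadMultiset, revcomp
from cascomp.decoder import decode, verify
from cascomp.encoder import (
    build_cascade,
    encode,
    encode_one,
    partition_reads,
    scan_genome,
)
from cascomp.errors import ValidationError
from cascomp.params import plan_cascade

from conftest import all_windows, random_dna

# Hand-checked toy fixture: w1 and w2 are windows of G, r_err is not a
# window of either strand ("AAAA" appears nowhere in G or its reverse
# complement).
TOY_G = "AATTCCGGATCG"
TOY_W1, TOY_W2, TOY_ERR = "AATT", "CCGG", "AAAA"
TOY_READS = [TOY_W1, TOY_W2, TOY_W2, TOY_ERR]


class TestPartition:
    def test_repeated_read_goes_to_fn(self):
        r_prime, fn0 = partition_reads(["ACGT", "TTTT", "TTTT"])
        assert r_prime == {"ACGT"}
        assert fn0 == ["TTTT", "TTTT"]

    def test_n_containing_read_goes_to_fn(self):
        r_prime, fn0 = partition_reads(["ANGT"])
        assert r_prime == set()
        assert fn0 == ["ANGT"]

    def test_counts_are_conserved(self, rng):
        pool = [random_dna(rng, 6) for _ in range(300)]
        reads = list(rng.choice(pool, size=1000)) + ["ACGNTA"[:6]] * 3
        r_prime, fn0 = partition_reads(reads)
        assert len(r_prime) + len(fn0) == len(reads)
        # dictionary oracle
        counts = Counter(reads)
        assert r_prime == {r for r, c in counts.items() if c == 1 and "N" not in r}
        assert Counter(fn0) == Counter(
            r for r in reads if counts[r] > 1 or "N" in r
        )

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            partition_reads([])
        with pytest.raises(ValidationError):
            partition_reads(["ACGT", "ACGTA"])
        with pytest.raises(ValidationError):
            partition_reads(["ACGX"])


class TestScanGenome:
    def test_hand_enumeration(self):
        # G = ACGTA: forward windows ACGT, CGTA; reverse strand adds TACG
        # (rc of CGTA); rc(ACGT) = ACGT is a duplicate under set semantics.
        P = scan_genome("ACGTA", 4, lambda w: True)
        assert P == {"ACGT", "CGTA", "TACG"}

    def test_windows_overlapping_n_are_skipped(self):
        P = scan_genome("ACGTNACGT", 4, lambda w: True)
        assert P == {"ACGT", "ACGT", revcomp("ACGT")} == {"ACGT"}

    def test_reject_all_predicate(self):
        assert scan_genome("ACGTACGT", 4, lambda w: False) == set()

    def test_matches_enumeration_oracle(self, rng):
        g = random_dna(rng, 300)
        P = scan_genome(g, 21, lambda w: True)
        assert P == all_windows(g, 21)

    def test_bloom_filter_sweep_equals_predicate_sweep(self, rng):
        g = random_dna(rng, 500)
        bf = BloomFilter(4096, 2)
        targets = sorted(all_windows(g, 15))[:40]
        bf.insert_strings(targets, 15)
        assert scan_genome(g, 15, bf) == scan_genome(g, 15, bf.query)

    def test_windows_never_span_contigs(self):
        genome = Genome([("c1", "ACGTACGT"), ("c2", "TTTTTTTT")])
        P = scan_genome(genome, 8, lambda w: True)
        spanning = "ACGTACGTTTTTTTTT"[4:12]
        assert spanning not in P

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValidationError):
            scan_genome("ACG", 4, lambda w: True)


class TestEncodeOne:
    def test_reads_equal_to_windows_leave_fn_empty(self, rng):
        g = random_dna(rng, 2000)
        windows = sorted(all_windows(g, 20))
        reads = list(rng.choice(windows, size=50, replace=False))
        res = encode_one(reads, g)
        assert res.fn == []  # inserted windows are always recovered
        assert res.fp1 <= res.accepted
        assert res.fp1.isdisjoint(set(reads))

    def test_mutated_read_always_lands_in_fn(self, rng):
        g = random_dna(rng, 500)
        w = g[100:120]
        mutated = ("A" if w[0] != "A" else "C") + w[1:]
        if mutated in all_windows(g, 20):  # pragma: no cover - seed-stable
            pytest.skip("mutation coincided with another window")
        res = encode_one([mutated], g)
        assert res.fn == [mutated]

    def test_toy_fixture_hand_trace(self):
        res = encode_one(TOY_READS, TOY_G)
        assert res.r_prime == {TOY_W1, TOY_ERR}
        assert res.b1.n_inserted == 2
        assert res.fn == [TOY_W2, TOY_W2, TOY_ERR]
        assert TOY_ERR not in res.accepted


class TestBuildCascade:
    def test_empty_fp1_collapses_chain(self):
        params = plan_cascade(1000, 60)
        filters, fp_sets, _ = build_cascade({"ACGT"}, set(), params, 4)
        assert len(filters) == 3
        assert all(bf.n_inserted == 0 for bf in filters)
        assert fp_sets[-1] == set()

    def test_subset_chain_and_scalar_oracle(self, rng):
        # small universe: all 4-mers, exact recomputation by scalar queries
        universe = ["".join(p) for p in __import__("itertools").product("ACGT", repeat=4)]
        chosen = rng.permutation(len(universe))
        r_prime = {universe[i] for i in chosen[:60]}
        fp1 = {universe[i] for i in chosen[60:100]}
        params = plan_cascade(1000, 60)
        filters, fp_sets, _ = build_cascade(r_prime, fp1, params, 4)
        b2, b3, b4 = filters
        fp2 = {x for x in r_prime if b2.query(x)}
        fp3 = {x for x in fp1 if b3.query(x)}
        fp4 = {x for x in fp2 if b4.query(x)}
        assert fp_sets[1] == fp2
        assert fp_sets[2] == fp3
        assert fp_sets[3] == fp4
        assert fp2 <= r_prime and fp3 <= fp1 and fp4 <= fp2
        assert b2.n_inserted == len(fp1)
        assert b3.n_inserted == len(fp2)
        assert b4.n_inserted == len(fp3)


class TestEncode:
    def test_toy_roundtrip(self):
        blob, stats = encode(TOY_READS, TOY_G)
        assert verify(TOY_READS, decode(blob, TOY_G))
        assert stats["fn_size"] == 3

    def test_all_n_reads(self):
        reads = ["NNNN", "NNNN"]
        blob, stats = encode(reads, TOY_G)
        assert stats["n_unique"] == 0
        assert stats["fn_size"] == 2
        assert verify(reads, decode(blob, TOY_G))

    def test_empty_read_set(self):
        blob, stats = encode([], TOY_G)
        assert stats["n_reads"] == 0
        decoded = decode(blob, TOY_G)
        assert len(decoded) == 0

    def test_reencoding_is_byte_identical(self, rng):
        g = random_dna(rng, 800)
        reads = list(rng.choice(sorted(all_windows(g, 12)), size=60))
        blob1, _ = encode(reads, g, master_seed=11)
        blob2, _ = encode(reads, g, master_seed=11)
        assert blob1 == blob2
        blob3, _ = encode(reads, g, master_seed=12)
        assert blob3 != blob1  # different hash family, same content

    def test_oversized_clean_fixture_has_empty_residues(self, rng):
        # reads = distinct windows of a large genome with few reads: the
        # planned F is tiny, so FN and the residual FP list are empty.
        g = random_dna(rng, 5000)
        reads = sorted(all_windows(g, 25))[::40][:30]
        blob, stats = encode(reads, g)
        assert stats["fn_size"] == 0
        assert stats["fp_last_size"] == 0
        assert verify(reads, decode(blob, g))

    def test_single_level_cascade(self, rng):
        g = random_dna(rng, 600)
        reads = list(rng.choice(sorted(all_windows(g, 10)), size=40))
        blob, stats = encode(reads, g, num_levels=1)
        assert len(stats["levels"]) == 1
        assert verify(reads, decode(blob, g))
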