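# cascomp

Lossless, alignment-free, **reference-based compression of fixed-length
sequencing reads** using a cascade of Bloom filters.

Reference-based read compressors usually align every read to the genome and
store positions plus differences — compact, but alignment dominates the run
time. `cascomp` skips alignment entirely: the unique reads are hashed into a
Bloom filter, and decompression *rediscovers* them by querying the filter
with every read-length window of the reference genome, on both strands.
Everything the filter cannot represent exactly is stored explicitly, so the
reconstruction is exact: the decoder returns precisely the original multiset
of read sequences (order, names and qualities are out of scope).

It is intended for people working with high-coverage resequencing data who
want reference-based compression ratios at reference-free speed, and as a
compact, fully tested implementation of the Bloom-filter-cascade encoding
for teaching and further experimentation.

## Method

For a Bloom filter of m bits holding n elements with h hash functions the
false-positive rate is F ≈ (1 − e^(−hn/m))^h, minimised at h = ln(2)·ρ
(ρ = m/n bits per element), where F = c^ρ with c = 2^(−ln 2) ≈ 0.6185.

**Encoding** (reads R, genome G of length g):

1. Repeated reads (kept at full multiplicity) and reads containing `N` go to
   an explicit list **FN**; the remaining unique reads R′ are inserted into
   filter B₁.
2. Every read-length window of G (both strands, 2g queries) is queried
   against B₁. Accepted windows form P. Unique reads the scan cannot produce
   (sequencing errors, donor mutations) are appended to FN (R′ \ P); windows
   wrongly accepted are FP₁ = P \ R′.
3. Instead of storing FP₁ verbatim, a cascade stores it in filter B₂; the
   false positives of B₂ (members of R′ it accepts) form FP₂, stored in B₃,
   and so on. With four filters only the small residual list FP₄ is written
   out. Since FP₂ ⊆ R′, FP₃ ⊆ FP₁, FP₄ ⊆ FP₂, level sizes fall geometrically.

**Decoding** replays the same genome scan: each window runs through
B₁…B₄ until first rejection — rejected at an even level ⇒ real read, odd
level ⇒ fake; accepted by all four ⇒ real iff in FP₄. Genome-derived reads
are exactly R′ ∩ P, so together with FN the output equals R — independent
of hash seeds and of how many false positives occur.

The per-read cost of an infinite cascade, ρ·(1 + (2g/n)·c^ρ)/(1 − c^ρ)
bits, is minimised numerically over ρ; the minimiser fixes the common
per-level rate F = c^ρ*, and each level's (h, m) is then sized for its
actual element count.

## Worked example

```bash
# simulate a 1 Mb genome and coverage-30 reads (SNP rate 0.001,
# substitution error ramping 0 -> 0.005 along the 100 bp reads)
cascomp simulate --out-prefix sim --length 1000000 --coverage 30 --seed 1

# compress
cascomp encode --ref sim.ref.fa --reads sim.reads.fastq --out sim.brc

# decompress and check exactness
cascomp verify --ref sim.ref.fa --archive sim.brc --reads sim.reads.fastq
```

prints

```
encoded 300000 reads -> 1672555 bytes (0.4460 bits/base); |FN|=111691, |FP|=830, rho=6.029, F=0.0552
lossless: true
```

Reading: the 30 Mbases of reads compressed to 0.446 bits per base. Of the
300 000 reads, 111 691 went to the explicit FN list (repeats, N-reads, and
reads that errors/mutations detached from the reference); the optimiser
chose a budget of ρ ≈ 6.0 bits per unique read, i.e. a per-level
false-positive rate F ≈ 0.055, leaving a residual list of only 830
windows after four cascade levels. `lossless: true` confirms the decoded
multiset equals the input exactly.

Compression improves with coverage (more redundancy per genome position):
on the same reference, coverage 10 gives ≈ 0.58 bits/base and coverage 50
≈ 0.43 bits/base.

## Layout

| module | contents |
| --- | --- |
| `cascomp.bloom` | seeded Bloom filter + F/ρ/h algebra |
| `cascomp.params` | cost model, ρ optimisation, per-level (h, m) sizing |
| `cascomp.encoder` | read partitioning, genome scan, cascade construction |
| `cascomp.decoder` | parity classification, exact reconstruction |
| `cascomp.container_io` | BRC1 archive format, FASTA/FASTQ I/O, backends |
| `cascomp.simulate` | genome/read simulator + FN expectation models |
| `cascomp.cli` | `cascomp simulate / encode / decode / verify / stats` |

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
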