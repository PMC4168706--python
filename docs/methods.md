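# Methods

## The encoding model

`cascomp` treats the reference genome as an implicit dictionary. A Bloom
filter B₁ holds the set R′ of unique, N-free reads; decoding enumerates
every read-length window of the reference on both strands and asks B₁
whether that window was a read. Because a Bloom filter has no false
negatives, every member of R′ that exists as a reference window is
guaranteed to be rediscovered. Exactness then rests on two explicit
residual structures:

* **FN** (false negatives of the *scheme*, not of the filter): repeated
  reads at full multiplicity, reads containing `N`, and unique reads that
  no reference window reproduces (sequencing errors and donor SNPs).
  Stored verbatim, in first-occurrence order of the input stream.
* **FP chain**: windows wrongly accepted by B₁ form FP₁; rather than
  storing FP₁ verbatim it is inserted into B₂, whose false positives
  against R′ form FP₂, inserted into B₃, and so on. After L levels the
  residual list FP_L is stored verbatim (sorted lexicographically).

Decoding classifies each window by the parity of the first rejecting
filter (even ⇒ real, odd ⇒ fake; survivor of all L levels ⇒ resolved by
membership in FP_L, with the sense flipped for odd L). Because the encoder
materialises each FP set exactly before loading the next filter, the
classification is exact by construction: the genome-derived output is
precisely R′ ∩ P, whatever the hash seeds, filter sizes, or number of
collisions. The decoded multiset is FN ⊎ (R′ ∩ P) = R. Filters only ever
trade *size* against correctness, never correctness itself.

Window strings have set semantics on both sides: a string reachable from
several genome positions, both strands, or equal to its own reverse
complement is counted once (reads in R′ are unique by construction, so one
acceptance suffices). Windows are enumerated per contig (never spanning a
contig boundary), 0-based half-open; windows containing a non-ACGT symbol
are skipped, which is consistent because N-containing reads never enter
the filters.

## Cost model and parameter selection

A filter holding n elements at false-positive rate F needs ρ =
log(1/F)/log(1/c) bits per element at the real-valued optimal hash count,
with c = 2^(−ln 2) ≈ 0.6185. Level element counts alternate between
read-driven (n, nF, nF², …) and genome-driven (2gF, 2gF², …: the scan
makes 2g queries), so an infinite cascade costs

    bits/read = ρ (1 + (2g/n) c^ρ) / (1 − c^ρ),

minimised over ρ ∈ [0.1, 100] by a coarse vectorised grid followed by
bounded scalar minimisation (`scipy.optimize.minimize_scalar`, xatol
1e−10); tests require agreement with a 10⁻³-step grid oracle to 1e−8 in
objective value. The objective is extremely flat near its minimum (for
g = 10⁶, n = 3·10⁵ the minimum 8.72 bits/read sits at ρ ≈ 5.77, with the
value changing by <0.01 over ρ ∈ [5.6, 6.0]), so downstream behaviour is
insensitive to the exact minimiser.

**Per-level (h, m) sizing.** Each level is sized for its *actual* element
count, known exactly at build time (the a-priori expectations above are
used only for planning and reporting). For the common rate F = c^ρ*, h is
incremented from 1 to the smallest value whose exact size
`required_bits(n, F, h)` fits (a) the absolute uncompressed per-filter cap
(default 500 MiB) and (b) a bounded-overhead budget of 1.25× the
real-h-optimal size n·ln(1/F)/ln(2)². Small h keeps filters sparse — much
more compressible by the byte-level backend and faster to query — while
the 25% overhead bound keeps the uncompressed cascade within the cost
model's envelope; for the F values the optimiser produces (0.03–0.15) this
yields h ∈ {2, 3}, and h ∈ {1..3} across the parameter ranges of interest.
If nothing fits the absolute cap, the size-minimising h is used and the
violation flagged. Degenerate levels (n = 0) get a 64-bit minimum filter
so the archive layout never contains zero-length arrays.

Cascade depth defaults to 4 and is configurable (`--levels`); depth 1
reduces to the single-filter scheme where the stored residual list is FP₁
itself (containing fakes rather than reals — the parity flip is handled
uniformly).

## Hashing

Double hashing: position_i = (h_a + i·h_b) mod m for i < h. Each element's
raw upper-case ASCII bytes are digested once by two independent
multiply-add chains (mod 2⁶⁴); each filter derives (h_a, h_b) by xoring
the two digests with its stored 64-bit seed pair and applying a
splitmix64 finalizer (h_b is forced odd). Digests are vectorised with
numpy over read matrices and sliding genome windows, which is what makes
the 2g-query genome sweeps cheap; the scalar and vectorised paths are
tested to be bit-identical. Reads are hashed as whole strings — no 2-bit
packing or canonicalisation — keeping an exact correspondence between a
read and its genome window. Seeds derive deterministically from one
master seed (CLI `--seed`), default fixed, always stored in the archive
header: decoding never depends on ambient state, and re-encoding with the
same seed is byte-identical.

## Archive format (BRC1)

Header: magic `BRC1`, version, read length, level count, SHA-256 digest of
the reference (over contig names and upper-cased sequences — decode
*refuses* a mismatched reference rather than warning, since a wrong
dictionary would silently corrupt the output), backend id, ρ and F, genome
length, unique-read count, per-level filter metadata (m, h, seeds,
n_inserted), and per-block compressed lengths. Blocks: each filter's
serialized form (metadata + LSB-first bit data), then FP_L and FN as
newline-delimited ASCII. Every block is independently compressed by a
pluggable byte-level backend (`xz` = stdlib LZMA preset 6 by default;
`zlib` and `raw` included; arbitrary backends registrable). FN stays plain
ASCII because it may contain `N`; read-boosting compressors specialised
for sequence overlap would slot in behind the same backend contract.

## Simulator

`simulate` emulates a standard short-read simulation: a donor genome is
derived from the reference by SNP-only mutation (default rate 0.001 per
base; no indels), n = round(coverage·g/L) single-end reads are drawn
uniformly with replacement from all valid start positions, each oriented
forward or reverse-complement with probability ½, and each base is
substituted (uniformly among the three alternatives) with probability
rising linearly from `error_start` = 0 at the 5′ end to `error_end` =
0.005 at the 3′ end — mean per-base rate exactly 0.0025 for 100 bp reads.
One seed drives genome, mutation, sampling and error streams through
independent derived child seeds; reads are generated in fixed 65 536-read
blocks (part of the deterministic stream layout) so memory stays flat.
Ground-truth origins (contig, start, strand, error count) are returned as
a data frame / TSV sidecar.

What the generator does *not* emulate: indels and structural variation,
quality-score realism, GC or positional sampling bias, paired-end
structure, and the repeat structure of real genomes (IID sequence has far
fewer near-repeats than, say, a human chromosome; an optional
repeat-injection mode plants one exact long repeat for stress tests).
Passing round-trip tests therefore demonstrate exactness of the codec
under realistic error/mutation loads, and the measured compression ratios
show the right coverage trends, but absolute ratios on real genomes will
differ (real FN lists are more redundant and compress better; real repeat
content sends more reads to FN).

### FN expectation models

Two closed forms predict the composition of FN and are validated against
simulation:

* **Repeats**: reads land on ~2G (position, strand) slots; the expected
  multiplicity-weighted repeat count is k·R·(1 − (1 − 1/(2G))^(R−1)).
  The default prefactor k = 1 matches observed counts (the k = 2 variant,
  which double-counts the strand correction, is exposed as an option).
  This contribution grows with coverage.
* **Errors**: with mean per-base error p = 0.0025, the fraction of reads
  carrying at least one error is 1 − (1−p)^L (0.22144 for L = 100), with
  the one- and two-error binomial terms carrying most of the mass
  (0.21934). This fraction is coverage-independent, so the error-driven
  part of FN scales linearly with read count while the repeat-driven part
  accelerates.

## Numerical and edge-case choices

* `fpr` uses expm1/log1p forms; `required_bits` guards its closed-form
  ceiling with an exact adjustment loop so the returned m is the true
  smallest size meeting F.
* Empty read sets encode to a well-formed archive with 64-bit empty
  filters and decode to an empty multiset; all-N inputs put everything in
  FN. A genome with no contig ≥ the read length is rejected at encode.
* FN preserves input stream order (deterministic archives; multiset
  semantics make order immaterial), FP_L is sorted lexicographically.
* Decoded output order is FN followed by the sorted genome-derived reads;
  comparisons are multiset-based throughout.
* Exit codes: 0 success, 1 verification mismatch, 2 validation error,
  3 reference-digest mismatch, 4 corrupt archive.

## Problem sizes used in tests

The test and acceptance workloads run the full study conditions at
desk scale: 1 Mb genomes for round-trip, size-model and coverage-trend
checks (coverages 10–50, i.e. up to 500 k reads per run), and 100 kb
genomes for the Monte-Carlo validation of the FN expectation models
(averaged over several seeds per coverage). These sizes keep the ratio
R/2G — the quantity that controls repeat load — in the same range as the
motivating full-scale experiments (e.g. R/2G = 0.25 at coverage 50 either
way), so the scaled runs exercise the same regime.

## Known limitations

* Fixed read length only; variable-length input is rejected.
* Read names, qualities and pair linkage are out of scope by design.
* Single-threaded; block compression and the two strand sweeps are
  embarrassingly parallel but no concurrency is attempted.
* No streaming/random-access decode; the genome scan is all-or-nothing.
* The byte-level backends are generic; a sequence-aware backend for the
  FN block would likely improve ratios materially at high coverage.
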