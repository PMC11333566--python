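# phaseprep

Phasing preliminaries for reference-based genotype phasing and imputation:
the data structures a PBWT-based phaser builds for every target sample
before any phase is called, plus a bit-exact streaming model of the same
computation organised as a hardware-style dataflow.

## The problem

Reference-based phasing resolves which chromosome of a diploid target
carries each heterozygous allele by matching the target against a panel of
N fully phased haplotypes over M biallelic sites.  Before the search
itself, a per-target preprocessing stage dominates the work:

1. **Scoring and K-best selection.**  Encode the target's genotypes as
   per-site bitstreams `is0` (homozygous reference), `is2` (homozygous
   alternative), `missing`, and `call` (the heterozygous sites whose phase
   must be decided).  A haplotype allele `hap` contradicts the target at a
   site iff

   `inc = (is0 AND hap) OR (is2 AND NOT hap)`

   Each panel haplotype is scored by its inconsistency count over the
   homozygous sites and the K lowest-scoring haplotypes are kept
   (ties toward the lower panel index; K defaults to 10 000).
2. **Condensed reference.**  Over the k selected haplotypes and the C call
   sites, build `2C + 1` alternating bit rows: the raw allele row at each
   call site, and for each segment between call sites the OR of the
   per-site inconsistency rows — one bit per haplotype saying whether it
   contradicts the target anywhere in that segment.
3. **Compact indexed PBWT.**  Transform the condensed rows (forward and
   backward) into a positional Burrows-Wheeler transform: per site, the
   alleles permuted into reversed-prefix sorted order, with the zero count
   `cnt0` and a rank index — one 32-bit counter per 32-bit block holding
   the cumulative zero count through that block — so `rank0`/`rank1` need
   one lookup plus a partial-block popcount.
4. **Set-maximal matching.**  Against a panel PBWT, report every agreement
   interval of a query haplotype that no panel haplotype extends on either
   side — the primitive an imputation step copies alleles from.  A minimal
   majority-vote filler is included to exercise it end to end.

The `pipeline_sim` module is a transaction-level twin of steps 1–3 shaped
like a parallel-pipeline accelerator (16-bit bus beats, mask compaction,
condense state machine, dual-port 2-bit-per-cycle PBWT engine, 32-bit
deserializer, 512-bit DRAM word packing with per-pipeline offsets,
host-side indexing).  Its contract is bit-for-bit equality with the direct
implementations, and it carries the design's analytic throughput model.

## Worked example

```sh
python examples/02_pbwt_and_rank.py
```

```
input rows (variant-major):
   0101
   1100
   0110
PBWT rows (reversed-prefix sorted order per site):
   0101 cnt0=2
   1010 cnt0=2
   1001 cnt0=2
final permutation: [3, 0, 2, 1]
block zero-count index: [[2], [2], [2]]
rank0(site=2, pos=3) = 2  rank1 = 1
roundtrip from rows+cnt0 alone restores the input: True
```

Row 0 is emitted in input order (the initial permutation is the identity);
after it, indices are routed into a zero-queue and a one-queue split at
`cnt0`, so at every later site the haplotypes appear sorted by their
reversed prefixes.  The final permutation `[3, 0, 2, 1]` lists haplotype
indices in that sorted order after all three sites.  The other examples
cover the condensed reference (`01`), set-maximal matching and allele
filling (`03`), and the streaming model with its throughput report (`04`).

The same functionality is reachable from a shell via the `phaseprep` CLI
(`synth`, `prelim`, `pbwt build/rank`, `match`, `simulate`, `throughput`),
e.g.:

```sh
phaseprep throughput
{"clock_ratio": 2.33, "main_domain_cycles_per_dram_word": 110, "pbwt_slowdown_vs_condensed_max": 3.43}
```

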