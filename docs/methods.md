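# Methods

## Encodings and conventions

All haplotype data is variant-major: one bit row per site, one bit per
haplotype, 0 = reference allele, 1 = alternative.  Internal site indices
are 0-based; VCF positions stay 1-based at the I/O boundary.  Bit order is
LSB-first within words, and the single convention covers every word size in
the package (16-bit bus words, 32-bit output words, 512-bit DRAM words);
round-trip tests pin it.  Reference panels must be fully phased, diploid
and biallelic; haploid samples and multi-allelic records are rejected
rather than coerced, and no strand harmonisation or allele flipping is
attempted — target sites must match the panel on (chrom, pos, ref, alt)
exactly.

A diploid target is four per-site bitstreams: `is0`, `is2`, `missing`, and
`call`.  Call sites are defined as exactly the heterozygous sites.
Missing genotypes have `is0 = is2 = 0`, which makes them consistent with
every haplotype under the inconsistency equation; they are left to a
downstream imputation step and are never call sites.

## Scoring and K-best selection

The only quantity the inconsistency equation defines between a haplotype
and a target is the count of contradicted homozygous sites, so that count
(lower is better) is the selection score; ties break toward the lower
haplotype index, implemented as a stable argsort.  Selection returns a
membership mask in panel order rather than a sorted list: the downstream
mask compaction is order-preserving by construction, so order carries no
information.  K defaults to 10 000 and saturates at N.

## Condensed reference

The layout is fixed at `2C + 1` rows with strict SEGMENT/CALLSITE
alternation.  Degenerate segments — before a leading call site, between
adjacent call sites, after a trailing call site, and the single row of a
target with no call sites — are explicit all-zero rows.  Fixing the layout
keeps downstream indexing position-computable from C and k alone; the OR
accumulator makes segment rows monotone in segment extent, which is tested
as an invariant.

## Compact PBWT and the block index

Construction is the queue-routing form: identity initial permutation, per
site a scan in permuted order emitting the allele and routing the index
into the zero-queue (cursor at 0) or one-queue (cursor at `cnt0`).  The
permutation arrays are transient build state; the persisted artifact is
rows + `cnt0` + index, and a reconstruction routine (`invert_pbwt`)
demonstrates that nothing else is needed.  The backward PBWT is defined as
the forward PBWT of the site-reversed matrix, reported in reversed site
order.

The rank index is one 32-bit counter per 32-bit block with inclusive
cumulative semantics and no superblock hierarchy.  Padding bits beyond N
in a row's last block are stored zero and masked out of every count, which
preserves `cnt0 == last index value` as an invariant.  The on-disk
container interleaves each data block with its index word.

## Set-maximal matching

The sweep tracks, per site, the interval `[f, g)` of reversed-prefix-sorted
positions whose haplotypes agree with the query on `[e, site)`, advanced
with `rank0`/`rank1` on the indexed rows.  When the interval empties, the
haplotypes in it are reported as set-maximal matches ending at that site,
and the sweep re-anchors on the longest query suffix still present in the
panel: the query's insertion position in the next sorted order is computed
by rank, its two sorted-order neighbours are compared backwards against
the query to find the new `e`, and the interval is re-expanded around the
insertion point by direct comparison.  The backward scans make the
worst case quadratic in M, amortised linear on realistic data; correctness
is defined by exact set equality with a brute-force enumeration oracle,
and any algorithm equivalent under that oracle would be acceptable.
Matches are reported sorted by (end, start, hap).

The allele filler is a deliberate minimal stand-in — a per-site majority
vote over haplotypes whose match covers the site, ties to the reference
allele, no-call where nothing covers — so the matching primitive can be
exercised end to end.  It is not an imputation model: no dosages, no
recombination- or distance-weighted copying.

## Streaming dataflow model

The model is transaction-level: every queue is lossless and unbounded,
buffers swap at site boundaries, and cycle counts appear only in the
analytic throughput report.  Fidelity choices that matter for bit-exactness:

- **Mask compaction** keeps selected lanes in order (the behaviour of
  routing data alongside the sorted mask bits of an odd-even transposition
  network) and collects sub-words until full 16-bit words are available;
  the residue is flushed at each row boundary.
- **Condense state machine**: segment data ORs into a k-bit accumulator;
  a call site releases the accumulator and then its own raw row.  The
  hardware releases the stored call-site word only when the next variant
  arrives; since release order is unchanged, the model emits immediately.
- **Dual-port 2-bit engine**: two permutation reads and two buffer fetches
  per cycle; within a pair the lower-indexed lane always routes first into
  its queue, which forces stability and hence equality with the 1-bit
  reference engine and the direct construction.  Odd row widths end with
  a single-bit cycle.  `cnt0` is accumulated while a site is written into
  the inactive buffer, one site ahead of its processing.
- **Deserializer and DRAM**: permuted bits pack into 32-bit words flushed
  (zero-padded) per site; per-pipeline streams land in disjoint DRAM
  regions of `ceil(bits/512)` words at cumulative offsets, with a
  double-buffer id modelling the alternation across target blocks.
  The host-side indexer works from the 32-bit word stream using popcounts
  only.

The throughput report computes three ratios from the configuration
constants (defaults: 32 pipelines, 16-bit bus, 2 bits/cycle, 114 MHz main
clock, 266 MHz PBWT clock, 32-bit output words, 512-bit DRAM words):
clock ratio 266/114 ≈ 2.33; worst-case PBWT slowdown versus the condense
stage (16/2) × (114/266) ≈ 3.43; and (512/2) × (114/266) ≈ 109.7 → 110
main-domain cycles per DRAM word, rounded half-up to the nearest cycle.
The slowdown is a worst case: the condense stage usually emits far fewer
bits than it consumes (only call sites and K haplotypes survive), so the
PBWT engine is rarely the bottleneck in practice.

## Synthetic data

Panels draw per-site alternative-allele frequencies uniformly from
[0.05, 0.95] and alleles independently per haplotype — linkage within the
panel is not modelled.  Targets are template-switching mosaics: each
haplotype copies one panel haplotype and switches templates with
probability 0.01 per site, the minimal structure under which K-best
selection has signal and set-maximal matches are long; the per-site
missingness default is 0.02, a typical genotyping-array magnitude.  Two
mosaic haplotypes combine into an unphased genotype; truth haplotypes are
returned for evaluation.  All randomness derives from the single `seed`
field, and every generator is pure in (spec, arguments).  Because the
panel lacks linkage disequilibrium and the mosaic lacks a recombination
map or mutation, passing tests demonstrate structural and algorithmic
correctness — not phasing or imputation accuracy on real cohorts.

## Problem sizes

The test and acceptance sweeps run at desk scale, chosen to cover every
structural regime rather than production volume: PBWT and matching oracles
at N ≤ 64, M ≤ 40 (hundreds of instances); streamed-versus-direct
equivalence on 100 instances spanning selected widths k = 1…200 —
including odd k and sub-bus-word residues — with panels up to N = 512,
M = 300.  The quantities the package computes (equalities, ranks, the
throughput ratios) are size-independent claims checked exhaustively at
these sizes.

## Known limitations

- No windowed/chunked processing of long chromosomes; a panel is held in
  memory as a dense bit matrix.
- No run-length or sparse PBWT compression, multi-allelic support, or
  dynamic updates.
- The phasing search itself (beam search over the PBWT) and real
  imputation (dosages, r², info scores) are out of scope.
- Backpressure between pipeline stages is modelled as unbounded buffering;
  latency and stalling behaviour are not represented.
- Haploid samples (e.g. chromosome X in males) are rejected, not handled.
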