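# Methods

## Scope and model

`svstream` implements a batch-incremental SV-calling core for long-read
data. The unit of input is an alignment batch (SAM/BAM): the package
deliberately consumes alignments rather than raw reads, so that the
streaming logic, clustering and recovery machinery can be specified and
tested independently of any particular aligner. An external aligner can be
put in front of the watch directory without changing anything downstream.

The design invariant that everything else serves is *streaming/offline
equivalence*: for any partition of the input into batches, in any arrival
order, with any number of interim cycles or crash/resume events, the final
callset is byte-identical to a single offline pass. Three properties
combine to give this guarantee:

1. signature extraction is per-read, hence additive over batch partitions
   that keep one read's records together (batches are written that way);
2. the signature store and depth track are order-insensitive accumulators,
   and clustering iterates them in a canonical order (contig-table order,
   type, start, read id) rather than insertion order;
3. `call_variants` is a pure function of (store, depth, parameters), and
   the VCF writer injects fixed header metadata (file date, source) so
   equal callsets produce equal bytes.

## Signature extraction

Intra-alignment evidence: every CIGAR `D`/`I` op is a candidate regardless
of size. Same-type candidates on one read whose anchors lie within
`merge_dist` (default 500 bp) chain into one event — merging happens
*before* the `min_size` filter (default 30 bp), so a deletion fragmented by
a short matched spacer is still recovered at its full length. Merged
deletions keep the first start and sum lengths; merged insertions anchor at
the length-weighted mean position, rounded half-up — a deterministic choice
that is stable under permutation of the merged ops.

Inter-alignment evidence: segments of one read (primary + SA-tag
supplementaries, query coordinates normalised to the forward strand) are
sorted by query start, and only *consecutive* pairs generate signatures.
This bounds work per read and matches split-alignment semantics; it also
means a three-segment read across an inversion yields pair-wise evidence
rather than one reconstructed event — nested/complex SV reconstruction is
out of scope. Supplementary segments must carry mapq ≥ 20 and span ≥ 300 bp
of reference (`min_segment_len`); reads whose primary mapq < 20 contribute
nothing (single gate at batch reading).

Defaults (min_size 30, mapq 20, merge 500, per-type cluster biases) follow
the conventions long-read SV callers have converged on; all are exposed in
`ExtractionParams`/`ClusterParams` and the CLI's `--config` YAML.

## Clustering, support threshold, genotyping

Clustering is a greedy linear scan per (contig, type) with per-type
position biases (DEL 200, INS 100, INV 500, DUP 500, BND 50 bp); gaps
chain, so clusters can exceed the bias end to end. Cluster summaries use
the lower median (deterministic for even counts) and count *distinct*
supporting reads, so one chimeric read cannot inflate support.

The support threshold is `clamp(round(0.1 · mean_depth), 2, 10)`, a
piecewise-constant function of run-level mean depth. The run-level (not
local) depth drives it: the threshold is a property of how much data the
run has produced, and stepping it globally produces the characteristic
transient dips in the detection-rate curve exactly when the threshold
increments. The exact functional form is a documented package choice; only
its stepwise character matters to the feedback behaviour.

DR at a locus is inferred from the binned depth track
(`round(local_depth) − DV`, floored at 0) rather than by re-querying spent
batches; the bias of this estimate is bounded by bin granularity (1 kb
default) and keeps the pipeline strictly forward-streaming. Genotypes
maximise the binomial posterior over alt-read probabilities
{ε, ½, 1−ε}, ε = 0.1, uniform prior, ties broken toward the lower-alt
genotype; quality is −10·log₁₀(posterior error), capped at 100. For ε = 0.1
no exact likelihood ties exist (a tie would need 9^dr = 5^n), so the
float implementation agrees with an exact rational-arithmetic oracle
everywhere it is tested (all dv+dr ≤ 60).

## Streaming, checkpoints, recovery

File readiness is defined purely by the two-poll rule: unchanged size and
mtime across two polls separated by the stability window (default 5 s,
configurable to milliseconds). OS event hooks could accelerate discovery
but never define readiness. The fixture writes each batch to a temp name
and renames it, so partially written files are never seen as stable.

Checkpoints (versioned JSON: ledger with content checksums and per-batch
signature counts, full signature store, depth bins, cycle counter, rate
history, parameter snapshot) are written after every batch and every cycle
via write-temp-then-atomic-rename. Recovery reloads the last complete
checkpoint (a corrupt one falls back to a fresh state, re-queuing
everything), verifies every ledger entry's checksum against the file on
disk — a mismatch is a hard error, because a mutated input invalidates the
accumulated state — deletes interim VCFs the checkpoint has not sealed, and
queues stabilized files absent from the ledger. Checksums cover the first
and last 64 KiB plus the length: enough to detect truncation and in-place
edits without re-reading whole batches. One engine instance owns an output
directory (lock file); scaling across sequencing chips means one engine per
chip directory.

## Feedback and evaluation

The feedback statistic is truth-side coverage ("detection rate"): the
fraction of a truth set, restricted to common variants (AF strictly > 0.1;
records with missing AF fail the filter), matched by ≥ 1 call. Matching
uses community benchmarking conventions: breakpoints within 1 kb, size
ratio ≥ 0.7 for length-bearing types, type-strict by default, breakends on
contig/position only. Truth-side counting makes the statistic monotone in
the callset. Call-side precision/recall/F1 against a same-sample truth is
available offline (`svstream evaluate`, `feedback.benchmark`) but is not
part of the feedback loop. The stop signal is a recommendation in the
report and log; the engine never terminates an external process.

## Synthetic fixture

The generator emulates batch-wise sequencer output: equal-size batches of
reads materialised into a directory at a configurable interval (the study
conditions scale down a real run's equal-read-count batching at fixed
intervals). Defaults: 2 × 500 kb uniform-random contigs; 40 implanted SVs
(12 DEL, 12 INS, 6 INV, 6 DUP, 4 BND) with ≥ 2 kb spacing, 50% heterozygous,
AF ~ U(0.02, 0.6); 20× coverage of N(8 kb, 2 kb) reads; breakpoint jitter
N(0, 10 bp); 10% per-read evidence dropout (the read is drawn from the
reference allele); background 1–10 bp indels at 0.2/kb, i.e. strictly below
`min_size`, so the size filter is exercised without ambiguous truth.

DEL/INS sizes default to 50–500 bp. INV/DUP default to 800–2000 bp: the
segment-pair geometry requires each supplementary segment to span ≥ 300 bp
of reference, so split-based detection of balanced events much below
~600 bp is geometrically impossible — the fixture implants events the
detector's evidence model can represent. Split-read support for INV/DUP/BND
is constructed explicitly (Poisson(coverage) spanning reads thinned by
zygosity and dropout) with SA tags and query intervals exactly consistent
with the extractor's geometry rules.

What the fixture does *not* emulate: base-level sequencing error, mapping
ambiguity in repeats, soft-clip-only evidence, nested SVs, reference bias,
or aligner-specific split conventions. Passing tests therefore demonstrate
the correctness of the streaming/clustering/recovery machinery and of the
evidence geometry handling — not calling accuracy on real noisy genomes.

## Problem sizes and numerical choices

Tests and the acceptance script use the default fixture (1 Mb genome, 20×,
~2 500 reads, 10 batches) and a 2 × 200 kb / 60× variant to exercise
threshold stepping — sizes chosen so every end-to-end property (streaming
equivalence, three crash points, detection-rate shape) runs in seconds
while keeping ≥ 4 supporting reads on the weakest implanted event.
Rounding is half-up everywhere a threshold or anchor is computed
(`floor(x + 0.5)`), lower medians break even-count ties, and VCF conversion
to 1-based coordinates happens at exactly one boundary. Degenerate inputs:
header-only batches contribute nothing; an empty store calls nothing; an
empty truth set makes the detection rate a hard error rather than a silent
0/0.

## Known limitations

* Coupled to its own extraction conventions; CRAM, phased genotypes and
  multi-sample VCFs are out of scope.
* DR from binned depth slightly misestimates reference support near bin
  edges and in high-variance coverage.
* The detection-rate statistic inherits the representativeness of the
  supplied truth set; with a population truth set, rates differ across
  samples from different populations.
* mtime granularity bounds how small the stability window can usefully be
  on coarse filesystems.
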