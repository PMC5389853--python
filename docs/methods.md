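# Methods

This note documents the models and procedures implemented in exocrac,
the parameter defaults and why they were chosen, what the synthetic
library generator does and does not emulate, and the numerical and
design decisions a maintainer would want written down.

## The experimental setting being modelled

CRAC libraries capture the RNA footprints of a tagged protein: RNA is
UV-crosslinked to the protein in vivo, partially digested, ligated to
a 3' adapter and a 5' linker carrying three random nucleotides,
reverse-transcribed, PCR-amplified and sequenced. Three sequence-level
signatures matter downstream:

1. **PCR duplicates** share the insert and the 3-nt random barcode;
   distinct molecules essentially never do. Collapsing on
   (insert, barcode) therefore recovers molecule counts.
2. **Crosslink sites** appear as single-nucleotide deletions
   introduced by reverse transcriptase reading through the
   crosslinked residue.
3. **TRAMP substrates** carry short non-encoded oligo(A) tails at the
   read 3' end.

## Pre-processing

Adapter trimming keeps the longest 3'-anchored adapter match covering
at least `min_overlap` = 4 adapter bases with at most `max_mismatch` =
1 mismatch, and rejects reads without a qualifying match — only
adapter-containing reads are complete cDNAs. These two defaults encode
the conventional trimmer settings for this library type and are both
exposed as flags.

Duplicate collapsing defaults to sequence mode (identical full insert
plus identical barcode), because collapsing happens before alignment;
a coordinate mode (alignment end-coordinates plus barcode) exists for
mapped data. Ambiguous bases never match: a read with an N in its
barcode or insert always keeps its own identity. Output order is
sorted by key, so collapsing is deterministic and idempotent.

The low-complexity rule drops reads whose longest single-nucleotide
run exceeds 75% of the read length. Whether the 75% criterion refers
to the longest run or to overall base composition is genuinely
ambiguous; both are implemented (`mode="run"` is the default, and the
mode used is recorded in the report). The filter is *not* applied in
the tRNA-database branch: oligo(A)-tailed tRNA reads are legitimately
A-rich and would be destroyed. A mean-Phred quality filter (default
off, threshold 20 when enabled) stands in for the unspecified
"quality filtered" step.

## The small-reference aligner

Genome-scale gapped alignment is out of scope (SAM/BAM ingestion
covers it). The built-in aligner serves the flanked tRNA database and
toy genomes: it is mismatch-only plus at most one 1-nt read deletion,
the crosslink signature. Candidate placements come from exact k-mer
seeds (k = 6) tiled across the read; by pigeonhole, a read with at
most `max_mismatch` = 2 substitutions over >= 4 disjoint seeds cannot
escape candidate generation, and a deletion only shifts downstream
seeds by one (both shifted candidates are verified). Verification is
vectorized mismatch counting with a prefix-sum scan over all possible
deletion positions.

Scoring is mismatches + 0.5 per deletion. The half-point penalty makes
an ungapped placement at equal mismatch count strictly better than a
gapped one, which prevents spurious gapped ties across near-identical
gene copies, while still letting a genuine crosslink deletion
(score 0.5) outrank any one-mismatch alternative. All placements tied
at the minimum score are returned and `n_hits` set to the tie count —
a deterministic replacement for an aligner's "random" multi-mapping
policy, and strictly more informative. `min_aligned` = 15 nt is the
smallest footprint accepted; a read one base shorter may still align
in deletion mode, since it then spans 15 reference bases. Within a
homopolymer run a deletion is placed at the leftmost equivalent
position (all positions in the run yield the same sequence).

## Pre-tRNA versus mature tRNA

The database holds every tRNA gene with 15 nt of genomic context on
each side, in transcript orientation. Reads with a unique best
placement necessarily overlap a flank and are counted as pre-tRNA of
that gene; reads tied across several copies of a single family are
counted as the mature pool of the family (one row per family in count
tables); ties spanning different families are reported as ambiguous.
Classification is a pure function of the sense-strand hit set;
antisense hits are kept but flagged and excluded from counting by
default. The mismatch allowance for this branch (default 2) is a
documented assumption.

## Oligo(A) tail calling

For each insert the maximal 3' A-run is stripped; the remaining body
(minimum 15 nt, else no-call) is aligned; reference A's immediately
downstream of the body's 3' end absorb up to the full run
(they could have been templated); the remainder is the non-encoded
length, and `min_tail` = 2 non-encoded A's call the read tailed —
1-nt tails are indistinguishable from sequencing error. The run must
be pure A; mixed tails are out of scope. When the body ties across
identical gene copies the most A-rich tied context is used for
absorption: the true origin is among the ties, so this can only make
the caller more conservative, never produce a false tail.

A tail followed by genomic A's is intrinsically partially
unobservable; absorption under-calls it by the length of the genomic
A-run. This is a property of the data, not the implementation, and
the no-call and absorption columns in the tail table expose it. The
tailed-fraction summary supports two denominators: all reads (no-calls
count as untailed — the stratification convention) or callable reads
only (the estimator used when recovering a planted fraction).

## Quantification, clustering, profiles, pathway

Counting windows: mRNA = [TSS, polyA); other non-tRNA classes = gene
+/- 50 nt; tRNA counts are injected from the pre/mature assignment.
A read counts for every window it overlaps by >= 1 nt on the sense
strand (a `primary_only` option keeps the maximal-overlap window);
multimapped reads count once, at the lowest-coordinate placement.
RPM/RPKM layers are always regenerated from the raw layer, so the
round trip is exact by construction. Replicate averaging is the mean
by default, with a deepest-replicate policy for constructs where one
replicate is much shallower. Top-N selection ranks by the averaged
values of a configurable reference sample (Rrp44-exo by convention,
since no ranking sample is canonical), with ties broken toward the
lexicographically smaller id.

Clustering reduces each gene to (exo fraction, exo-S1 fraction) by
row-sum normalization — the relative-binding reading; a unit-magnitude
variant is available and the variant used is recorded in outputs.
k-medians (k = 4) uses Euclidean assignment with component-wise median
updates, reseeding empty clusters from the farthest point, best of 50
seeded restarts. Restart seeding indexes rows through a canonical
lexicographic ordering, so results are invariant to row permutation at
fixed seed. Labels are renumbered by ascending mean exo-S1 fraction:
cluster 1 is the most S1-dependent (direct access), cluster 4 the
least (threaded).

Pileup tracks live in transcript orientation and count full read
bodies by default (an ends-only mode counts 5' ends); coverage,
deletion and substitution layers are kept separately, with optional
per-million scaling. Metagene matrices shift each track so the anchor
is column zero; out-of-window mass is excluded *and reported*, so
matrix mass plus out-of-window mass equals total track mass exactly.
Heatmap row order defaults to descending mature length. Two-bin
fractions split the mature tRNA at its midpoint (odd lengths give the
extra base to the 5' bin); flanking signal is excluded unless
requested; zero-hit tRNAs are dropped. Pearson correlations are
computed on replicate-averaged 5'-fraction vectors over shared tRNAs
(minimum 3).

The pathway ratio is WT/channel on replicate-averaged RPKM, undefined
when either mean is zero. Orientation matters and is inferred rather
than stated anywhere authoritative: per-million normalization means
global depletion of cytoplasmic substrates in the channel mutant
*raises* unaffected (nuclear) transcripts' channel-strain RPKM, so
nuclear substrates land below 1 and the < 0.8 rule calls them. The
orientation is switchable by flag for readers who prefer the inverse.
Boundary values are intermediate (strict inequalities); the upper
(cytoplasmic) threshold defaults to 1.25. Tables are sorted
ratio-ascending, most-nuclear first.

## The synthetic library generator

The generator is first-class, tested code, and its defaults define the
conditions under which the pipeline's properties are demonstrated.

Genome: one chromosome (default 50 kb, base composition
A/C/G/T = 0.3/0.2/0.2/0.3), with 5 tRNA families x 3 copies
(mature length 70-90 nt, 20% of families carrying a 15-nt intron),
10 mRNAs (400-1,500 nt), 4 snoRNAs, 4 CUTs, 4 SUTs, optional rDNA
unit. Genes are packed without overlap with >= 40 nt gaps and an
80-nt edge margin; all copies of a family carry a string-identical
gene sequence with unique random 15-nt flanks (verified at build
time). Coordinates are 0-based half-open internally; GFF3 output is
1-based inclusive.

Library model per sample: positional mixture components
(anchor in {5' end, 3' end, TSS, mature 3' end} + offset + spread)
place footprint 5' starts; footprint length is normal (default
22 +/- 3 nt, floor 15 — a plausible protein footprint, chosen as an
assumption, not an inference). Defaults: crosslink-deletion
probability 0.15 per read (uniform in the middle third of the
footprint, at most one); substitution error rate 0.002/base (typical
short-read error); PCR duplication geometric with mean 3; oligo(A)
tail probability per class (0 unless configured), geometric length
with mean 4 and minimum 2; 10% of reads carry a truncated (< 4 nt)
adapter to exercise the rejection path. Reads are
barcode + insert (+ tail) + adapter with uniform-random 3-nt barcodes,
emitted in shuffled order with a per-molecule truth table.

Three identifiability guarantees make truth labels exact rather than
statistical, each switchable:

- `collision_free` rejects (insert, barcode) collisions between
  distinct molecules, so collapsing recovers molecule counts exactly.
- `distinguishable_tails` plants tails only at footprints whose
  downstream reference base is not A, so the planted tail length
  equals the observable non-encoded length (no genomic absorption of
  truth).
- `distinguishable_boundaries` rejects tRNA footprints whose flank
  overlap is matched base-for-base by a sibling copy's flank — such
  reads are sequence-identical between copies and no aligner could
  attribute them, so the planted per-copy truth would be meaningless.

What the generator does **not** emulate: position-dependent quality
degradation, indel sequencing errors (only crosslink deletions),
ligation and RT sequence biases, paired-end reads, spliced mature
tRNAs (footprints are genomic, so "mature" cores include introns), or
chimeric/adapter-dimer artifacts. Passing tests therefore demonstrate
the correctness of the pipeline's logic under a clean generative
model, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script use library sizes of 1,000-10,000
molecules on the 50-kb toy genome, sizes at which every property they
check is already stable; brute-force oracles (all-position alignment
scans, run enumeration, exhaustive k-medians partitions at n = 8)
remain exact at these scales. The dedup-exactness measurement sets
adapter truncation to 0 — with truncated adapters present, molecules
whose every copy is rejected at trimming are unrecoverable by any
collapser, and that rejection path is exercised separately. The
planted-tail recovery conditions (23% and 2%) mirror the tailed-read
fractions characteristic of exosome versus RNA-polymerase CRAC
samples. The channel-mutant study depletes cytoplasmic transcripts
5-fold at >= 200 molecules per transcript with two strains of equal
molecule budget before depletion.

Floating-point conventions: row-normalized fractions sum to 1 within
1e-12; k-medians convergence tolerance 1e-12 on the objective;
Pearson/Spearman come from scipy.stats. Degenerate inputs (zero rows,
empty clusters, zero denominators, unresolvable anchors, zero-hit
tRNAs) are dropped-and-reported or emitted as missing values rather
than silently imputed; hard errors are reserved for contract
violations (negative counts, unknown classes, k > n).

## Known limitations

- The mini-aligner's single-deletion model cannot place two deletions
  in one read; such reads (rare at deletion probability 0.15) go
  unassigned.
- Reads overlapping a tRNA flank by only 1-2 nt are attributable only
  when the flank bases happen to differ between copies; the generator's
  boundary guarantee sidesteps this for truth-based evaluation, but on
  real data such reads inflate the mature pool slightly.
- Tail calling under-calls tails adjacent to genomic A-runs by
  construction; comparisons against external tail-calling pipelines
  must state this convention.
- The k-medians objective (Euclidean distances to component-wise
  medians) follows the Cluster3.0 convention; it is a heuristic target
  and the component-wise median is not the geometric median.
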