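# Methods

## Problem setting

A DNA-barcoding amplicon is a short, taxonomically informative gene
fragment — here a 421 bp insert standing in for a mitochondrial
cytochrome-b barcode — PCR-amplified between a primer pair (25/26 nt) and
flanked by dual 24-nt sample indexes, then sequenced on a nanopore device.
Basecalled reads carry roughly 9% per-base error (mean Phred quality
≈ 10.5, since Q = −10·log10(p) and 10^(−1.05) ≈ 0.089), arrive in both
strand orientations, and indels concentrate in homopolymer runs. The
pipeline's job is to assign each read to its sample, reject junk, and
distil one accurate consensus barcode per sample for comparison against
reference sequences.

## Read simulator

The simulator generates the full indexed molecule
`fwd_index + fwd_primer + insert + rc(rev_primer) + rc(rev_index)` (or its
reverse complement with probability `1 − strand_fraction`, default 0.5)
corrupted by a per-base independent error process:

| parameter | default | meaning |
|---|---|---|
| `sub_rate` | 0.03 | substitution probability per base (new base ≠ old) |
| `ins_rate` | 0.03 | insertion after each base (uniform random base) |
| `del_rate` | 0.03 | deletion probability per base |
| `homopolymer_del_multiplier` | 3 | factor on `del_rate` inside runs ≥ `hp_min_len` |
| `hp_min_len` | 3 | minimal run length counting as a homopolymer |
| `mean_read_quality` | 10.5 | centre of the per-read quality draw (Phred) |
| `quality_sd` | 1.5 | spread of the per-read quality draw |

The 3%/3%/3% split is a calibration choice: only the total (~9%,
matching mean read quality 10.5) is anchored in reported run statistics for
this class of data; per-class rates are not published, so they are split
evenly with deletions up-weighted in homopolymers, reproducing the
qualitative error structure (indel-dominated residual errors in runs).
Quality is drawn per read — Normal(10.5, 1.5), clamped to [2, 40] — and
held constant across the read, because per-read means are the reliably
reported quantity at this scale; per-base quality variation carries no
information in this model. An optional `chimera_rate` concatenates two
template copies to exercise the length filter.

The bundled references are deterministic synthetic stand-ins (fixed
internal seeds): two 421-bp inserts at ~79% mutual identity with embedded
homopolymer runs (4–6 nt), one primer pair, and an index panel with
pairwise edit distance ≥ 10. Real barcode sequences are database
accessions and are not shipped; any user-supplied FASTA works in their
place.

What the simulator does **not** model: signal-level artefacts, basecaller
miscalls correlated along the read, quality–error correlation within a
read, sample-specific amplification bias, and adapter/chimera structure
beyond simple concatenation. Consequently, passing tests demonstrate the
pipeline's algorithmic behaviour under the stated error model, not
performance on any particular real flow cell.

## Demultiplexing

Both indexes of a pair must be found near the appropriate read ends
(search window 150 bp) by semi-global alignment; single-end hits stay
unassigned, and a tie between two index pairs is ambiguous → unassigned.
Assigned reads are re-oriented forward-index-first, which makes the
downstream pipeline strand-uniform.

*Score mode* defines score = 100·(L − edits)/L per index, takes the worse
of the two, and assigns at `min_score` (default 99). For 24-nt indexes
this threshold admits only exact matches (one edit scores 95.8), so at 9%
per-base error it retains ≈1% of reads — an intentionally stringent
regime in which consensus accuracy is tested on very few reads.
*Edit mode* admits up to 2 edits per index (retaining ≈40% of simulated
reads) and additionally trims primers located within 11 edits; a primer
that cannot be located is kept (under-trimming is preferred to cutting
barcode sequence).

The 11-edit primer budget is safe during demultiplexing because the primer
sits at a known position next to a located index. For primer trimming of
the *final consensus*, position is unknown and the best chance match of a
25-nt primer against unrelated sequence has edit distance ~9–12, inside
an 11-edit budget; consensus trimming therefore adds an absence guard —
a hit is trusted only at ≤ 0.25 × primer length edits (6 for a 25-mer).
Polished consensuses place true primers at 0–3 edits, far below the guard.

## Filtering and subsetting

Mean read quality is the error-probability average
`−10·log10(mean(10^(−q_i/10)))`; the arithmetic mean of Phred values would
overstate accuracy and silently loosen the Q ≥ 7 filter. Length bounds
(321–521 bp, inclusive) are a ±100 bp buffer around the 421 bp insert and
are applied to the demultiplexed, trimmed read. Subsetting is uniform
without replacement with a fixed seed; requesting more reads than exist
returns everything with a warning.

## Clustering

Reads are processed in descending mean-quality order. Each read's
minimizer sketch (lexicographic minimizers, k = 13, window 5) is compared
against each existing cluster's *profile* — the union of its first 8
members' sketches — and the read joins the first cluster containing at
least `min_shared_fraction` (default 0.10) of its minimizers, else founds
a new cluster. Clusters holding strictly more than 10% of the reads that
entered clustering survive the gate.

The threshold is a fraction-of-intact-seeds criterion, not sequence
identity: at ~9% error a 13-mer survives in a read with probability
≈ 0.91¹³ ≈ 0.29, so sharing against a multi-read union profile is ≈ 0.2–0.35
for same-template reads and ≤ 0.05 for templates below 80% identity —
measured margins of ≥2× on both sides of the default. A single-read
profile would be too noisy (sharing ~0.09 with a wide tail), which is why
the profile pools several members; the recorded representative (the
founding, highest-quality member) orders consensus construction.
Comparison is same-strand only: opposite-orientation reads share no
minimizers and form separate clusters that the merge stage reconciles.
Minimizer selection is not strand-symmetric, so reads sitting exactly at
the join threshold may decide differently if the whole input is
reverse-complemented; away from the threshold the partition mirrors
exactly.

## POA consensus

Sequences are progressively aligned into a base-labelled DAG. The
read-vs-graph dynamic programming is global in the read with free graph
end gaps, linear gap scoring (match +2, mismatch −4, gap −4), vectorised
along the read axis with numpy; matched bases reuse nodes, mismatches
extend a column's ring of alternatives (with a topological-rank guard that
keeps the graph acyclic), insertions create fresh nodes. Edge weights
count traversing reads; the consensus is the heaviest source-to-sink path
(ties: smaller node id).

Only the 100 highest-quality members of a cluster enter the graph — the
draft saturates long before that, and polishing later uses every
supporting read; this bounds graph growth and keeps desk-scale runs in
seconds. With gap = mismatch − match (e.g. −6) and diagonal-preferring
ties, the POA consensus of gap-free equal-length inputs provably reduces
to per-column majority, and the test suite verifies that reduction at that
scoring; the default −4 is kept for real reads because a harsher gap
penalty distorts alignments of genuinely indel-rich nanopore reads and
measurably degrades draft length accuracy.

## Merge, majority, polish

Cluster drafts are grouped by single linkage when
`max(identity(a,b), identity(a, rc(b))) ≥ 0.9`, with identity = matches /
length of the shorter sequence under a free-end-gap global alignment —
the convention of global nucleotide clustering tools, and robust for
drafts whose residual error would otherwise put a true strand pair at the
cutoff. The group with the most supporting reads is the majority (ties:
higher mean read quality, logged); its fraction of the reads that entered
clustering is the reported `fraction_reads_clustered`.

Polishing aligns every majority-group read to the draft of the majority
group's largest cluster (edlib, global), accumulates per-column votes over
{A, C, G, T, deletion} and per-junction insertion candidates, and rewrites
the draft by majority; insertions require a strict majority of aligned
reads. A tied column keeps the draft call — at an even split the reads
carry no usable signal and the draft, built from whole-read context,
stands. Two rounds by default, stopping early at a fixed point; error-free
reads are a fixed point by construction. Residual consensus errors
concentrate where half the reads share a homopolymer deletion — the known
failure mode of this data type — and shrink rapidly with read depth.

## Identification

The trimmed consensus is aligned globally (free end gaps, both
orientations) against every reference in the panel; the best hit by
percent identity (100 · matches / alignment length) is reported with the
number of identical aligned positions (`matching_length`). Criteria:
identity > 99%, matching length within ±5 bp of the expected 421 (the
"≈421 bp" working definition), and an `investigate` flag when fewer than
75% of filtered reads support the consensus. Exhaustive pairwise alignment
against the supplied panel replaces a database search; with reference
panels of a handful of sequences this is exact and dependency-free.

## Problem sizes and determinism

The shipped acceptance computations use 500 reads (clean sample, score
mode — retaining ~5–10 reads, deliberately the stringent few-read regime),
1000 reads with 22% contamination (edit mode, ~400 retained), and a
12 000-read simulation for the 100/500/5000-subset benchmark grid; these
sizes keep a full run in tens of seconds while leaving every measured
quantity well inside its sampling noise. Every stochastic step (simulation,
quality draws, subsetting) flows from explicit seeds; a rerun with the same
inputs, configuration and seed writes byte-identical artifacts.

## Known limitations

- Small-sample stochasticity in score mode: with ~5–10 surviving reads,
  consensus identity fluctuates around 99–100% and the trimmed length can
  land at 420 ± a few bp on unlucky draws — an irreducible consequence of
  the exact-index regime, not of the consensus machinery (edit mode at the
  same depth is stable at 100%/421).
- Mixed-species samples are resolved only to the majority species;
  minority groups are reported via the reduced majority fraction, not
  separately identified.
- The greedy clustering is a deliberate simplification of quality-aware
  long-read clustering; its statistical acceptance rule is a shared-seed
  fraction, verified against a brute-force identity oracle at desk scale.
- No affine gap model in POA; linear gaps are adequate at amplicon length
  but would misplace long indels in repeat-rich templates.
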