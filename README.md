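# ampcon — nanopore amplicon barcoding consensus

`ampcon` turns error-prone nanopore amplicon reads into accurate DNA
barcode sequences for species identification. It is a self-contained,
native re-implementation of the clustering-based consensus workflow used
for portable MinION barcoding of wildlife samples: each sample's ~421 bp
mitochondrial barcode (e.g. cytochrome b) is PCR-amplified between a primer
pair, flanked by dual 24-nt sample indexes, and sequenced to reads with
~9% per-base error (mean Phred quality ≈ 10.5). The pipeline recovers a
consensus typically >99% identical to the true barcode.

The package is aimed at people building or studying such pipelines —
there is no dependence on external bioinformatics binaries, and a bundled
read simulator with known truth makes every stage testable at desk scale.

## Pipeline

```
reads.fastq
  → demultiplex   dual-index assignment; two modes:
                    score:  per-index score 100·(L−edits)/L, min-score 99
                            (exact dual-index match for 24-nt indexes)
                    edit:   ≤2 edits per index, primers trimmed within ≤11 edits
  → filter        mean quality ≥ Q7 (error-probability average), 321–521 bp
  → subset        optional seeded random subsample (100/500/5000-read grids)
  → cluster       greedy minimizer clustering, quality-ordered, strand-aware;
                  clusters with >10% of reads retained
  → consensus     partial order alignment (POA) draft per cluster
  → merge         reverse-complement-aware grouping of drafts at 0.9 identity
  → majority      group with the most reads wins; its fraction is reported
  → polish        rounds of alignment-pileup majority voting over all reads
  → trim + id     primer removal, global-alignment identity vs a reference panel
```

The consensus core is an in-package partial order alignment: reads are
progressively aligned into a base-labelled DAG (match +2, mismatch −4, gap
−4; graph end gaps free) whose edge weights count traversing reads, and
the consensus is the heaviest source-to-sink path. Polishing re-aligns
every supporting read to the draft and takes per-column majorities over
{A, C, G, T, deletion} plus strictly-majority-supported insertions.

A sample passes identification when the consensus matches a reference at
**>99% identity** over **≈421 matching bases**, and the fraction of
filtered reads behind the consensus (**≥75%** expected; lower values flag
the sample for investigation of error or contaminant clusters) is
reported alongside.

## Worked example

`examples/01_clean_sample_run.py` simulates one clean sample and runs the
whole pipeline:

```
$ python examples/01_clean_sample_run.py
simulated 500 reads, mean length 514 bp
demultiplexed: 8 reads (exact dual-index matches only at min-score 99)
filtered:      8 reads (mean Q >= 7, 321-521 bp)
majority group: 100.0% of filtered reads
consensus:     421 bp after primer trimming
identity:      100.00% to insert_A (421 matching bases)
flags:         {'identity_pass': True, 'length_pass': True, 'investigate': False}
```

Reading the numbers: at ~9% per-base error only ~1% of reads carry both
24-nt indexes error-free, so score-mode demultiplexing keeps 8 of 500 reads
— yet the POA draft plus pileup polishing already reconstructs the exact
421-bp barcode from them, with every filtered read in the majority group.
`examples/02_contaminated_sample.py` shows the same machinery isolating a
22% contaminant species (majority fraction drops to ~76–80%, identification
still correct), and `examples/03_subset_benchmark.py` sweeps read-depth ×
demultiplexer grids.

A thin CLI mirrors the library:

```
ampcon sim --n 500 --seed 42 --out reads.fastq --truth truth.tsv
ampcon run reads.fastq --panel panel.tsv --primers primers.fasta \
           --references refs.fasta --mode score --outdir out/
ampcon benchmark reads.fastq --panel panel.tsv --primers primers.fasta \
           --references refs.fasta --subset 100 --subset 500 --out grid.tsv
```

## Layout

- `src/ampcon/` — library: `seq_io`, `simulate`, `demux`, `read_qc`,
  `clustering`, `poa`, `consensus`, `species_id`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `tests/` — pytest suite (unit, property, and acceptance tests)
- `docs/methods.md` — models, parameters, numerical choices, limitations
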