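# circkit

Consensus circRNA calling, annotation and benchmarking toolkit.

Circular RNAs (circRNAs) are covalently closed transcripts formed by
back-splicing, detected in RNA-seq as reads spanning the back-splice
junction (BSJ). Every BSJ caller has its own output format, coordinate
convention and error profile, so robust circRNA profiling combines several
callers and keeps only well-supported candidates. `circkit` implements that
combination layer for seven callers — CIRCexplorer2, CIRIquant/CIRI2,
circRNA_finder, DCC, find_circ, MapSplice and Segemehl — for
bioinformaticians who already have caller outputs and want a defensible
consensus call set with annotation and benchmarking.

## What it computes

* **Dialect normalisation** — each caller's tab-separated output is mapped
  to canonical 0-based half-open calls `(chrom, start, end, strand,
  bsj_reads)` by a declared, invertible dialect description.
* **Filtering and consensus** — calls need ≥ `bsj_filter` junction reads
  (default 2) and a circRNA key must be reported by ≥ `tool_filter` callers;
  per-tool counts aggregate by `max` or `mean` into a circRNA × sample count
  matrix.
* **Four-case annotation** — against a GTF, each circRNA is classified as
  exonic circRNA (both ends on, or within `exon_boundary` = 200 bp of, exon
  boundaries of a transcript), EI-circRNA (an end beyond the tolerance),
  ciRNA (intronic) or intergenic, written as extended BED12 (type, parent
  gene, transcript, mature spliced length) plus the mature sequence FASTA.
* **MRE intersection** — miRanda and TargetScan predictions are kept only
  when both algorithms call the (circRNA, miRNA) pair; post-hoc filtering
  removes 6mer sites and hybrids with MFE ≥ −20 kcal/mol. A seed-site
  scanner (6mer / 7mer-A1 / 7mer-m8 / 8mer) validates planted fixtures.
* **Benchmarking** — against a truth set with no true negatives:
  precision = 100·TP/detected, sensitivity = 100·TP/|truth|,
  F1 = 2PS/(P+S), all to two decimals; the pairwise common-candidate
  proportion matrix P(i,j) = C(i,j)/N_i; and a combinatorics sweep scoring
  every tool subset at every consensus threshold (sizes 1–6 over 7 tools
  give 126 unique subsets).
* **Fixtures** — a deterministic generator for a toy genome, gene models,
  truth circRNAs of all four classes, caller files with exact planted
  true/false-positive composition, and prediction files with planted MRE
  sites.

## Worked example

Generate a synthetic dataset and run the pipeline:

```bash
circkit fixtures --seed 7 --outdir demo/fix
circkit parse --sample sample_01 --bsj-filter 2 --out demo/calls.tsv \
    $(for t in circexplorer2 ciriquant circrna_finder dcc find_circ mapsplice segemehl; \
      do echo "--input $t=demo/fix/$t/sample_01.txt"; done)
circkit consensus --calls sample_01=demo/calls.tsv --tool-filter 2 --out demo/matrix.tsv
circkit annotate --matrix demo/matrix.tsv --gtf demo/fix/annotation.gtf --out demo/annotated.bed
circkit benchmark --truth demo/fix/truth.bed --bsj-filter 1 --out demo/bench.tsv \
    $(for t in circexplorer2 ciriquant circrna_finder dcc find_circ mapsplice segemehl; \
      do echo "--calls $t=demo/fix/$t/sample_01.txt"; done)
```

The log reports each stage:

```
[circkit 0.1.0] sample_01: 50 circRNAs pass tool-filter 2
[circkit 0.1.0] wrote 50 x 1 matrix to demo/matrix.tsv
[circkit 0.1.0] annotated 50 circRNAs: EI-circRNA=10, ciRNA=10, circRNA=20, intergenic=10
[circkit 0.1.0] circexplorer2: precision 80.0 sensitivity 80.0 F1 80.0
```

Each caller file planted 40 of the 50 truth circRNAs plus 10 decoys, so
every per-tool benchmark row reads 80.00/80.00/80.00 exactly; requiring two
callers (`--tool-filter 2`) removes every caller-unique decoy, leaving
precisely the 50 truth keys. The annotation class counts match the planted
composition (10 exact + 10 near-boundary exonic = 20 circRNA, 10
EI-circRNA, 10 ciRNA, 10 intergenic). A line of the extended BED12:

```
chr1  13233  14348  chr1:13233-14348:+  0  +  13233  14348  0  2  164,264  0,851  circRNA  SYM5  GENE0005.t1  428
```

— a two-exon circRNA of gene SYM5 with a mature spliced length of 428 nt.

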