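# Methods

## Scope and model

`circkit` implements the bespoke computational core of a multi-tool circRNA
analysis: everything between the native output files of seven back-splice
junction (BSJ) callers and the analysis-ready artefacts (count matrix,
annotated BED12, mature FASTA, MRE table, benchmark tables). Running the
aligners and callers themselves, read simulation, and downstream differential
expression are out of scope; established packages cover those steps.

A circRNA is identified throughout by the canonical key `(chrom, start, end)`
in 0-based half-open coordinates. Strand is deliberately excluded from the
identity: caller strand assignments are unreliable, and strand-agnostic
matching maximises cross-tool consensus recall. A surviving record's strand
is resolved by majority vote over the calling tools, with ties going to `+`.
This tie policy is a documented package choice.

## Caller dialects

Each supported caller (`circexplorer2`, `ciriquant`, `circrna_finder`,
`dcc`, `find_circ`, `mapsplice`, `segemehl`) is described by a declarative
`ToolDialect` record: coordinate base (0 or 1), end inclusivity, column
positions and comment prefix. BED-derived outputs (find_circ, CIRCexplorer2,
circRNA_finder, Segemehl) are treated as 0-based half-open; CIRI2/CIRIquant,
DCC and MapSplice as 1-based inclusive. Conversion to the canonical system is
total and invertible (`start0 = start - base`,
`end0 = end - base + end_inclusive`), and the fixture writer is the exact
inverse of the parser, which the round-trip tests enforce. Exact column
layouts vary across caller versions; because the adapters are data, a
correction is a one-line edit, and the synthetic fixtures are the format
contract. Within one tool and sample, duplicate keys merge by summing BSJ
reads, preserving read evidence. Chromosome names match by exact string
equality; no `chr`-prefix normalisation is attempted.

## Filtering and consensus

* `--bsj-filter` (default 2): keep calls with at least that many
  BSJ-spanning reads; the threshold is inclusive.
* `--tool-filter` (default 1): keep keys called by at least that many
  distinct tools. `tool_filter = 1` is the key union, `tool_filter = n` the
  intersection; survivor count is non-increasing in the threshold.
* `--duplicates-fun` (`max` | `mean`): aggregates per-tool read counts for a
  surviving key. `mean` keeps the exact value internally and emits a
  round-half-up integer in the count matrix so count-based downstream tools
  remain applicable.

Consensus is computed per sample; the count matrix rows are the union of
surviving keys across samples, with 0 for absent cells, rows and columns
ordered lexicographically.

## Four-case annotation

Against an ENSEMBL-style GTF (exon features with `gene_id` /
`transcript_id`; `gene_name` falls back to `gene_id`), each consensus call is
classified:

1. no overlapping gene → **intergenic** (`NA` gene/transcript, single
   full-span block);
2. overlapping gene but no exon overlap → **ciRNA** (single block);
3. exon overlap: for every transcript of the overlapping genes with at least
   one exon in the call interval, compute the distance from the call start to
   the nearest exon start and from the call end to the nearest exon end. The
   transcript minimising the summed distance anchors the annotation (ties:
   more exons, then lexicographically smaller transcript id — deterministic
   and insertion-order independent). If both distances are within
   `--exon-boundary` (default 200 bp) the call is an exonic **circRNA**,
   with blocks = the transcript's exons intersected with the call interval
   and the outer block ends snapped to the call ends; otherwise it is an
   **EI-circRNA** with a single full-span block.

Numerical choices: the boundary test is inclusive (`distance <=
exon_boundary`), so the flag value is an attainable bound — the "within
200 bp" phrasing leaves a one-bp ambiguity either way. Candidate genes prefer
the call's strand when it has one (back-splicing is strand-specific), falling
back to either strand because caller strands are unreliable. EI-circRNAs and
ciRNAs carry a single genomic-span block, so their mature length equals the
genomic span: retained intronic sequence is implied and no intron-resolution
is attempted. Distances are measured per transcript, not jointly across
transcripts.

The mature spliced sequence is the concatenation of block sequences in
genomic order, reverse-complemented for minus-strand records; its length
always equals the summed block length.

## MRE intersection and seed sites

miRanda and TargetScan prediction files are parsed and only (circRNA, miRNA)
pairs reported by **both** algorithms are kept — intersection is per pair,
not per site, following the rule that target miRNAs must be called by both
algorithms. Site type and position come from TargetScan (strongest site if
several), score and minimum free energy from miRanda (best-scoring hit).
The post-hoc filter drops 6mer sites and removes hybrids with
MFE ≥ −20.0 kcal/mol; the boundary is removed inclusively.

The bundled seed-site scanner uses the canonical definitions: a 6mer core is
a Watson–Crick match of the target (5'→3') to miRNA nucleotides 2–7;
a match opposite nucleotide 8 upgrades to 7mer-m8, an adenine on the target's
3' flank (opposite nucleotide 1) to 7mer-A1, and both to 8mer. Each position
gets its single strongest label. Junction-spanning sites are found by
scanning the mature sequence extended with its first `len(miRNA) − 1`
nucleotides; only sites starting within the original sequence are reported
(a start inside the appended copy would duplicate a circular position), and
sites whose core crosses the junction are flagged.

## Benchmarking

With a simulated truth set there are no true negatives, so every called key
not in the truth is a false positive. Precision = 100·TP/detected,
sensitivity = 100·TP/|truth|, F1 = harmonic mean of the two, computed from
unrounded values and reported to two decimals, rounding half away from zero.
Truth matching is exact on canonical keys by default, with an optional
±slack bp on both coordinates. The pairwise common-candidate proportion is
P(i, j) = C(i, j)/N_i, satisfying P(i, j)·N_i = P(j, i)·N_j. The
combinatorics sweep enumerates order-free tool subsets (sizes 1–6 over seven
tools give 126 unique subsets) and scores, for each subset and each
`tool_filter` value not exceeding the subset size, the keys called by at
least that many subset members. Recomputing F1 from already-rounded
two-decimal precision/sensitivity can differ from an F1 rounded from
unrounded values by up to 0.01; the tests document which published
combination rows reproduce exactly under each convention.

## Synthetic fixtures

The generator emulates the post-quantification world only — caller output
files, not sequencing reads. Defaults: 2 chromosomes × 50 kb of uniform
random nucleotides; 12 non-overlapping genes (3–6 exons of 80–300 bp,
introns 300–800 bp, intergenic gaps 1.5–3 kb, both strands; every second
gene has a second transcript skipping one internal exon); a 50-record truth
set of 10 exact-boundary exonic, 10 near-boundary exonic (ends shifted
1–50 bp, inside the 200 bp tolerance), 10 exon–intron (end pushed
250–290 bp past the last exon end, beyond the tolerance but inside the
intergenic gap), 10 intronic (50 bp inside an intron) and 10 intergenic
(≥100 bp clear of any gene) circRNAs; per caller, 40 true keys sampled from
the truth plus 10 decoy keys drawn to avoid the truth exactly, with BSJ
reads uniform in 2–50 so the default read filter keeps the composition
intact. These offsets are chosen so each intended class is attainable by
construction given the gene geometry — the generator raises a spec error
otherwise. MRE fixtures plant seed sites by overwriting target bases
(flanking bases forced non-matching so a planted 6mer cannot read as a
stronger type), emit the planted pairs in both prediction formats and decoy
pairs in exactly one each.

Everything is a pure function of the `FixtureSpec` (numpy `SeedSequence`
streams per stage), so identical specs produce byte-identical files.

What the fixtures do **not** emulate: read-level error models, RNase-R
enrichment, expression-correlated read counts, overlapping or nested genes,
and decoy keys that fall near (rather than on) truth coordinates. Passing
tests therefore demonstrate the correctness of the bookkeeping — coordinate
normalisation, filtering logic, classification rules, metric arithmetic —
not the biological performance of any caller on real data.

## Problem sizes and determinism

The default test and acceptance runs use the fixture defaults above (toy
100 kb genome, 50-record truth sets, seven callers, 126-subset sweeps),
which complete in seconds; the published benchmark's full simulated dataset
is reproduced only at the level of its metric arithmetic, from its printed
detected/true-positive counts. All randomness flows from explicit seeds; the
acceptance script derives every stream from its `--seed` argument.

## Known limitations

* Caller dialect layouts are modelled on each tool's published format family
  but are not guaranteed against every released version; the declared-data
  adapters are the intended correction point.
* The both-strands merge policy (strand-agnostic key, majority-vote strand)
  is a package choice; analyses requiring strand-resolved circRNA identities
  should not rely on the consensus key.
* Mature sequences for EI-circRNAs and ciRNAs include intronic sequence by
  construction.
* The MRE stage parses predictor outputs; it does not re-implement miRanda
  alignment scoring or hybrid thermodynamics.
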