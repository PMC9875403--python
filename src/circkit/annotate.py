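"""Reference-guided circRNA annotation.

Each back-splice junction call is classified against the gene model into one
of four classes:

* **circRNA** (exonic) — both ends coincide with exon boundaries of some
  transcript, exactly or within ``exon_boundary`` bp (default 200).
* **EI-circRNA** (exon-intron) — the call overlaps exons but at least one end
  lies more than ``exon_boundary`` bp from the nearest exon boundary,
  implying retained intronic sequence.
* **ciRNA** (intronic) — the call lies within a gene but overlaps no exon.
* **intergenic** — the call overlaps no annotated gene; gene and transcript
  fields are the literal ``"NA"``.

Exonic circRNAs get exon blocks from the best-matching transcript (ends
snapped to the call); EI-circRNAs and ciRNAs get a single full-span block, so
their mature length equals the genomic span (intron retention implied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from Bio.Seq import Seq

from .io import GeneModel, Transcript, extract_sequence
from .records import AnnotatedCircRNA, CircRNACall


@dataclass(frozen=True)
class BoundaryMatch:
    """Distance of a call's ends to the nearest exon boundaries of one transcript."""

    transcript_id: str
    start_distance: int
    end_distance: int

    @property
    def exact(self) -> bool:
        return self.start_distance == 0 and self.end_distance == 0

    @property
    def total(self) -> int:
        return self.start_distance + self.end_distance


def boundary_match(start: int, end: int, transcript: Transcript) -> BoundaryMatch:
    start_d = min(abs(start - s) for s, _ in transcript.exons)
    end_d = min(abs(end - e) for _, e in transcript.exons)
    return BoundaryMatch(transcript.transcript_id, start_d, end_d)


def best_transcript(
    start: int, end: int, candidates: Sequence[Transcript]
) -> BoundaryMatch:
    """Pick the transcript minimising summed boundary distance.

    Ties break deterministically: more exons first, then lexicographically
    smaller transcript id.
    """
    if not candidates:
        raise ValueError("best_transcript requires at least one candidate")
    scored = [
        (boundary_match(start, end, tx), tx)
        for tx in candidates
    ]
    scored.sort(key=lambda pair: (pair[0].total, -len(pair[1].exons),
                                  pair[1].transcript_id))
    return scored[0][0]


def exon_blocks(
    start: int, end: int, transcript: Transcript
) -> Tuple[Tuple[int, int], ...]:
    """Transcript exons intersected with ``[start, end)``, ends snapped.

    The first block's start is snapped down to the call start and the last
    block's end up to the call end, so the blocks tile the call span at its
    extremities even when the call boundary is slightly off the exon boundary.
    """
    blocks = [
        (max(s, start), min(e, end))
        for s, e in transcript.exons
        if s < end and e > start
    ]
    if not blocks:
        raise ValueError("transcript has no exon overlapping the call")
    blocks[0] = (start, blocks[0][1])
    blocks[-1] = (blocks[-1][0], end)
    return tuple(blocks)


def classify_circrna(
    call: CircRNACall,
    model: GeneModel,
    exon_boundary: int = 200,
) -> AnnotatedCircRNA:
    """Apply the four-case decision procedure to one call.

    Candidate genes prefer the call's strand when it has one (back-splicing is
    strand-specific) and fall back to either strand. The boundary test is
    inclusive: a distance equal to ``exon_boundary`` still counts as exonic.
    """
    if exon_boundary < 0:
        raise ValueError("exon_boundary must be >= 0")

    genes = model.overlapping_genes(call.chrom, call.start, call.end)
    if call.strand in "+-":
        same_strand = [g for g in genes if g.strand == call.strand]
        if same_strand:
            genes = same_strand

    span_block = ((call.start, call.end),)
    if not genes:
        return AnnotatedCircRNA(
            call.chrom, call.start, call.end, call.strand,
            "intergenic", "NA", "NA", "NA", span_block,
        )

    overlapping_tx = [
        tx
        for gene in genes
        for tx in model.gene_transcripts(gene.gene_id)
        if any(s < call.end and e > call.start for s, e in tx.exons)
    ]
    if not overlapping_tx:
        gene = genes[0]
        return AnnotatedCircRNA(
            call.chrom, call.start, call.end, call.strand,
            "ciRNA", gene.gene_id, gene.gene_name, "NA", span_block,
        )

    match = best_transcript(call.start, call.end, overlapping_tx)
    tx = model.transcripts[match.transcript_id]
    gene = model.genes[tx.gene_id]
    if match.start_distance <= exon_boundary and match.end_distance <= exon_boundary:
        return AnnotatedCircRNA(
            call.chrom, call.start, call.end, call.strand,
            "circRNA", gene.gene_id, gene.gene_name, tx.transcript_id,
            exon_blocks(call.start, call.end, tx),
        )
    return AnnotatedCircRNA(
        call.chrom, call.start, call.end, call.strand,
        "EI-circRNA", gene.gene_id, gene.gene_name, tx.transcript_id,
        span_block,
    )


def mature_sequence(record: AnnotatedCircRNA, genome) -> str:
    """Concatenated block sequence in genomic order, strand corrected.

    For minus-strand records the reverse complement of the concatenation is
    returned; length always equals ``record.mature_length``.
    """
    parts = [
        extract_sequence(genome, record.chrom, s, e, "+")
        for s, e in record.blocks
    ]
    seq = "".join(parts)
    if record.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def annotate_all(
    calls: Iterable[CircRNACall],
    model: GeneModel,
    exon_boundary: int = 200,
) -> List[AnnotatedCircRNA]:
    return [classify_circrna(c, model, exon_boundary) for c in calls]
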