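"""Four-case classification, transcript selection, blocks and sequences."""

import random

import pytest

from circkit.annotate import (
    best_transcript,
    boundary_match,
    classify_circrna,
    exon_blocks,
    mature_sequence,
)
from circkit.io import GeneModel, Transcript
from circkit.records import AnnotatedCircRNA, CircRNACall


def _call(start, end, chrom="chr1", strand="+"):
    return CircRNACall(chrom, start, end, strand, 5, "tool", "s")


class TestFourCases:
    """Toy transcript T1 has exons [100,200) and [300,400) (conftest)."""

    def test_exact_boundaries_exonic(self, toy_model):
        ann = classify_circrna(_call(100, 400), toy_model)
        assert ann.circ_type == "circRNA"
        assert ann.transcript_id == "T1"
        assert ann.gene_name == "GENE_ONE"
        assert ann.blocks == ((100, 200), (300, 400))
        assert ann.mature_length == 200

    def test_near_boundaries_still_exonic(self, toy_model):
        ann = classify_circrna(_call(95, 405), toy_model, exon_boundary=200)
        assert ann.circ_type == "circRNA"
        assert ann.blocks == ((95, 200), (300, 405))

    def test_far_boundary_is_exon_intron(self, toy_model):
        # end 250 bp past the nearest exon end
        ann = classify_circrna(_call(100, 650), toy_model, exon_boundary=200)
        assert ann.circ_type == "EI-circRNA"
        assert ann.blocks == ((100, 650),)
        assert ann.mature_length == 550

    def test_intronic(self, toy_model):
        ann = classify_circrna(_call(210, 290), toy_model)
        assert ann.circ_type == "ciRNA"
        assert ann.gene_id == "G1"
        assert ann.transcript_id == "NA"
        assert ann.blocks == ((210, 290),)

    def test_intergenic_on_featureless_chrom(self, toy_model):
        ann = classify_circrna(_call(10, 90, chrom="chrM"), toy_model)
        assert ann.circ_type == "intergenic"
        assert ann.gene_id == ann.gene_name == ann.transcript_id == "NA"

    def test_zero_boundary_forces_exact(self, toy_model):
        assert classify_circrna(_call(100, 400), toy_model, 0).circ_type == "circRNA"
        assert (
            classify_circrna(_call(95, 405), toy_model, 0).circ_type
            == "EI-circRNA"
        )

    def test_boundary_is_inclusive(self, toy_model):
        # distance exactly equal to the threshold still counts as exonic
        ann = classify_circrna(_call(95, 405), toy_model, exon_boundary=5)
        assert ann.circ_type == "circRNA"
        assert classify_circrna(_call(95, 405), toy_model, 4).circ_type == "EI-circRNA"

    def test_every_call_gets_exactly_one_label(self, reference, truth):
        for t in truth:
            ann = classify_circrna(
                _call(t.start, t.end, chrom=t.chrom, strand=t.strand),
                reference.model,
            )
            assert ann.circ_type == t.label


def test_same_strand_gene_preferred():
    model = GeneModel()
    model.add_exon("chr1", 100, 200, "+", "Gplus", "Tplus", "PLUS")
    model.add_exon("chr1", 100, 200, "-", "Gminus", "Tminus", "MINUS")
    model.finalise()
    assert classify_circrna(_call(100, 200, strand="-"), model).gene_id == "Gminus"
    assert classify_circrna(_call(100, 200, strand="+"), model).gene_id == "Gplus"


class TestBestTranscript:
    def _tx(self, tx_id, exons):
        return Transcript(tx_id, "g", "chr1", "+", exons=list(exons))

    def test_single_candidate(self):
        tx = self._tx("T1", [(100, 200)])
        assert best_transcript(100, 200, [tx]).transcript_id == "T1"

    def test_minimises_total_distance(self):
        t1 = self._tx("T1", [(100, 200), (300, 400)])
        t2 = self._tx("T2", [(120, 230), (310, 417)])
        match = best_transcript(100, 400, [t1, t2])
        assert match.transcript_id == "T1"
        assert match.exact

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            best_transcript(0, 10, [])

    def test_tie_breaks_deterministic(self):
        a = self._tx("TB", [(100, 200)])
        b = self._tx("TA", [(100, 200)])
        # equal distance and exon count -> lexicographically smaller id
        assert best_transcript(100, 200, [a, b]).transcript_id == "TA"
        assert best_transcript(100, 200, [b, a]).transcript_id == "TA"
        # more exons wins over id
        c = self._tx("TZ", [(100, 150), (160, 200)])
        assert best_transcript(100, 200, [b, c]).transcript_id == "TZ"

    def test_matches_exhaustive_argmin(self):
        rng = random.Random(9)
        for _ in range(20):
            transcripts = []
            for i in range(10):
                n = rng.randrange(1, 5)
                exons, pos = [], rng.randrange(0, 500)
                for _ in range(n):
                    length = rng.randrange(50, 200)
                    exons.append((pos, pos + length))
                    pos += length + rng.randrange(50, 300)
                transcripts.append(self._tx(f"T{i:02d}", exons))
            start = rng.randrange(0, 800)
            end = start + rng.randrange(100, 1500)
            got = best_transcript(start, end, transcripts)
            scored = sorted(
                (
                    min(abs(start - s) for s, _ in tx.exons)
                    + min(abs(end - e) for _, e in tx.exons),
                    -len(tx.exons),
                    tx.transcript_id,
                )
                for tx in transcripts
            )
            assert (
                got.total, -len(
                    next(t for t in transcripts
                         if t.transcript_id == scored[0][2]).exons
                ),
            ) == (scored[0][0], scored[0][1])
            assert got.transcript_id == scored[0][2]


class TestExonBlocks:
    def test_snap_to_call_ends(self):
        tx = Transcript("T", "g", "chr1", "+", exons=[(100, 200), (300, 400)])
        assert exon_blocks(95, 405, tx) == ((95, 200), (300, 405))

    def test_single_exon_equals_span(self):
        tx = Transcript("T", "g", "chr1", "+", exons=[(100, 200), (300, 400)])
        assert exon_blocks(100, 200, tx) == ((100, 200),)

    def test_empty_intersection_rejected(self):
        tx = Transcript("T", "g", "chr1", "+", exons=[(100, 200)])
        with pytest.raises(ValueError):
            exon_blocks(300, 400, tx)

    def test_matches_per_base_membership(self):
        rng = random.Random(13)
        for _ in range(30):
            exons, pos = [], rng.randrange(0, 100)
            for _ in range(rng.randrange(1, 6)):
                length = rng.randrange(20, 80)
                exons.append((pos, pos + length))
                pos += length + rng.randrange(20, 100)
            tx = Transcript("T", "g", "chr1", "+", exons=exons)
            start = rng.randrange(exons[0][0], exons[-1][1] - 1)
            end = rng.randrange(start + 1, exons[-1][1] + 1)
            inters = [
                (max(s, start), min(e, end))
                for s, e in exons
                if s < end and e > start
            ]
            if not inters:
                continue
            blocks = exon_blocks(start, end, tx)
            # per-base membership: exon∩call bases, plus the head/tail gaps
            # the snap rule fills in
            member = set()
            for s, e in inters:
                member.update(range(s, e))
            member.update(range(start, inters[0][0]))
            member.update(range(inters[-1][1], end))
            runs = []
            for base in sorted(member):
                if runs and runs[-1][1] == base:
                    runs[-1][1] = base + 1
                else:
                    runs.append([base, base + 1])
            assert blocks == tuple(tuple(r) for r in runs)


class TestMatureSequence:
    GENOME = {"c": "ACGTNNNNTTAA"}

    def _record(self, blocks, strand):
        return AnnotatedCircRNA(
            "c", blocks[0][0], blocks[-1][1], strand, "circRNA",
            "g", "G", "t", tuple(blocks),
        )

    def test_plus_strand_concatenation(self):
        rec = self._record([(0, 4), (8, 12)], "+")
        assert mature_sequence(rec, self.GENOME) == "ACGTTTAA"

    def test_minus_strand_reverse_complement(self):
        rec = self._record([(0, 4), (8, 12)], "-")
        assert mature_sequence(rec, self.GENOME) == "TTAAACGT"

    def test_length_equals_mature_length(self, reference, truth):
        for t in truth:
            ann = classify_circrna(
                _call(t.start, t.end, chrom=t.chrom, strand=t.strand),
                reference.model,
            )
            seq = mature_sequence(ann, reference.genome)
            assert len(seq) == ann.mature_length


def test_classification_invariant_to_transcript_order(reference, truth):
    """Tie-breaks make the result independent of model insertion order."""
    model = reference.model
    reversed_model = GeneModel()
    for tx in reversed(list(model.transcripts.values())):
        gene = model.genes[tx.gene_id]
        for exon in reversed(tx.exons):
            reversed_model.add_exon(
                tx.chrom, exon[0], exon[1], tx.strand,
                gene.gene_id, tx.transcript_id, gene.gene_name,
            )
    reversed_model.finalise()
    for t in truth:
        call = _call(t.start, t.end, chrom=t.chrom, strand=t.strand)
        a = classify_circrna(call, model)
        b = classify_circrna(call, reversed_model)
        assert (a.circ_type, a.transcript_id, a.blocks) == (
            b.circ_type, b.transcript_id, b.blocks,
        )
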