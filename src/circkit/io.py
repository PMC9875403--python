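"""Readers and writers for the file dialects the toolkit consumes and emits.

Seven circRNA caller output dialects (CIRCexplorer2, CIRIquant/CIRI2,
circRNA_finder, DCC, find_circ, MapSplice, Segemehl) are normalised into
:class:`~circkit.records.CircRNACall` records with 0-based half-open
coordinates. Each dialect is declared as data (:class:`ToolDialect`), so a
layout correction for a new caller version is a one-line edit.

Also here: ENSEMBL-style GTF loading into a :class:`GeneModel` with interval
lookup, extended BED12 (16 column) output, truth-set BED reading, and
strand-aware FASTA sequence extraction/writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .records import AnnotatedCircRNA, CircRNACall


class DialectError(ValueError):
    """Unknown caller identifier."""


class ParseError(ValueError):
    """Malformed input line; message carries file path and line number."""


# ---------------------------------------------------------------------------
# Caller output dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolDialect:
    """Declarative description of one caller's tabular output layout.

    ``coordinate_base`` is 0 or 1; ``end_inclusive`` says whether the end
    column is the last covered base (1-based inclusive convention) or one past
    it. Conversion to canonical 0-based half-open is total and invertible:
    ``start0 = start - base``; ``end0 = end - base + end_inclusive``.
    """

    tool: str
    coordinate_base: int
    end_inclusive: bool
    n_columns: int
    chrom_col: int
    start_col: int
    end_col: int
    bsj_col: int
    strand_col: Optional[int] = None
    comment_prefix: Optional[str] = None
    #: template used by the fixture writer for filler columns
    filler: str = "."

    def to_canonical(self, start: int, end: int) -> Tuple[int, int]:
        return (start - self.coordinate_base,
                end - self.coordinate_base + int(self.end_inclusive))

    def from_canonical(self, start0: int, end0: int) -> Tuple[int, int]:
        return (start0 + self.coordinate_base,
                end0 + self.coordinate_base - int(self.end_inclusive))


# Layouts follow each tool's published format family; BED-derived outputs
# (find_circ, CIRCexplorer2, circRNA_finder, Segemehl) are 0-based half-open,
# CIRI2/CIRIquant, DCC and MapSplice report 1-based inclusive coordinates.
DIALECTS: Dict[str, ToolDialect] = {
    d.tool: d
    for d in (
        # BED12-like circularRNA_known.txt; readNumber in column 13.
        ToolDialect("circexplorer2", 0, False, 18, 0, 1, 2, 12, 5, "#"),
        # CIRI2 tabular output with its characteristic header line.
        ToolDialect("ciriquant", 1, True, 11, 1, 2, 3, 4, 10, "circRNA_ID"),
        # BED6 with junction-read count in the score column.
        ToolDialect("circrna_finder", 0, False, 6, 0, 1, 2, 4, 5),
        # CircRNACount-style: Chr Start End Strand count, with header.
        ToolDialect("dcc", 1, True, 5, 0, 1, 2, 4, 3, "Chr"),
        # BED6; name column holds the splice-site id.
        ToolDialect("find_circ", 0, False, 6, 0, 1, 2, 4, 5),
        # simplified circular_RNAs.txt: chrom start end name coverage strand.
        ToolDialect("mapsplice", 1, True, 6, 0, 1, 2, 4, 5),
        # sngl-bed-like with the read count in column 7.
        ToolDialect("segemehl", 0, False, 7, 0, 1, 2, 6, 3),
    )
}

SUPPORTED_TOOLS: Tuple[str, ...] = tuple(sorted(DIALECTS))


def get_dialect(tool: str) -> ToolDialect:
    try:
        return DIALECTS[tool]
    except KeyError:
        raise DialectError(
            f"unsupported caller {tool!r}; supported: {', '.join(SUPPORTED_TOOLS)}"
        ) from None


def parse_tool_output(path: str, tool: str, sample: str) -> List[CircRNACall]:
    """Read one caller's native output into canonical calls, preserving order.

    Duplicate keys within the file are merged by summing their BSJ reads; the
    first occurrence's position in the file is kept.
    """
    dialect = get_dialect(tool)
    merged: Dict[Tuple[str, int, int], CircRNACall] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if dialect.comment_prefix and line.startswith(dialect.comment_prefix):
                continue
            fields = line.split("\t")
            if len(fields) != dialect.n_columns:
                raise ParseError(
                    f"{path}:{lineno}: expected {dialect.n_columns} columns "
                    f"for {tool}, got {len(fields)}"
                )
            try:
                raw_start = int(fields[dialect.start_col])
                raw_end = int(fields[dialect.end_col])
                bsj = int(float(fields[dialect.bsj_col]))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinate or read count"
                ) from None
            start, end = dialect.to_canonical(raw_start, raw_end)
            strand = "."
            if dialect.strand_col is not None:
                strand = fields[dialect.strand_col]
                if strand not in ("+", "-"):
                    strand = "."
            chrom = fields[dialect.chrom_col]
            key = (chrom, start, end)
            try:
                if key in merged:
                    prev = merged[key]
                    merged[key] = CircRNACall(
                        chrom, start, end, prev.strand,
                        prev.bsj_reads + bsj, tool, sample,
                    )
                else:
                    merged[key] = CircRNACall(
                        chrom, start, end, strand, bsj, tool, sample
                    )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return list(merged.values())


def write_tool_output(calls: Sequence[CircRNACall], path: str, tool: str) -> None:
    """Write calls in a caller's native dialect (inverse of the parser)."""
    dialect = get_dialect(tool)
    with open(path, "w") as handle:
        if dialect.comment_prefix == "circRNA_ID":
            handle.write(
                "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
                "SM_MS_SMS\t#non_junction_reads\tjunction_reads_ratio\t"
                "circRNA_type\tgene_id\tstrand\n"
            )
        elif dialect.comment_prefix == "Chr":
            handle.write("Chr\tStart\tEnd\tStrand\tCount\n")
        elif dialect.comment_prefix == "#":
            handle.write("#" + "\t".join(f"col{i+1}" for i in range(dialect.n_columns)) + "\n")
        for call in calls:
            raw_start, raw_end = dialect.from_canonical(call.start, call.end)
            fields = [dialect.filler] * dialect.n_columns
            fields[dialect.chrom_col] = call.chrom
            fields[dialect.start_col] = str(raw_start)
            fields[dialect.end_col] = str(raw_end)
            fields[dialect.bsj_col] = str(call.bsj_reads)
            if dialect.strand_col is not None:
                fields[dialect.strand_col] = call.strand if call.strand in "+-" else "."
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_ids: List[str] = field(default_factory=list)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    #: sorted, non-overlapping 0-based half-open exon intervals
    exons: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


class GeneModel:
    """Genes -> transcripts -> exons from a GTF, with fast interval lookup."""

    def __init__(self) -> None:
        self.genes: Dict[str, Gene] = {}
        self.transcripts: Dict[str, Transcript] = {}
        self._gene_tree: Dict[str, IntervalTree] = {}

    @property
    def n_exons(self) -> int:
        return sum(len(t.exons) for t in self.transcripts.values())

    def add_exon(self, chrom: str, start: int, end: int, strand: str,
                 gene_id: str, transcript_id: str, gene_name: str) -> None:
        gene = self.genes.get(gene_id)
        if gene is None:
            gene = Gene(gene_id, gene_name, chrom, strand, start, end)
            self.genes[gene_id] = gene
        else:
            gene.start = min(gene.start, start)
            gene.end = max(gene.end, end)
        tx = self.transcripts.get(transcript_id)
        if tx is None:
            tx = Transcript(transcript_id, gene_id, chrom, strand)
            self.transcripts[transcript_id] = tx
            gene.transcript_ids.append(transcript_id)
        tx.exons.append((start, end))

    def finalise(self) -> None:
        for tx in self.transcripts.values():
            tx.exons.sort()
            for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
                if s2 < e1:
                    raise ParseError(
                        f"overlapping exons in transcript {tx.transcript_id}"
                    )
        for gene in self.genes.values():
            self._gene_tree.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end, gene.gene_id
            )

    def overlapping_genes(self, chrom: str, start: int, end: int) -> List[Gene]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return [self.genes[g] for g in hits]

    def gene_transcripts(self, gene_id: str) -> List[Transcript]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]


def read_gtf(path: str) -> GeneModel:
    """Load exon features from an ENSEMBL-attribute-style GTF.

    Coordinates are converted from GTF 1-based inclusive to 0-based half-open.
    ``gene_name`` falls back to ``gene_id`` when absent.
    """
    model = GeneModel()
    for feature in gffutils.DataIterator(path):
        if feature.featuretype != "exon":
            continue
        if "transcript_id" not in feature.attributes:
            raise ParseError(f"{path}: exon feature lacking transcript_id")
        if feature.end < feature.start:
            raise ParseError(
                f"{path}: exon with end < start at {feature.seqid}:{feature.start}"
            )
        gene_id = feature.attributes.get("gene_id", ["NA"])[0]
        gene_name = feature.attributes.get("gene_name", [gene_id])[0]
        model.add_exon(
            feature.seqid,
            feature.start - 1,
            feature.end,
            feature.strand,
            gene_id,
            feature.attributes["transcript_id"][0],
            gene_name,
        )
    model.finalise()
    return model


# ---------------------------------------------------------------------------
# Extended BED12 and truth BED
# ---------------------------------------------------------------------------

BED12_EXT_COLUMNS = (
    "chrom", "chromStart", "chromEnd", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts", "circType", "geneName", "transcript", "matureLength",
)


def write_bed12(records: Sequence[AnnotatedCircRNA], path: str) -> None:
    """Write annotated circRNAs as extended BED12 (16 tab-separated columns).

    Columns 1-12 follow the standard BED12 contract (blockStarts relative to
    chromStart); columns 13-16 add circRNA type, parent gene, transcript and
    mature spliced length.
    """
    with open(path, "w") as handle:
        for rec in records:
            sizes = ",".join(str(e - s) for s, e in rec.blocks)
            offsets = ",".join(str(s - rec.start) for s, _ in rec.blocks)
            row = (
                rec.chrom, str(rec.start), str(rec.end), rec.circ_id, "0",
                rec.strand, str(rec.start), str(rec.end), "0",
                str(len(rec.blocks)), sizes, offsets,
                rec.circ_type, rec.gene_name, rec.transcript_id,
                str(rec.mature_length),
            )
            handle.write("\t".join(row) + "\n")


def read_bed12(path: str) -> List[AnnotatedCircRNA]:
    """Re-parse an extended BED12 file written by :func:`write_bed12`."""
    records: List[AnnotatedCircRNA] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BED12_EXT_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(BED12_EXT_COLUMNS)} columns"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            sizes = [int(x) for x in fields[10].split(",") if x]
            offsets = [int(x) for x in fields[11].split(",") if x]
            if len(sizes) != int(fields[9]) or len(offsets) != int(fields[9]):
                raise ParseError(f"{path}:{lineno}: blockCount mismatch")
            blocks = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            gene_name = fields[13]
            records.append(
                AnnotatedCircRNA(
                    chrom, start, end, fields[5], fields[12],
                    "NA" if gene_name == "NA" else gene_name,
                    gene_name, fields[14], blocks,
                )
            )
    return records


def read_truth_bed(path: str) -> List[Tuple[str, int, int, str, str]]:
    """Read a truth-set BED: (chrom, start, end, label, strand) per record."""
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            label = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            out.append((fields[0], int(fields[1]), int(fields[2]), label, strand))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def extract_sequence(genome, chrom: str, start: int, end: int,
                     strand: str = "+") -> str:
    """Slice ``[start, end)`` from an indexed FASTA (e.g. ``pyfaidx.Fasta``).

    Minus-strand requests return the reverse complement of the forward slice.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    chrom_len = len(genome[chrom])
    if not 0 <= start < end <= chrom_len:
        raise IndexError(
            f"interval {start}-{end} outside {chrom} (length {chrom_len})"
        )
    seq = str(genome[chrom][start:end]).upper()
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 60) -> None:
    """Write sequences with 60-column line wrapping."""
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
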