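"""Core record types shared across the toolkit.

All genomic intervals are 0-based half-open internally, regardless of the
convention used by any caller's native output. ``CircKey`` — the tuple
``(chrom, start, end)`` — is the cross-tool identity of a back-splice
junction; strand is deliberately excluded (see :mod:`circkit.consensus`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

CircKey = Tuple[str, int, int]

#: The four annotation classes, in the order they are documented.
CIRC_TYPES = ("circRNA", "EI-circRNA", "ciRNA", "intergenic")

#: miRNA seed-site types ordered by increasing specificity/efficacy.
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


@dataclass(frozen=True)
class CircRNACall:
    """One normalised back-splice junction call from one tool on one sample."""

    chrom: str
    start: int
    end: int
    strand: str
    bsj_reads: int
    tool: str
    sample: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.bsj_reads < 0:
            raise ValueError("bsj_reads must be >= 0")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> CircKey:
        return (self.chrom, self.start, self.end)

    @property
    def circ_id(self) -> str:
        return circ_id(self.chrom, self.start, self.end, self.strand)


def circ_id(chrom: str, start: int, end: int, strand: str = ".") -> str:
    """Render the canonical circRNA string identifier ``chrom:start-end:strand``."""
    return f"{chrom}:{start}-{end}:{strand}"


def parse_circ_id(text: str) -> Tuple[str, int, int, str]:
    """Invert :func:`circ_id`. Chromosome names may themselves contain ':'."""
    head, _, strand = text.rpartition(":")
    chrom, _, span = head.rpartition(":")
    if not chrom or "-" not in span:
        raise ValueError(f"malformed circRNA identifier: {text!r}")
    start_s, _, end_s = span.rpartition("-")
    return chrom, int(start_s), int(end_s), strand


@dataclass(frozen=True)
class AnnotatedCircRNA:
    """A consensus call plus its reference-guided annotation.

    ``blocks`` are sorted 0-based half-open intervals tiling within
    ``[start, end)``: the first block starts at ``start`` and the last ends at
    ``end``. ``mature_length`` is the summed block length in nucleotides.
    """

    chrom: str
    start: int
    end: int
    strand: str
    circ_type: str
    gene_id: str
    gene_name: str
    transcript_id: str
    blocks: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.circ_type not in CIRC_TYPES:
            raise ValueError(f"unknown circRNA type {self.circ_type!r}")
        if not self.blocks:
            raise ValueError("at least one block is required")
        if self.blocks[0][0] != self.start or self.blocks[-1][1] != self.end:
            raise ValueError("blocks must span [start, end) exactly at the ends")
        prev_end = None
        for b_start, b_end in self.blocks:
            if not self.start <= b_start < b_end <= self.end:
                raise ValueError(f"block ({b_start},{b_end}) outside record span")
            if prev_end is not None and b_start < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = b_end
        if self.circ_type == "intergenic" and self.gene_id != "NA":
            raise ValueError("intergenic records must carry gene_id 'NA'")

    @property
    def key(self) -> CircKey:
        return (self.chrom, self.start, self.end)

    @property
    def circ_id(self) -> str:
        return circ_id(self.chrom, self.start, self.end, self.strand)

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class MREPrediction:
    """One circRNA-miRNA interaction supported by both prediction algorithms."""

    circ_id: str
    mirna_id: str
    miranda_score: float
    mfe: float
    site_type: str
    position: int
    junction_spanning: bool = False

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class ConsensusRecord:
    """A back-splice junction surviving cross-tool consensus filtering."""

    key: CircKey
    strand: str
    per_tool_counts: Dict[str, int] = field(default_factory=dict)
    aggregated_count: int = 0
    aggregated_exact: float = 0.0

    @property
    def n_tools(self) -> int:
        return len(self.per_tool_counts)

    @property
    def circ_id(self) -> str:
        return circ_id(*self.key, self.strand)


@dataclass(frozen=True)
class BenchmarkResult:
    """Detection counts and derived metrics against a truth set (percent)."""

    detected: int
    tp: int
    truth_size: int
    precision: float
    sensitivity: float
    f1: float
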